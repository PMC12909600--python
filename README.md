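# latticert

A planning toolkit for **simulation-free spatially fractionated (lattice)
radiotherapy**. In lattice radiotherapy (a modern form of SFRT/GRID
therapy), a high ablative dose is delivered to a sparse 3D array of small
spherical sub-volumes inside a bulky tumour rather than uniformly, exploiting
the steep dose gradients of SBRT delivery. This package implements the
computational core of a two-phase adaptive workflow for medical physicists
and planning researchers:

1. **Phase 1** — 12 Gy to a lattice of 1 cm diameter spheres spaced 2 cm
   center-to-center (PTV_High), with a simultaneous 4 Gy bath to the gross
   tumour volume's 5 mm expansion (PTV_Low);
2. **Phase 2** — four further fractions of 4 Gy to PTV_Low, totalling 20 Gy
   to the low-dose target.

It provides:

* sphere-**lattice generation** about a center point, with the clinical
  cropping rule: every sphere outside the GTV or within 1 cm of its boundary
  is removed (partially cropped spheres are deleted automatically via a
  voxel-completeness tolerance);
* **margin operations** (uniform expand/retract by exact Euclidean distance
  transform) deriving PTV_Low, PTV_High and the normal-tissue ring
  `(PTV_Low + 3 cm) − PTV_Low`;
* a deterministic **stand-in dose painter** (radial kernels with hard caps)
  that constructs Phase 1/Phase 2 dose fields satisfying the planning
  objectives by design — it replaces a commercial optimizer so the
  evaluation stack can be exercised end to end;
* **DVH evaluation**: D0.03cc, Dx%, VxGy, Dmean, RTOG conformity index
  `CI = V_rx(Body) / V(target)`, objective checking against the clinical
  template (PTV_High V12Gy ≥ 90 %, D0.03cc ≤ 15 Gy; PTV_Low D95% ≥ 4 Gy,
  D0.03cc ≤ 12 Gy, Dmean 3.5–5.5 Gy; ring D0.03cc ≤ 4 Gy) and
  plan-vs-plan delta reports;
* **3D gamma-index** secondary verification (global normalisation,
  trilinear search, presets 3 %/2 mm and 5 %/3 mm with a 10 % low-dose
  threshold, 90 % pass gate);
* **contour verification** via Dice coefficient and mean surface distance;
* a **synthetic patient generator** (thorax and extremity cases, ellipsoid
  or lobed GTVs, seeded and fully deterministic) so the whole pipeline runs
  with no patient data.

Masks and doses are NRRD or NIfTI files on axis-aligned millimetre grids;
in memory everything is NumPy arrays on a shared `VoxelGrid`.

## Worked example

```python
import latticert as lt
from latticert.workflow import run_phase1, run_phase2, WorkflowConfig

case = lt.generate_case(lt.CaseSpec(site="thorax", seed=1))
res = run_phase1(case, WorkflowConfig())
print(res.metrics.to_frame()[["structure", "metric", "value", "passed"]])
total, summary = run_phase2(case, res)
print(f"gamma pass rate: {res.gamma.pass_rate_pct:.1f}%")
print(f"total PTV_Low mean: {summary['ptv_low_mean_total_gy']:.2f} Gy")
```

prints

```
  structure   metric       value  passed
0  PTV_High    V12Gy  100.000000    True
1  PTV_High  D0.03cc   12.000000    True
2   PTV_Low     D95%    4.000000    True
3   PTV_Low     V4Gy  100.000000    True
4   PTV_Low  D0.03cc   12.000000    True
5   PTV_Low    Dmean    4.328592    True
6      Ring  D0.03cc    3.529988    True
gamma pass rate: 100.0%
total PTV_Low mean: 20.33 Gy
```

i.e. the painted Phase 1 plan covers the sphere lattice at the 12 Gy
prescription with no hotspot above 15 Gy, keeps the low-dose bath inside its
mean-dose window, spills at most 3.5 Gy into the normal-tissue ring, passes
secondary gamma verification, and the accumulated two-phase course delivers
the prescribed 20 Gy to the low-dose target.

The same pipeline is available from the shell:

```bash
latticert run --site thorax --seed 1 --out results/case01
latticert cohort --n-thorax 5 --n-extremity 5 --out results/cohort
```

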