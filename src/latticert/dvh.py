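"""Cumulative DVHs, dose metrics, objective checking and plan comparison.

Metric conventions (standard DVH nomenclature):

* ``D(v)`` — minimum dose received by the hottest ``v`` (cc or %) of a
  structure, e.g. D0.03cc (near-maximum) or D95%.
* ``V(d)`` — structure volume (relative % or absolute cc) receiving at
  least ``d`` Gy, e.g. V12Gy.
* ``Dmean`` — arithmetic mean of in-structure voxel doses.
* RTOG conformity index — prescription-isodose volume inside Body divided
  by the target volume.

D(v) uses partial-voxel interpolation at the volume cut (with 2 mm voxels a
0.03 cc cut falls inside the fourth-hottest voxel), with a stable descending
dose sort as the documented tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DoseGrid, StructureMask

__all__ = [
    "DVHCurve",
    "Objective",
    "ObjectiveSet",
    "default_objectives",
    "MetricReport",
    "dose_at_volume",
    "volume_at_dose",
    "mean_dose",
    "rtog_ci",
    "dvh_curve",
    "check_objectives",
    "compare_plans",
    "TABLE_METRICS",
]


def _in_mask_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    dose.grid.require_same(mask.grid, "DVH metric")
    if mask.is_empty:
        raise ValueError(f"DVH metric on empty structure {mask.name!r}")
    return dose.dose_gy[mask.occupancy]


def dose_at_volume(dose: DoseGrid, mask: StructureMask, volume: float,
                   relative: bool = False) -> float:
    """D(v): the largest dose d such that at least ``volume`` of the
    structure receives >= d.

    ``volume`` is absolute cc by default, or percent of the structure
    volume when ``relative``. Partial-voxel interpolation is applied at the
    cut; requesting more than the structure volume is an error.
    """
    vals = _in_mask_doses(dose, mask)
    vv = mask.grid.voxel_volume_cc
    total_cc = vals.size * vv
    v_cc = total_cc * volume / 100.0 if relative else float(volume)
    if v_cc > total_cc * (1 + 1e-9):
        raise ValueError(
            f"requested volume {v_cc:.3f} cc exceeds structure volume {total_cc:.3f} cc"
        )
    if v_cc <= 0:
        return float(vals.max())
    order = np.sort(vals, kind="stable")[::-1]  # descending, stable tie-break
    cum_cc = np.arange(1, order.size + 1) * vv
    # piecewise-linear through (k * vv, k-th hottest dose); clamp inside first voxel
    return float(np.interp(v_cc, cum_cc, order))


def volume_at_dose(dose: DoseGrid, mask: StructureMask, threshold_gy: float,
                   relative: bool = True) -> float:
    """V(d): structure volume receiving at least ``threshold_gy``, as
    percent of the structure (default) or absolute cc."""
    vals = _in_mask_doses(dose, mask)
    n = int((vals >= threshold_gy).sum())
    if relative:
        return 100.0 * n / vals.size
    return n * mask.grid.voxel_volume_cc


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    return float(_in_mask_doses(dose, mask).mean())


def rtog_ci(dose: DoseGrid, target: StructureMask, rx_gy: float,
            body: StructureMask) -> float:
    """RTOG conformity index: (Body volume receiving >= rx) / target volume."""
    if rx_gy <= 0:
        raise ValueError("rx_gy must be positive")
    if target.is_empty:
        raise ValueError("rtog_ci requires a non-empty target")
    iso_cc = volume_at_dose(dose, body, rx_gy, relative=False)
    return iso_cc / target.volume_cc


def dvh_curve(dose: DoseGrid, mask: StructureMask,
              bin_gy: float = 0.05) -> "DVHCurve":
    vals = _in_mask_doses(dose, mask)
    edges = np.arange(0.0, vals.max() + 2 * bin_gy, bin_gy)
    vv = mask.grid.voxel_volume_cc
    ge = (vals[None, :] >= edges[:, None]).sum(axis=1)
    return DVHCurve(
        structure=mask.name,
        dose_gy=edges,
        volume_pct=100.0 * ge / vals.size,
        volume_cc=ge * vv,
    )


@dataclass
class DVHCurve:
    """Cumulative DVH: volume receiving at least each dose level."""

    structure: str
    dose_gy: np.ndarray
    volume_pct: np.ndarray
    volume_cc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_gy": self.dose_gy, "pct_volume": self.volume_pct,
             "cc": self.volume_cc}
        )


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Objective:
    """One planning objective on a named structure.

    ``metric`` is one of ``V<d>Gy`` (relative %), ``D<v>cc``, ``D<v>%`` or
    ``Dmean``; ``comparator`` is ``>=``, ``<=`` or ``within`` (the latter
    with ``threshold`` as a (lo, hi) pair).
    """

    structure: str
    metric: str
    comparator: str
    threshold: float | tuple[float, float]

    def evaluate(self, dose: DoseGrid, mask: StructureMask) -> float:
        m = self.metric
        if m == "Dmean":
            return mean_dose(dose, mask)
        if m.startswith("V") and m.endswith("Gy"):
            return volume_at_dose(dose, mask, float(m[1:-2]), relative=True)
        if m.startswith("D") and m.endswith("cc"):
            return dose_at_volume(dose, mask, float(m[1:-2]), relative=False)
        if m.startswith("D") and m.endswith("%"):
            return dose_at_volume(dose, mask, float(m[1:-1]), relative=True)
        raise ValueError(f"unrecognised metric descriptor {self.metric!r}")

    def passes(self, value: float) -> bool:
        if self.comparator == ">=":
            return value >= self.threshold
        if self.comparator == "<=":
            return value <= self.threshold
        if self.comparator == "within":
            lo, hi = self.threshold
            return lo <= value <= hi
        raise ValueError(f"unknown comparator {self.comparator!r}")


@dataclass
class ObjectiveSet:
    objectives: list[Objective] = field(default_factory=list)


def default_objectives(strict_ptv_low_dmean: bool = False) -> ObjectiveSet:
    """The clinical template objectives.

    PTV_High: V12Gy >= 90 %, D0.03cc <= 15 Gy. PTV_Low: D95% >= 4 Gy,
    D0.03cc <= 12 Gy, Dmean in [3.5, 5.5] Gy (the stricter 5.0 Gy upper
    bound used for prospective plan acceptance is available via
    ``strict_ptv_low_dmean``). Ring: D0.03cc <= 4 Gy.
    """
    dmean_hi = 5.0 if strict_ptv_low_dmean else 5.5
    return ObjectiveSet([
        Objective("PTV_High", "V12Gy", ">=", 90.0),
        Objective("PTV_High", "D0.03cc", "<=", 15.0),
        Objective("PTV_Low", "D95%", ">=", 4.0),
        Objective("PTV_Low", "V4Gy", ">=", 95.0),
        Objective("PTV_Low", "D0.03cc", "<=", 12.0),
        Objective("PTV_Low", "Dmean", "within", (3.5, dmean_hi)),
        Objective("Ring", "D0.03cc", "<=", 4.0),
    ])


@dataclass
class MetricReport:
    """Evaluated objectives for one plan: values, per-objective pass flags
    and the overall verdict."""

    rows: list[dict] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return all(r["passed"] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_dict(self) -> dict:
        return {"overall_pass": self.overall_pass, "objectives": self.rows}


def check_objectives(dose: DoseGrid, structures: dict[str, StructureMask],
                     objectives: ObjectiveSet | None = None) -> MetricReport:
    """Evaluate every objective; a missing or empty structure is recorded
    as a failure with a reason rather than raising."""
    objectives = objectives or default_objectives()
    report = MetricReport()
    for obj in objectives.objectives:
        row = {"structure": obj.structure, "metric": obj.metric,
               "comparator": obj.comparator, "threshold": obj.threshold,
               "value": None, "passed": False, "reason": ""}
        mask = structures.get(obj.structure)
        if mask is None:
            row["reason"] = "structure missing"
        elif mask.is_empty:
            row["reason"] = "structure empty"
        else:
            value = obj.evaluate(dose, mask)
            row["value"] = float(value)
            row["passed"] = bool(obj.passes(value))
            if not row["passed"]:
                row["reason"] = "objective not met"
        report.rows.append(row)
    return report


# Metric families reported in plan-vs-plan comparisons.
TABLE_METRICS: dict[str, list[str]] = {
    "PTV_High": ["D0.03cc", "V12Gy", "Dmean", "V6Gy", "CI"],
    "PTV_Low": ["D0.03cc", "V4Gy", "Dmean", "V12Gy", "V8Gy"],
    "Ring": ["D0.03cc"],
}

_RX_GY = {"PTV_High": 12.0, "PTV_Low": 4.0}


def _metric_value(metric: str, dose: DoseGrid, mask: StructureMask,
                  structures: dict[str, StructureMask]) -> float:
    if metric == "CI":
        body = structures.get("Body", mask)
        return rtog_ci(dose, mask, _RX_GY.get(mask.name, 12.0), body)
    return Objective(mask.name, metric, ">=", 0.0).evaluate(dose, mask)


def compare_plans(dose_a: DoseGrid, dose_b: DoseGrid,
                  structures: dict[str, StructureMask]) -> pd.DataFrame:
    """Absolute per-metric differences |a − b| for the standard metric
    families; symmetric in its two plans."""
    dose_a.grid.require_same(dose_b.grid, "compare_plans")
    rows = []
    for struct, metrics in TABLE_METRICS.items():
        mask = structures.get(struct)
        if mask is None or mask.is_empty:
            continue
        for metric in metrics:
            va = _metric_value(metric, dose_a, mask, structures)
            vb = _metric_value(metric, dose_b, mask, structures)
            rows.append({"structure": struct, "metric": metric,
                         "value_a": va, "value_b": vb,
                         "abs_delta": abs(va - vb)})
    return pd.DataFrame(rows)
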