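import numpy as np
import pytest

import latticert as lt
from latticert.workflow import WorkflowConfig, run_phase1


def make_grid(dims, spacing=1.0, origin=None):
    dims = (dims,) * 3 if np.isscalar(dims) else tuple(dims)
    spacing = (spacing,) * 3 if np.isscalar(spacing) else tuple(spacing)
    if origin is None:
        origin = tuple(-(d - 1) * s / 2.0 for d, s in zip(dims, spacing))
    return lt.VoxelGrid(origin, spacing, dims)


def random_blob(grid, seed, density=0.5, smooth_vox=2.0, role="GTV", name="blob"):
    """Smooth random mask for oracle tests: thresholded filtered noise."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(grid.dims), smooth_vox)
    occ = field > np.quantile(field, 1.0 - density)
    return lt.StructureMask(grid, name, role, occ)


@pytest.fixture(scope="session")
def thorax_case():
    """The default synthetic thorax case used by the end-to-end checks."""
    return lt.generate_case(lt.CaseSpec(site="thorax", seed=1))


@pytest.fixture(scope="session")
def phase1_result(thorax_case):
    """Accepted Phase 1 plan for the default thorax case (computed once)."""
    result = run_phase1(thorax_case, WorkflowConfig())
    assert result.dose is not None, "default thorax case must produce a plan"
    return result
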