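import numpy as np
import pytest

from rehoseed.imgio import BrainMask, GridGeom, Volume4D
from rehoseed.pipeline import pipeline_from_cohort
from rehoseed.synthdata import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_volume(data_3d_t: np.ndarray, tr: float = 2.0, affine: np.ndarray | None = None,
                mask_inside: np.ndarray | None = None) -> Volume4D:
    """Wrap a (x, y, z, t) array as a masked Volume4D."""
    shape = data_3d_t.shape[:3]
    affine = np.diag([4.0, 4.0, 4.0, 1.0]) if affine is None else affine
    geom = GridGeom(shape, affine)
    inside = np.ones(shape, dtype=bool) if mask_inside is None else mask_inside
    mask = BrainMask(geom, inside)
    return Volume4D(geom=geom, mask=mask, data=data_3d_t[mask.inside], tr_seconds=tr)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the generator's default study conditions."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def default_pipeline(default_cohort):
    return pipeline_from_cohort(default_cohort)
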