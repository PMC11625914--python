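import numpy as np
import pytest

from nvcoupling.synthetic import (CohortSpec, generate_atlas,
                                  generate_ground_truth, make_tissue_masks)
from nvcoupling.types import BoldSeries


def tiny_spec(**overrides) -> CohortSpec:
    """Desk-scale study conditions: 7-region atlas on a 16x16x12 grid."""
    kw = dict(n_patients=3, n_controls=2, grid=(16, 16, 12), n_timepoints=80,
              n_regions=7, seed=5)
    kw.update(overrides)
    return CohortSpec(**kw)


@pytest.fixture(scope="session")
def spec():
    return tiny_spec()


@pytest.fixture(scope="session")
def atlas(spec):
    return generate_atlas(spec)


@pytest.fixture(scope="session")
def masks(spec):
    return make_tissue_masks(spec)


@pytest.fixture(scope="session")
def truth(spec):
    return generate_ground_truth(spec)


def make_series(values: np.ndarray, tr_s: float = 1.5,
                mask: np.ndarray | None = None) -> BoldSeries:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape[:3], dtype=bool)
    return BoldSeries(values=values, tr_s=tr_s, brain_mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
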