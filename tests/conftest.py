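import numpy as np
import pandas as pd
import pytest

from cordfa import CohortConfig, FeatureTable, generate_feature_cohort
from cordfa.types import BASE_REGIONS


def random_blob_mask(rng, shape=(24, 24), n_seeds=40):
    """Random connected-ish ROI mask: union of small disks around a center."""
    ny, nx = shape
    cy, cx = rng.integers(6, ny - 6), rng.integers(6, nx - 6)
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for _ in range(n_seeds):
        py = int(np.clip(cy + rng.normal(0, 3), 1, ny - 2))
        px = int(np.clip(cx + rng.normal(0, 3), 1, nx - 2))
        r = rng.integers(1, 4)
        mask |= (yy - py) ** 2 + (xx - px) ** 2 <= r**2
    return mask


def make_table(values, labels, subject_ids=None, feature_names=None):
    """Build a FeatureTable from a plain array for compact test setup."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(labels) > 1:
        values = values.T
    n, m = values.shape
    feature_names = list(feature_names or [f"f{j}" for j in range(m)])
    frame = pd.DataFrame(values, columns=feature_names)
    frame["subject_id"] = subject_ids if subject_ids is not None else [
        f"s{i}" for i in range(n)
    ]
    frame["slice_id"] = range(n)
    frame["class"] = list(labels)
    return FeatureTable(frame, feature_names)


@pytest.fixture
def base_regions():
    return BASE_REGIONS


@pytest.fixture
def small_cohort():
    """Default 14-subject cohort at 12 slices each, fixed seed."""
    return generate_feature_cohort(CohortConfig(seed=11))
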