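import numpy as np
import pandas as pd
import pytest

from gbmrad.radiomics import extract_cohort_features
from gbmrad.synthetic_cohort import (
    default_config,
    generate_cohort,
    make_anatomy,
    zero_effect_config,
)

# Small grid (same physical extent as the default, coarser lattice) keeps
# per-subject generation/extraction around 0.1 s for unit tests.
SMALL = dict(shape=(32, 32, 32), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def small_config():
    return default_config(**SMALL)


@pytest.fixture(scope="session")
def small_zero_config():
    return zero_effect_config(**SMALL)


@pytest.fixture(scope="session")
def small_anatomy(small_config):
    return make_anatomy(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """3 subjects/class on the coarse grid, with anatomy."""
    records, anatomy = generate_cohort(small_config, 3, seed=11)
    return records, anatomy


@pytest.fixture(scope="session")
def small_features(small_cohort):
    records, anatomy = small_cohort
    base = extract_cohort_features(records, anatomy)
    labels = pd.Series({r.subject_id: r.subtype for r in records})
    tc_masks = {r.subject_id: r.mask.region("TC") for r in records}
    return base, labels, tc_masks


@pytest.fixture(scope="session")
def medium_cohort(small_config):
    """8 subjects/class on the coarse grid — enough for 5-fold CV tests."""
    records, anatomy = generate_cohort(small_config, 8, seed=5)
    base = extract_cohort_features(records, anatomy)
    labels = pd.Series({r.subject_id: r.subtype for r in records})
    tc_masks = {r.subject_id: r.mask.region("TC") for r in records}
    return base, labels, tc_masks


@pytest.fixture(scope="session")
def strong_cohort():
    """Default strong-effect cohort, 30 subjects/class, default grid, seed 1."""
    records, anatomy = generate_cohort(default_config(), 30, seed=1)
    base = extract_cohort_features(records, anatomy)
    labels = pd.Series({r.subject_id: r.subtype for r in records})
    tc_masks = {r.subject_id: r.mask.region("TC") for r in records}
    return records, anatomy, base, labels, tc_masks


@pytest.fixture(scope="session")
def zero_cohort():
    """Zero-effect cohort, 30 subjects/class, coarse grid."""
    records, anatomy = generate_cohort(zero_effect_config(**SMALL), 30, seed=17)
    base = extract_cohort_features(records, anatomy)
    labels = pd.Series({r.subject_id: r.subtype for r in records})
    tc_masks = {r.subject_id: r.mask.region("TC") for r in records}
    return base, labels, tc_masks


def rng(seed=0):
    return np.random.default_rng(seed)
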