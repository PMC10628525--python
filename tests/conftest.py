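import numpy as np
import pytest

from deltarad import CohortConfig, generate_cohort
from deltarad.pipeline import build_feature_table

#: Shared small-volume cohort geometry used by the heavier fixtures.
SMALL_SHAPE = (24, 24, 24)
SMALL_RADII = (5.0, 7.0)


def planted_config(seed: int, n_pcr: int = 78, n_nonpcr: int = 85) -> CohortConfig:
    """Cohort with a strong planted C4 enhancement-decline class difference."""
    return CohortConfig(
        n_pcr=n_pcr,
        n_nonpcr=n_nonpcr,
        image_shape=SMALL_SHAPE,
        tumor_radius_range_mm=SMALL_RADII,
        decline_pcr=(1.0, 0.6, 0.15),
        decline_nonpcr=(1.0, 0.95, 0.85),
        noise_sd=2.0,
        reader_perturb_mm=0.0,
        seed=seed,
    )


def null_config(seed: int, n_per_class: int = 75) -> CohortConfig:
    """Cohort with identical decline factors in both classes (no signal)."""
    return CohortConfig(
        n_pcr=n_per_class,
        n_nonpcr=n_per_class,
        image_shape=SMALL_SHAPE,
        tumor_radius_range_mm=SMALL_RADII,
        decline_pcr=(1.0, 0.8, 0.6),
        decline_nonpcr=(1.0, 0.8, 0.6),
        noise_sd=2.0,
        reader_perturb_mm=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def null_table():
    """Longitudinal feature table of a no-signal cohort (75 + 75 subjects)."""
    cohort = generate_cohort(null_config(seed=20260906))
    return build_feature_table(cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """18-subject planted-effect cohort with reader2/repeat masks."""
    cfg = CohortConfig(
        n_pcr=9,
        n_nonpcr=9,
        image_shape=SMALL_SHAPE,
        tumor_radius_range_mm=SMALL_RADII,
        decline_pcr=(1.0, 0.6, 0.15),
        decline_nonpcr=(1.0, 0.95, 0.85),
        noise_sd=2.0,
        reader_perturb_mm=1.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_feature_table(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
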