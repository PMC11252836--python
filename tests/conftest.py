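import pytest

from kittengrowth import SimConfig, breed_threshold_table, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """~500-kitten cohort for structural tests."""
    cfg = SimConfig(n_litters=120, seed=7)
    return simulate_cohort(cfg), breed_threshold_table(cfg), cfg


@pytest.fixture(scope="session")
def study_scale_cohort():
    """Default-condition cohort at the study's scale (~5,500 kittens)."""
    cfg = SimConfig(seed=1)
    return simulate_cohort(cfg), breed_threshold_table(cfg), cfg
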