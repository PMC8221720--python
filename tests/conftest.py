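import pytest

import audiocohort as ac


@pytest.fixture(scope="session")
def small_cohort():
    """A small default cohort for structural/pipeline tests."""
    cfg = ac.CohortConfig(n_patients=400, seed=7)
    cohort, truth = ac.generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def big_default_cohort():
    """Large default-config cohort shared by calibration/recovery tests."""
    cfg = ac.CohortConfig(n_patients=50_000, seed=11)
    cohort, truth = ac.generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def big_default_bundle(big_default_cohort):
    cfg, cohort, _ = big_default_cohort
    return cfg, ac.run_pipeline(cohort)


@pytest.fixture()
def params():
    return ac.PersistenceParams()
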