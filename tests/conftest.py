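import pytest

from apoekit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """2000-sample cohort with a raised hazard so events are plentiful."""
    config = SimulationConfig(n_samples=2000, baseline_hazard=3e-3, seed=42)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def study_cohort():
    """One cohort at the emulated study scale (~600 events)."""
    return simulate_cohort(SimulationConfig(n_samples=51_104, seed=1))


@pytest.fixture(scope="session")
def rich_e2_cohort():
    """Cohort with boosted e2 so the e2/e2 reference has plenty of cases."""
    config = SimulationConfig(
        n_samples=20_000,
        hap_freqs={"e2": 0.2, "e3": 0.6, "e4": 0.2},
        baseline_hazard=3e-3,
        seed=7,
    )
    return simulate_cohort(config)
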