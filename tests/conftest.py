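import warnings

import pytest

from fidtol import SamplerSettings, SimulationConfig, ToleranceModel, simulate_dataset

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale campaign: 10 individuals x 4 trials/observer over 8 dates."""
    return SimulationConfig(n_individuals=10, trials_per_observer=4, n_dates=8, seed=42)


@pytest.fixture(scope="session")
def small_trials(small_config):
    trials, truth = simulate_dataset(small_config)
    return trials, truth


@pytest.fixture(scope="session")
def quick_settings() -> SamplerSettings:
    # deliberately light; unit tests assert structure, not convergence
    return SamplerSettings(chains=2, iterations=400, warmup=150, seed=7, min_ess=1.0, max_rhat=5.0)


@pytest.fixture(scope="session")
def small_vod_fit(small_trials, quick_settings):
    trials, _ = small_trials
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ToleranceModel(trials, response="vod").fit(quick_settings)
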