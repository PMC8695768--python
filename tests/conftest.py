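import numpy as np
import pytest

from xylokin.simulate import StandScenario, bimodal_demo_scenario, generate_study


@pytest.fixture(scope="session")
def recovery_scenario():
    """Well-specified single-pulse stand: the total count follows the
    Gompertz model exactly (no cambial additive term), Poisson noise,
    5 trees sampled weekly across the season."""
    def make(i: int = 0, **overrides) -> StandScenario:
        kw = dict(
            stand_id=f"R{i}", planting_year=2000, n_trees=5,
            A_mean=120.0, A_sd=15.0, beta=1.5, k=0.007, pulse_split=1.0,
            cambial_baseline=0.0, cambial_gain=0.0,
            noise_model="poisson", sampling_interval_days=7,
            season_start_doy=30, season_end_doy=340,
        )
        kw.update(overrides)
        return StandScenario(**kw)
    return make


@pytest.fixture(scope="session")
def demo_study():
    """One bimodal demo stand with 5 trees, fixed seed."""
    return generate_study([bimodal_demo_scenario()], seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
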