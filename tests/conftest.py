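import numpy as np
import pytest

import vagusloop as vl


@pytest.fixture
def default_cfg() -> vl.FuzzyControllerConfig:
    return vl.FuzzyControllerConfig(setpoint=300.0)


@pytest.fixture
def noiseless_params() -> vl.PlantParams:
    """A deterministic synthetic animal (no beat jitter)."""
    return vl.PlantParams(
        baseline_hr=400.0,
        max_drop=200.0,
        perturb_sensitivity=9.0,
        control_sensitivity=9.0,
        block_start_amp=1.8,
        block_sensitivity=64.3,
        time_constant=3.0,
        rr_jitter_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_trial() -> vl.TrialRecord:
    """One full closed-loop trial at the default gain, shared across tests."""
    (rng_animal,) = vl.spawn_rngs(777, 1)
    params = vl.sample_animal(rng_animal, seed=777)
    calib = vl.calibrate_plant(params, seed=778)
    return vl.run_trial(params, calib, gain=5.0, seed=779)
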