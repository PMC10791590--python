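import numpy as np
import pytest

from kelptpc import ingest, synthetic_data, tpc_models

ALL_RESPONSES = ("growth", "net_photosynthesis", "weight_change_pct", "d13c")


def noise_free_config(seed: int = 0) -> synthetic_data.ExperimentSimConfig:
    """Experiment config with zero replicate noise and no mortality."""
    return synthetic_data.ExperimentSimConfig(
        seed=seed,
        noise_sd_frac=0.0,
        noise_sd_abs={(r, c): 0.0 for r in ALL_RESPONSES for c in ("current", "future")},
        mortality_prob_at_hottest={"current": 0.0, "future": 0.0},
    )


def oneill_dataset(
    rmax=1.0, topt=16.0, ctmax=30.0, q10=2.0, noise_sd=0.0, seed=0,
    temps=synthetic_data.REALIZED_TEMPS_C, n_reps=5, response="growth",
) -> ingest.ResponseDataset:
    """(temperature, rate) dataset drawn from a known O'Neill curve."""
    rng = np.random.default_rng(seed)
    t = np.repeat(np.asarray(temps, dtype=float), n_reps)
    r = tpc_models.evaluate("oneill_1972", {"rmax": rmax, "topt": topt, "ctmax": ctmax, "q10": q10}, t)
    r = r + rng.normal(0.0, noise_sd, t.size)
    return ingest.ResponseDataset(
        response=response, co2_level="current", temps_c=t, values=r,
        individual_ids=[f"i{k}" for k in range(t.size)],
    )


@pytest.fixture(scope="session")
def clean_experiment():
    """Noise-free simulated experiment (records, blanks)."""
    return synthetic_data.simulate_experiment(noise_free_config(seed=0))


@pytest.fixture(scope="session")
def noisy_experiment():
    """Default-noise simulated experiment with mortality at the hottest bath."""
    return synthetic_data.simulate_experiment(synthetic_data.ExperimentSimConfig(seed=11))
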