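import numpy as np
import pandas as pd
import pytest

from bartstop import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.TaskConfig:
    return sd.TaskConfig(n_trials=40, seed=101, iti_s=2.0)


@pytest.fixture(scope="session")
def small_session(small_config):
    """A small but complete simulated session (trials, spikes, LFP)."""
    trials = sd.generate_trials(small_config)
    trials = sd.simulate_agent_stops(trials, sd.AgentPolicy(), small_config, seed=102)
    truth = sd.GlmTruth(beta0=np.log(12.0), beta={"trial": np.log(1.4)}, gamma=0.1)
    params = sd.NeuralGenParams(glm_truth=truth, n_channels=2, fs_hz=1000.0)
    spikes = sd.simulate_spikes(trials, params, seed=103)
    lfp = sd.simulate_lfp(trials, params, seed=104)
    return {"config": small_config, "trials": trials, "spikes": spikes, "lfp": lfp,
            "params": params}


def manual_trials(rows) -> pd.DataFrame:
    """Build a trial table from (type, risk, start, stop, pop, outcome, points)."""
    return pd.DataFrame(
        [
            {
                "trial_id": i,
                "type": r[0],
                "risk": r[1],
                "t_start_s": r[2],
                "t_stop_s": r[3],
                "t_pop_s": r[4],
                "outcome": r[5],
                "points": r[6],
            }
            for i, r in enumerate(rows)
        ]
    )
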