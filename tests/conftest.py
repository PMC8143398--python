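import numpy as np
import pandas as pd
import pytest

from psyfi.angles import rad_to_deg
from psyfi.io import Dataset
from psyfi.observer import DecoderSpec, encoder_from_params, simulate_trials


def simulate_observer_dataset(lam, omega, n, seed, decoder=None,
                              group="NT", block="woFB", pid="s01"):
    """Single synthetic observer: uniform targets, encoder-decoder responses."""
    decoder = decoder or DecoderSpec(kind="posterior_mean")
    enc = encoder_from_params(lam, omega)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, np.pi, size=n)
    resp = simulate_trials(enc, decoder, theta, rng)
    return Dataset(pd.DataFrame({
        "participant_id": pid, "group": group, "block": block,
        "trial_index": np.arange(n),
        "target_deg": rad_to_deg(theta),
        "response_deg": rad_to_deg(resp),
        "rt_s": np.nan,
    }))


@pytest.fixture(scope="session")
def anisotropic_dataset():
    """One mid-capacity anisotropic observer, reused across tests."""
    return simulate_observer_dataset(14.7, 0.5, 20000, seed=1234)


@pytest.fixture()
def tiny_trials_csv(tmp_path):
    path = tmp_path / "trials.csv"
    path.write_text(
        "participant_id,group,block,trial_index,target_deg,response_deg,rt_s\n"
        "p01,NT,woFB,0,181.0,-5.0,1.2\n"
        "p01,NT,woFB,1,30.0,35.5,0.9\n"
        "p02,ASD,wFB2,0,90.0,88.0,\n")
    return path
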