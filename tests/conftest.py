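import numpy as np
import pandas as pd
import pytest

from hierseq.config import fixture_small
from hierseq.tfr import TFRGrid, TFRSet


@pytest.fixture(scope="session")
def fixture_rec():
    """Deterministic miniature 8-channel recording."""
    return fixture_small()


def make_grid(freqs=None, times=None):
    if freqs is None:
        freqs = np.arange(10.0, 101.0, 5.0)
    if times is None:
        times = np.arange(-0.3, 1.61, 0.02)
    return TFRGrid(np.asarray(freqs, float), np.asarray(times, float))


def make_tfrset(power, grid=None, condition="toy", role="standard"):
    """Wrap a trials x channels x freqs x times array as a TFRSet."""
    power = np.asarray(power, dtype=np.float32)
    if grid is None:
        grid = make_grid(
            freqs=np.arange(power.shape[2]) * 5.0 + 10.0,
            times=np.arange(power.shape[3]) * 0.02,
        )
    n_trials, n_ch = power.shape[:2]
    if np.isscalar(condition):
        condition = [condition] * n_trials
    if np.isscalar(role):
        role = [role] * n_trials
    meta = pd.DataFrame(
        {"trial_index": np.arange(n_trials), "onset": np.zeros(n_trials),
         "condition": condition, "role": role, "block": 0}
    )
    chans = pd.DataFrame(
        {"name": [f"ch{i:03d}" for i in range(n_ch)], "roi": ["other"] * n_ch}
    )
    return TFRSet(power, grid, meta, chans)
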