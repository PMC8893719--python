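import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from hierseq.preprocess import TrialSet
from hierseq.tfr import TFRGrid, baseline_correct, dpss_taper_count, tfr_multitaper

from conftest import make_tfrset


def _trialset(data, fs=500.0, window=(-1.0, 2.0)):
    data = np.asarray(data, dtype=float)
    n_trials, n_ch = data.shape[:2]
    meta = pd.DataFrame(
        {"trial_index": np.arange(n_trials), "onset": np.zeros(n_trials),
         "condition": "toy", "role": "standard", "block": 0}
    )
    chans = pd.DataFrame({"name": [f"ch{i}" for i in range(n_ch)],
                          "roi": ["other"] * n_ch})
    return TrialSet(data=data, fs=fs, window_s=window, trial_meta=meta,
                    channel_meta=chans)


def test_taper_count_is_three_under_stated_smoothing():
    for f in np.arange(10.0, 141.0):
        assert dpss_taper_count(4.0 / f, 0.5 * f) == 3


def test_taper_count_edge_cases():
    assert dpss_taper_count(1.0, 1.0) == 1
    with pytest.warns(UserWarning, match="clamping"):
        assert dpss_taper_count(0.1, 1.0) == 1


def test_pure_tone_peaks_within_its_smoothing_band():
    """A pure 40 Hz tone dominates the spectrum around 40 Hz.  Proportional
    smoothing (half-bandwidth 0.5*f) accepts the tone from f ~ 2/3 * f0
    upward, so under density normalization the argmax may sit anywhere in
    that acceptance band but the response must vanish above it."""
    fs = 500.0
    t = np.arange(int(3 * fs)) / fs
    x = np.sin(2 * np.pi * 40 * t)
    grid = TFRGrid(np.arange(10.0, 101.0, 2.0), np.arange(-0.5, 1.51, 0.02))
    out = tfr_multitaper(_trialset(x[None, None, :]), grid)
    profile = np.nanmean(out.power[0, 0], axis=-1)
    peak_f = grid.freqs_hz[np.nanargmax(profile)]
    assert 40.0 * 2 / 3 - 2.0 <= peak_f <= 42.0
    # energy at the tone frequency towers over out-of-band frequencies
    fi40 = np.argmin(np.abs(grid.freqs_hz - 40))
    assert profile[fi40] > 50 * profile[np.argmin(np.abs(grid.freqs_hz - 90))]


def test_power_scales_quadratically_with_amplitude():
    fs = 500.0
    rng = np.random.default_rng(0)
    x = rng.standard_normal(int(3 * fs))
    grid = TFRGrid(np.arange(20.0, 81.0, 10.0), np.arange(-0.4, 1.41, 0.02))
    p1 = tfr_multitaper(_trialset(x[None, None, :]), grid).power
    p2 = tfr_multitaper(_trialset(2 * x[None, None, :]), grid).power
    valid = np.isfinite(p1)
    np.testing.assert_allclose(p2[valid], 4 * p1[valid], rtol=1e-5)


def test_white_noise_spectrum_is_flat():
    fs = 500.0
    rng = np.random.default_rng(1)
    x = rng.standard_normal((200, 1, int(2 * fs)))
    grid = TFRGrid(np.arange(30.0, 121.0, 10.0), np.arange(-0.2, 0.81, 0.05))
    out = tfr_multitaper(_trialset(x, window=(-0.8, 1.2)), grid)
    per_trial = np.nanmean(out.power[:, 0], axis=-1)  # trials x freqs
    mean = per_trial.mean(axis=0)
    se = per_trial.std(axis=0) / np.sqrt(per_trial.shape[0])
    grand = mean.mean()
    assert np.all(np.abs(mean - grand) < 3 * (se + 1e-12))


def test_edge_cells_are_missing_not_extrapolated():
    fs = 500.0
    x = np.random.default_rng(2).standard_normal((1, 1, int(1.5 * fs)))
    # 10 Hz window is 0.4 s: grid times close to the epoch edge are invalid
    grid = TFRGrid(np.array([10.0, 80.0]), np.arange(-0.45, 0.96, 0.02))
    out = tfr_multitaper(_trialset(x, window=(-0.5, 1.0)), grid)
    low = out.power[0, 0, 0]
    high = out.power[0, 0, 1]
    assert np.isnan(low[0]) and np.isfinite(low[len(low) // 2])
    # the 80 Hz window (50 ms) is valid closer to the edge than the 10 Hz one
    assert np.sum(np.isnan(high)) < np.sum(np.isnan(low))


def test_frequency_above_nyquist_rejected():
    x = np.zeros((1, 1, 1000))
    grid = TFRGrid(np.array([100.0, 260.0]), np.arange(0.0, 1.0, 0.02))
    with pytest.raises(ValueError, match="Nyquist"):
        tfr_multitaper(_trialset(x), grid)


def test_baseline_correction_modes():
    power = np.ones((1, 1, 2, 40), dtype=np.float32)
    power[..., 20:] = 2.0  # power doubles after t=0.4
    tfr = make_tfrset(power)
    rel = baseline_correct(tfr, window=(0.0, 0.38), mode="relchange")
    np.testing.assert_allclose(rel.power[..., :20], 0.0, atol=1e-6)
    np.testing.assert_allclose(rel.power[..., 20:], 1.0, atol=1e-6)
    db = baseline_correct(tfr, window=(0.0, 0.38), mode="db")
    np.testing.assert_allclose(
        db.power, 10 * np.log10(rel.power + 1.0), atol=1e-5
    )
    with pytest.raises(ValueError, match="no grid time"):
        baseline_correct(tfr, window=(-5.0, -4.0))


def test_band_limited_probe_satisfies_parseval_within_10pct():
    """Frequency-integrated spectral density of a stationary band-limited
    probe matches its variance."""
    fs = 500.0
    rng = np.random.default_rng(3)
    sos = sps.butter(6, [30, 60], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(int(20 * fs)))
    n = int(3 * fs)
    trials = np.stack([x[i * n:(i + 1) * n] for i in range(6)])[:, None, :]
    grid = TFRGrid(np.arange(10.0, 101.0, 1.0), np.arange(-0.4, 1.41, 0.02))
    out = tfr_multitaper(_trialset(trials), grid)
    density = np.nanmean(out.power, axis=(0, 1, 3))  # mean over trials, time
    integrated = np.trapezoid(density, grid.freqs_hz)
    assert integrated == pytest.approx(np.var(x), rel=0.10)


@pytest.mark.parametrize("t0", [0.7, 0.9, 1.1])
def test_burst_peak_time_is_unbiased(t0):
    """A 70 Hz Gaussian burst at t0 peaks within one 20 ms grid step."""
    fs = 500.0
    t = np.arange(int(3 * fs)) / fs - 1.0
    env = np.exp(-0.5 * ((t - t0) / 0.03) ** 2)
    x = env * np.sin(2 * np.pi * 70 * (t - t0))
    grid = TFRGrid(np.arange(40.0, 101.0, 2.0), np.arange(-0.3, 1.61, 0.02))
    out = tfr_multitaper(_trialset(x[None, None, :]), grid)
    fi = np.argmin(np.abs(grid.freqs_hz - 70))
    trace = out.power[0, 0, fi]
    peak_t = grid.times_s[np.nanargmax(trace)]
    assert abs(peak_t - t0) <= 0.02 + 1e-9


def test_matches_mne_multitaper_peak_location():
    """Independent oracle: the same burst analyzed by MNE's multitaper
    (4 cycles, time-bandwidth 4 => 3 tapers) peaks at the same cell."""
    mne = pytest.importorskip("mne")
    fs = 500.0
    t = np.arange(int(3 * fs)) / fs - 1.0
    env = np.exp(-0.5 * ((t - 0.8) / 0.04) ** 2)
    x = (env * np.sin(2 * np.pi * 60 * (t - 0.8)))[None, None, :]
    freqs = np.arange(30.0, 101.0, 5.0)
    grid = TFRGrid(freqs, np.arange(-0.3, 1.61, 0.02))
    mine = tfr_multitaper(_trialset(x), grid).power[0, 0]
    theirs = mne.time_frequency.tfr_array_multitaper(
        x, sfreq=fs, freqs=freqs, n_cycles=4.0, time_bandwidth=4.0,
        output="power", verbose=False,
    )[0, 0]
    f_mine, t_mine = np.unravel_index(np.nanargmax(mine), mine.shape)
    idx = np.round((grid.times_s + 1.0) * fs).astype(int)
    theirs_on_grid = theirs[:, idx]
    f_mne, t_mne = np.unravel_index(np.nanargmax(theirs_on_grid),
                                    theirs_on_grid.shape)
    assert f_mine == f_mne
    assert abs(grid.times_s[t_mine] - grid.times_s[t_mne]) <= 0.04
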