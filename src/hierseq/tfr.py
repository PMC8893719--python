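"""Multitaper time-frequency decomposition on a fixed analysis grid.

Power at each (frequency, time) cell is the mean over DPSS tapers of the
squared magnitude of the tapered complex demodulate: the epoch segment
centered on the grid time, of length ``window_cycles / f`` seconds, is
multiplied by each unit-energy taper and correlated with a complex
exponential at f.  With a 4-cycle window and spectral half-bandwidth
0.5*f, the taper count ``floor(2*T*W) - 1`` equals 3 at every frequency —
the only reading under which the two stated smoothing parameters cohere.

Grid cells whose analysis window would extend past the epoch are set to
NaN (missing), never extrapolated, and are excluded from all downstream
statistics.  Raw power is scaled as one-sided spectral density (so
band-integrated power matches signal variance); baseline correction
divides it out anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import windows

from .preprocess import TrialSet

__all__ = [
    "TFRGrid",
    "TFRSet",
    "dpss_taper_count",
    "tfr_multitaper",
    "baseline_correct",
    "concat_tfrsets",
]


@dataclass(frozen=True)
class TFRGrid:
    freqs_hz: np.ndarray
    times_s: np.ndarray  # relative to first-tone onset
    window_cycles: float = 4.0
    smoothing_factor: float = 0.5  # half-bandwidth = factor * f

    def __post_init__(self):
        f = np.asarray(self.freqs_hz, dtype=float)
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "times_s", t)
        if f.size < 1 or np.any(np.diff(f) <= 0):
            raise ValueError("freqs_hz must be non-empty and ascending")
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times_s must be non-empty and ascending")
        if t.size > 2 and not np.allclose(np.diff(t), t[1] - t[0], atol=1e-9):
            raise ValueError("times_s must be uniform")

    @classmethod
    def default(
        cls,
        fifth_tone_onset_s: float = 0.8,
        fmin: float = 10.0,
        fmax: float = 140.0,
        fstep: float = 1.0,
        tmin: float = -0.3,
        tstep: float = 0.02,
        post_fifth_s: float = 0.8,
        window_cycles: float = 4.0,
        smoothing_factor: float = 0.5,
    ) -> "TFRGrid":
        freqs = np.arange(fmin, fmax + fstep / 2, fstep)
        tmax = fifth_tone_onset_s + post_fifth_s
        times = np.arange(tmin, tmax + tstep / 2, tstep)
        return cls(freqs, times, window_cycles, smoothing_factor)

    def window_s(self, f: float) -> float:
        """Analysis window length at frequency f (seconds)."""
        return self.window_cycles / f

    @property
    def tstep(self) -> float:
        return float(self.times_s[1] - self.times_s[0]) if self.times_s.size > 1 else np.nan


def dpss_taper_count(window_s: float, half_bandwidth_hz: float) -> int:
    """Number of DPSS tapers for a window/half-bandwidth pair:
    floor(2*T*W) - 1, floored at 1 (with a warning for degenerate products)."""
    # epsilon guards products that are integral up to float error
    k = int(np.floor(2.0 * window_s * half_bandwidth_hz + 1e-9)) - 1
    if k < 1:
        warnings.warn(
            f"time-bandwidth product 2*T*W = {2*window_s*half_bandwidth_hz:.3f} "
            "yields no taper; clamping to 1"
        )
        return 1
    return k


@dataclass
class TFRSet:
    """Power on the grid: trials x channels x freqs x times (float32).

    ``baseline_window_s`` is None for raw power; after baseline correction
    values are dimensionless relative change (or dB)."""

    power: np.ndarray
    grid: TFRGrid
    trial_meta: pd.DataFrame
    channel_meta: pd.DataFrame
    baseline_window_s: tuple[float, float] | None = None
    baseline_mode: str | None = None

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    @property
    def n_channels(self) -> int:
        return self.power.shape[1]

    def select(self, condition=None, role=None, task=None) -> "TFRSet":
        """Subset trials by condition/role/task metadata."""
        mask = np.ones(self.n_trials, dtype=bool)
        meta = self.trial_meta
        if condition is not None:
            conds = [condition] if isinstance(condition, str) else list(condition)
            mask &= meta["condition"].isin(conds).to_numpy()
        if role is not None:
            roles = [role] if isinstance(role, str) else list(role)
            mask &= meta["role"].isin(roles).to_numpy()
        if task is not None:
            if "task" not in meta.columns:
                raise KeyError("trial_meta has no 'task' column")
            mask &= (meta["task"] == task).to_numpy()
        return TFRSet(
            self.power[mask], self.grid, meta.loc[mask].reset_index(drop=True),
            self.channel_meta.copy(), self.baseline_window_s, self.baseline_mode,
        )


def tfr_multitaper(ts: TrialSet, grid: TFRGrid) -> TFRSet:
    """Raw multitaper power of every trial/channel on the grid."""
    fs = ts.fs
    nyq = fs / 2.0
    if np.any(grid.freqs_hz >= nyq):
        raise ValueError(
            f"grid frequencies reach Nyquist ({nyq} Hz) at fs={fs}"
        )
    n_trials, n_ch, n_samp = ts.data.shape
    t0 = ts.window_s[0]
    X = ts.data.reshape(n_trials * n_ch, n_samp)
    out = np.full((n_trials * n_ch, grid.freqs_hz.size, grid.times_s.size),
                  np.nan, dtype=np.float32)

    centers = np.round((grid.times_s - t0) * fs).astype(int)
    for fi, f in enumerate(grid.freqs_hz):
        win_s = grid.window_s(f)
        half_bw = grid.smoothing_factor * f
        L = int(round(win_s * fs))
        L = max(L, 4)
        k = dpss_taper_count(win_s, half_bw)
        nw = max(win_s * half_bw, 0.55)  # taper concentration T*W
        tapers = windows.dpss(L, nw, Kmax=k)
        tapers = np.atleast_2d(tapers)
        tapers = tapers / np.sqrt(np.sum(tapers**2, axis=1, keepdims=True))
        n_loc = np.arange(L) - (L - 1) / 2.0
        carrier = np.exp(-2j * np.pi * f * n_loc / fs)
        kernels = (tapers * carrier[None, :]).T  # L x k

        starts = centers - L // 2
        valid = (starts >= 0) & (starts + L <= n_samp)
        if not np.any(valid):
            continue
        sv = starts[valid]
        idx = sv[:, None] + np.arange(L)[None, :]
        seg = X[:, idx]  # (NT, n_valid, L)
        demod = seg @ kernels  # complex (NT, n_valid, k)
        power = (2.0 / fs) * np.mean(np.abs(demod) ** 2, axis=-1)
        out[:, fi, valid] = power.astype(np.float32)

    power = out.reshape(n_trials, n_ch, grid.freqs_hz.size, grid.times_s.size)
    return TFRSet(power, grid, ts.trial_meta.copy(), ts.channel_meta.copy())


def baseline_correct(
    tfrset: TFRSet,
    window=(-0.3, 0.0),
    mode: str = "relchange",
) -> TFRSet:
    """Per trial/channel/frequency baseline correction.

    ``relchange``: (power - mean_baseline) / mean_baseline;
    ``db``: 10*log10(power / mean_baseline).  The baseline mean is taken
    over valid (non-missing) baseline time points only."""
    if mode not in ("relchange", "db"):
        raise ValueError("mode must be 'relchange' or 'db'")
    t = tfrset.grid.times_s
    sel = (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise ValueError(f"baseline window {window} contains no grid time")
    base = tfrset.power[..., sel]
    if np.all(np.isnan(base)):
        raise ValueError("baseline window contains only missing cells")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(base, axis=-1, keepdims=True)
    if mode == "relchange":
        corrected = tfrset.power / m - 1.0
    else:
        corrected = 10.0 * np.log10(tfrset.power / m)
    return TFRSet(
        corrected.astype(np.float32), tfrset.grid, tfrset.trial_meta.copy(),
        tfrset.channel_meta.copy(), (float(window[0]), float(window[1])), mode,
    )


def concat_tfrsets(tfrsets: list[TFRSet]) -> TFRSet:
    """Stack trials from several TFR sets sharing one grid and channel set."""
    first = tfrsets[0]
    for other in tfrsets[1:]:
        if not (
            np.array_equal(other.grid.freqs_hz, first.grid.freqs_hz)
            and np.array_equal(other.grid.times_s, first.grid.times_s)
        ):
            raise ValueError("TFR grids differ; cannot concatenate")
        if other.power.shape[1] != first.power.shape[1]:
            raise ValueError("channel counts differ; cannot concatenate")
    power = np.concatenate([t.power for t in tfrsets], axis=0)
    meta = pd.concat([t.trial_meta for t in tfrsets], ignore_index=True)
    return TFRSet(power, first.grid, meta, first.channel_meta.copy(),
                  first.baseline_window_s, first.baseline_mode)
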