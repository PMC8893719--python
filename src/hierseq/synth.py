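"""Ground-truthed synthetic multichannel ECoG generator.

Emulates the statistical structure the analysis pipeline assumes: 96-channel
recordings at 1 kHz containing per-channel 1/f background, optional 50 Hz
line contamination, and condition-locked oscillatory components tied to a
ground-truth table:

* ``PE1`` — early gamma burst (first-level, tone-to-tone prediction error),
* ``PE2`` — late gamma burst (second-level, sequence prediction error),
* ``PRED`` — long-lasting beta (12-30 Hz) power *decrease* (top-down
  prediction update), realized as multiplicative suppression of the ongoing
  band-limited background so power stays nonnegative.

Gamma bursts are band-limited Gaussian noise carriers under a Gaussian
amplitude envelope (a pure sinusoid would ring in the TFR and bias latency
estimates).  The same carrier is shared across a component's target
channels (scaled by fixed per-channel gains), giving the rank-1
channel x frequency x time structure that the PARAFAC stage recovers.

Trial-to-trial amplitude couplings: within a deviant trial the PE2
amplitude can follow PE1 (``pe1_to_pe2_gain``); the PRED amplitude on a
deviant can drive PE1/PE2 amplitudes on the *immediately following standard
trial in the same block* (``pred_to_next_*_gain``), mirroring the
deviant -> post-deviant pairing rule used by the correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .fileio import SchemaError, table_from_group, table_to_group, require_columns
from .paradigm import EVENT_COLUMNS, RunSpec, events_table

__all__ = [
    "ROIS",
    "ElectrodeLayout",
    "ComponentSpec",
    "CouplingSpec",
    "SyntheticRecording",
    "default_layout",
    "default_components",
    "omission_component",
    "simulate_background",
    "inject_components",
    "write_recording",
    "read_recording",
]

ROIS = ("frontal", "auditory_core", "auditory_belt_parabelt", "STR", "other")

#: region-of-interest counts for the default 96-channel array
DEFAULT_ROI_COUNTS = {
    "auditory_core": 12,
    "auditory_belt_parabelt": 16,
    "STR": 8,
    "frontal": 24,
    "other": 36,
}

GROUND_TRUTH_COLUMNS = [
    "trial_index",
    "condition",
    "role",
    "component",
    "amplitude",
    "latency_center_s",
    "envelope_start_s",
]


@dataclass(frozen=True)
class ElectrodeLayout:
    labels: tuple[str, ...]
    roi: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.roi):
            raise ValueError("labels and roi must have equal length")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 channels")
        bad = set(self.roi) - set(ROIS)
        if bad:
            raise ValueError(f"unknown ROI label(s) {bad}; valid: {ROIS}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def channels_in(self, rois) -> np.ndarray:
        rois = {rois} if isinstance(rois, str) else set(rois)
        return np.array([i for i, r in enumerate(self.roi) if r in rois], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.labels, "roi": self.roi})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ElectrodeLayout":
        require_columns(df, ["name", "roi"], "channel table")
        return cls(tuple(str(x) for x in df["name"]), tuple(str(x) for x in df["roi"]))


def default_layout(roi_counts: dict | None = None) -> ElectrodeLayout:
    """Electrode layout partitioned into ROIs (default: the 96-channel
    whole-hemisphere array split 12/16/8/24/36)."""
    counts = dict(DEFAULT_ROI_COUNTS if roi_counts is None else roi_counts)
    labels, rois = [], []
    i = 0
    for roi in ROIS:
        for _ in range(int(counts.get(roi, 0))):
            labels.append(f"ch{i:03d}")
            rois.append(roi)
            i += 1
    return ElectrodeLayout(tuple(labels), tuple(rois))


@dataclass(frozen=True)
class ComponentSpec:
    """One injectable condition-locked component.

    ``latency_mean_s`` is measured from the onset of the fifth tone (the
    omitted-tone onset for omission sequences).  ``latency_anchor`` selects
    whether that latency is the Gaussian envelope *center* (natural for a
    peak-latency target) or the envelope *start* (center - duration/2;
    natural for an onset-latency target).
    """

    name: str
    band_hz: tuple[float, float]
    latency_mean_s: float
    latency_sd_s: float
    envelope_duration_s: float
    amplitude_mean: float  # power units for bursts; suppression depth (0..1) for decreases
    amplitude_sd: float
    sign: str = "increase"  # increase | decrease
    latency_anchor: str = "center"  # center | start
    envelope_shape: str = "gaussian"  # gaussian | ramp
    target_rois: tuple[str, ...] = ("auditory_core",)
    active_conditions: tuple[str, ...] = ()
    channel_gain_range: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self):
        if self.sign not in ("increase", "decrease"):
            raise ValueError("sign must be 'increase' or 'decrease'")
        if self.latency_anchor not in ("center", "start"):
            raise ValueError("latency_anchor must be 'center' or 'start'")
        if self.envelope_shape not in ("gaussian", "ramp"):
            raise ValueError("envelope_shape must be 'gaussian' or 'ramp'")
        if self.band_hz[0] >= self.band_hz[1]:
            raise ValueError("band_hz must be (low, high) with low < high")

    def center_latency(self, realized: float) -> float:
        if self.latency_anchor == "start":
            return realized + self.envelope_duration_s / 2
        return realized


@dataclass(frozen=True)
class CouplingSpec:
    pe1_to_pe2_gain: float = 0.0
    pred_to_next_pe1_gain: float = 0.0
    pred_to_next_pe2_gain: float = 0.0
    noise_sd: float = 0.02

    def __post_init__(self):
        for g in (self.pe1_to_pe2_gain, self.pred_to_next_pe1_gain,
                  self.pred_to_next_pe2_gain, self.noise_sd):
            if not np.isfinite(g):
                raise ValueError("coupling gains and noise_sd must be finite")


def default_components() -> list[ComponentSpec]:
    """Component set emulating the reported responses: PE1 gamma burst
    peaking 74 ms after the fifth tone on any xY sequence, PE2 gamma burst
    peaking 242 ms after the fifth tone on global deviants, and a
    long-lasting beta suppression on global deviants."""
    return [
        ComponentSpec(
            name="PE1", band_hz=(60.0, 110.0), latency_mean_s=0.074,
            latency_sd_s=0.010, envelope_duration_s=0.10,
            amplitude_mean=0.0625, amplitude_sd=0.04,
            target_rois=("auditory_core", "auditory_belt_parabelt"),
            active_conditions=("xY|xx", "xY|xY"),
        ),
        ComponentSpec(
            name="PE2", band_hz=(60.0, 110.0), latency_mean_s=0.242,
            latency_sd_s=0.010, envelope_duration_s=0.12,
            amplitude_mean=0.0625, amplitude_sd=0.04,
            target_rois=("auditory_belt_parabelt", "STR"),
            active_conditions=("xY|xx", "xx|xY"),
        ),
        ComponentSpec(
            name="PRED", band_hz=(12.0, 30.0), latency_mean_s=0.15,
            latency_sd_s=0.020, envelope_duration_s=0.45,
            amplitude_mean=0.7, amplitude_sd=0.2, sign="decrease",
            latency_anchor="start",
            target_rois=("frontal", "auditory_belt_parabelt"),
            active_conditions=("xY|xx", "xx|xY"),
        ),
    ]


def omission_component(onset_s: float = 0.048) -> ComponentSpec:
    """Gamma response to an unexpected omission in the xY task, anchored at
    its envelope start (the onset-latency recovery target)."""
    return ComponentSpec(
        name="PE1", band_hz=(60.0, 110.0), latency_mean_s=onset_s,
        latency_sd_s=0.0, envelope_duration_s=0.18, latency_anchor="start",
        envelope_shape="ramp",
        amplitude_mean=0.0625, amplitude_sd=0.04,
        target_rois=("auditory_core", "auditory_belt_parabelt"),
        active_conditions=("x_|xY",),
    )


@dataclass
class SyntheticRecording:
    signal: np.ndarray  # channels x samples
    fs: float
    events: pd.DataFrame
    layout: ElectrodeLayout
    ground_truth: pd.DataFrame
    seed: int | None = None

    def __post_init__(self):
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.signal.shape[0] != self.layout.n_channels:
            raise ValueError("signal rows must match layout channel count")

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs


def simulate_background(
    layout: ElectrodeLayout | int,
    duration_s: float,
    fs: float,
    exponent: float = 1.5,
    line_hz: float | None = None,
    line_amplitude: float = 0.0,
    rms: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Per-channel 1/f**exponent background via spectral shaping of white
    noise, plus an optional line-noise sinusoid.  Each channel is scaled to
    the requested RMS; deterministic under ``seed``."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n_ch = layout if isinstance(layout, int) else layout.n_channels
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape[None, :], n=n, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    x *= rms / std
    if line_hz is not None and line_amplitude > 0:
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        x += line_amplitude * np.sin(2 * np.pi * line_hz * t[None, :] + phases[:, None])
    return x


def _bandpass_sos(band, fs, order=4):
    nyq = fs / 2.0
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.99)
    return sps.butter(order, [lo, hi], btype="bandpass", output="sos")


def _gamma_burst(rng, fs, band, duration_s, shape="gaussian"):
    """Unit-RMS band-limited noise carrier under an amplitude envelope,
    returned with the sample offset of the envelope center.

    ``gaussian``: sigma = duration/4 (``duration`` spans +-2 sigma); the
    natural choice when the recovery target is the envelope *center*.
    ``ramp``: Tukey plateau that is exactly zero before the envelope start
    (cosine attack over 30% of the duration); the natural choice when the
    recovery target is the response *onset*."""
    if shape == "gaussian":
        sigma = duration_s / 4.0
        half = int(round(2.5 * sigma * fs))
        n = 2 * half + 1
        t = (np.arange(n) - half) / fs
        env = np.exp(-0.5 * (t / sigma) ** 2)
    elif shape == "ramp":
        n = max(int(round(duration_s * fs)), 8)
        env = sps.windows.tukey(n, alpha=0.6)
        half = n // 2
    else:
        raise ValueError(f"unknown envelope shape {shape!r}")
    pad = int(round(0.1 * fs))
    carrier = rng.standard_normal(n + 2 * pad)
    carrier = sps.sosfiltfilt(_bandpass_sos(band, fs), carrier)[pad:pad + n]
    burst = carrier * env
    # exact energy normalization: the realized burst energy tracks the
    # ground-truth amplitude instead of the carrier's chance energy
    r = np.sqrt(np.mean(burst**2))
    if r > 0:
        burst *= np.sqrt(np.mean(env**2)) / r
    return burst, half


def _pred_envelope(fs, duration_s):
    """Smooth plateau (Tukey) envelope for the long-lasting suppression."""
    n = max(int(round(duration_s * fs)), 8)
    return sps.windows.tukey(n, alpha=0.4)


def inject_components(
    signal: np.ndarray,
    run: RunSpec,
    components: list[ComponentSpec],
    coupling: CouplingSpec | None = None,
    fs: float = 1000.0,
    layout: ElectrodeLayout | None = None,
    seed: int | None = None,
) -> SyntheticRecording:
    """Add condition-locked components to a background signal.

    Returns a :class:`SyntheticRecording` whose ground-truth table records,
    per trial and active component, the realized amplitude, envelope-center
    latency and envelope-start latency (seconds after fifth-tone onset).
    """
    if layout is None:
        layout = default_layout()
    coupling = coupling or CouplingSpec()
    nyq = fs / 2.0
    for c in components:
        if c.band_hz[1] >= nyq:
            raise ValueError(
                f"component {c.name} band {c.band_hz} reaches Nyquist ({nyq} Hz)"
            )
    out = np.array(signal, dtype=float, copy=True)
    n_samp = out.shape[1]
    events = events_table(run)
    cfg = run.config
    fifth = cfg.fifth_tone_onset_s

    ss = np.random.SeedSequence(seed)
    amp_rng, lat_rng, carrier_rng, gain_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    comps = {c.name: c for c in components}
    # fixed per-channel gains (drawn once; give the spatial loading structure)
    chan_gain = {}
    for c in components:
        idx = layout.channels_in(c.target_rois)
        if idx.size == 0:
            raise ValueError(f"component {c.name}: no channels in ROIs {c.target_rois}")
        lo, hi = c.channel_gain_range
        chan_gain[c.name] = (idx, gain_rng.uniform(lo, hi, size=idx.size))

    # pre-filtered beta-band background per decrease component (for
    # multiplicative suppression)
    band_content = {}
    for c in components:
        if c.sign == "decrease":
            idx, _ = chan_gain[c.name]
            band_content[c.name] = sps.sosfiltfilt(
                _bandpass_sos(c.band_hz, fs), out[idx], axis=1
            )

    # ---- first pass: realized amplitudes/latencies per trial ----
    trials = run.trials
    gt_rows = []
    plan = []  # (trial, component, amplitude, center_latency)
    prev_deviant_amps: dict[str, float] | None = None  # PRED etc. of previous trial
    prev_block = None
    n_hab = len(run.habituation)
    for ti, trial in enumerate(trials):
        block_id = -1 if ti < n_hab else (ti - n_hab) // cfg.block_size
        this_amps: dict[str, float] = {}
        active = [c for c in components if trial.condition in c.active_conditions]
        # deterministic consumption of rng streams regardless of activity:
        for c in components:
            a_draw = amp_rng.normal(0.0, 1.0)
            n_draw = amp_rng.normal(0.0, 1.0)
            l_draw = lat_rng.normal(0.0, 1.0)
            if c not in active:
                continue
            if (
                c.name == "PE2"
                and "PE1" in this_amps
                and coupling.pe1_to_pe2_gain != 0.0
            ):
                pe1 = comps["PE1"]
                amp = (
                    c.amplitude_mean
                    + coupling.pe1_to_pe2_gain * (this_amps["PE1"] - pe1.amplitude_mean)
                    + coupling.noise_sd * n_draw
                )
            else:
                amp = c.amplitude_mean + c.amplitude_sd * a_draw
            lat = c.latency_mean_s + c.latency_sd_s * l_draw
            center = c.center_latency(lat)
            if c.sign == "decrease":
                amp = float(np.clip(amp, 0.0, 0.95))
            else:
                amp = float(max(amp, 0.0))
            this_amps[c.name] = amp
            plan.append((ti, trial, c, amp, center))
            gt_rows.append(
                (ti, trial.condition, trial.role, c.name, amp, center,
                 center - c.envelope_duration_s / 2)
            )
        # across-trial coupling: PRED on the previous (deviant) trial drives
        # PE bursts on this trial iff it is the immediately following
        # standard in the same block and the gain is set.
        if (
            prev_deviant_amps is not None
            and trial.role == "standard"
            and block_id == prev_block
            and "PRED" in prev_deviant_amps
        ):
            pred = comps.get("PRED")
            for pe_name, gain in (
                ("PE1", coupling.pred_to_next_pe1_gain),
                ("PE2", coupling.pred_to_next_pe2_gain),
            ):
                if gain == 0.0 or pe_name not in comps:
                    continue
                c = comps[pe_name]
                amp = (
                    c.amplitude_mean
                    + gain * (prev_deviant_amps["PRED"] - pred.amplitude_mean)
                    + coupling.noise_sd * amp_rng.normal()
                )
                amp = float(max(amp, 0.0))
                lat = c.latency_mean_s + c.latency_sd_s * lat_rng.normal()
                center = c.center_latency(lat)
                plan.append((ti, trial, c, amp, center))
                gt_rows.append(
                    (ti, trial.condition, trial.role, c.name, amp, center,
                     center - c.envelope_duration_s / 2)
                )
        prev_deviant_amps = this_amps if trial.role == "deviant" else None
        prev_block = block_id

    # ---- second pass: synthesis ----
    for ti, trial, c, amp, center in plan:
        idx, gains = chan_gain[c.name]
        t_center = trial.sequence_onset_s + fifth + center
        if c.sign == "increase":
            burst, half = _gamma_burst(carrier_rng, fs, c.band_hz,
                                       c.envelope_duration_s, c.envelope_shape)
            c0 = int(round(t_center * fs))
            lo, hi = c0 - half, c0 - half + burst.size
            blo, bhi = max(lo, 0), min(hi, n_samp)
            if bhi <= blo:
                continue
            seg = burst[blo - lo: bhi - lo]
            out[idx, blo:bhi] += np.sqrt(amp) * gains[:, None] * seg[None, :]
        else:
            env = _pred_envelope(fs, c.envelope_duration_s)
            n_env = env.size
            s0 = int(round((t_center - c.envelope_duration_s / 2) * fs))
            lo, hi = s0, s0 + n_env
            blo, bhi = max(lo, 0), min(hi, n_samp)
            if bhi <= blo:
                continue
            seg_env = env[blo - lo: bhi - lo]
            depth = np.clip(amp * gains, 0.0, 0.98)
            bc = band_content[c.name][:, blo:bhi]
            out[idx, blo:bhi] -= depth[:, None] * seg_env[None, :] * bc

    gt = pd.DataFrame(gt_rows, columns=GROUND_TRUTH_COLUMNS)
    return SyntheticRecording(out, fs, events, layout, gt, seed=seed)


# ---------------------------------------------------------------------------
# hierarchical container I/O
# ---------------------------------------------------------------------------

def write_recording(rec: SyntheticRecording, path) -> None:
    """Lossless HDF5 container: /signal, /events, /channels, /ground_truth;
    fs and seed as root attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.attrs["fs"] = rec.fs
        f.attrs["seed"] = -1 if rec.seed is None else rec.seed
        table_to_group(rec.events, f.create_group("events"))
        table_to_group(rec.layout.to_frame(), f.create_group("channels"))
        table_to_group(rec.ground_truth, f.create_group("ground_truth"))


def read_recording(path) -> SyntheticRecording:
    with h5py.File(path, "r") as f:
        for group in ("signal", "events", "channels"):
            if group not in f:
                raise SchemaError(f"recording file is missing /{group}")
        signal = f["signal"][()]
        fs = float(f.attrs["fs"])
        seed = int(f.attrs.get("seed", -1))
        events = table_from_group(f["events"])
        require_columns(events, EVENT_COLUMNS, "events table")
        layout = ElectrodeLayout.from_frame(table_from_group(f["channels"]))
        if "ground_truth" in f:
            gt = table_from_group(f["ground_truth"])
        else:
            warnings.warn("recording has no /ground_truth group; loading empty table")
            gt = pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
    return SyntheticRecording(signal, fs, events, layout, gt,
                              seed=None if seed < 0 else seed)
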