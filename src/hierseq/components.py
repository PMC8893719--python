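"""Component classification, rank-1 spatio-spectro-temporal patterns, and
per-trial contributions.

Significant clusters are labelled PE1 / PE2 / PRED by band, sign and
latency: PE1 and PE2 are positive gamma clusters (band minimum >= 40 Hz)
split at 0.15 s after the fifth tone (between the reported 74 ms and
242 ms peaks); PRED is a negative cluster overlapping 12-30 Hz lasting at
least 0.3 s.  Each component's channel x frequency x time window (the
union bounding box of its clusters) frames a 3-way tensor of trial-averaged
baseline-corrected power, which a rank-1 PARAFAC (alternating least
squares, multiple seeded restarts) factorizes into unit-norm electrode,
frequency and time loadings.  A trial's contribution is the least-squares
scalar fit of that fixed pattern to the trial's masked TFR.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_stats import ClusterResult, TFCluster, latency_estimates
from .tfr import TFRSet

__all__ = [
    "ClassificationRules",
    "ComponentMask",
    "ComponentModel",
    "classify_clusters",
    "fit_pattern",
    "trial_contributions",
]

COMPONENT_NAMES = ("PE1", "PE2", "PRED")


@dataclass(frozen=True)
class ClassificationRules:
    gamma_min_hz: float = 40.0
    pe_split_s: float = 0.15        # PE1/PE2 boundary after fifth-tone onset
    pred_band_hz: tuple[float, float] = (12.0, 30.0)
    pred_min_duration_s: float = 0.3
    #: clamp each mask's windows to the component's defining domain: the
    #: gamma band and pre/post-split times for PE1/PE2, the beta band for
    #: PRED.  Without this, clusters that merge across components (e.g. an
    #: early and a late gamma burst joined by supra-threshold cells) would
    #: hand one component's cells to the other's pattern
    clamp_to_band: bool = True

    def band_for(self, name: str) -> tuple[float, float]:
        if name == "PRED":
            return self.pred_band_hz
        return (self.gamma_min_hz, np.inf)

    def time_window_for(self, name: str) -> tuple[float, float]:
        """Defining time domain, seconds after the fifth-tone onset."""
        if name == "PE1":
            return (-np.inf, self.pe_split_s)
        if name == "PE2":
            return (self.pe_split_s, np.inf)
        return (-np.inf, np.inf)


@dataclass
class ComponentMask:
    name: str
    channels: tuple[int, ...]
    freq_window_hz: tuple[float, float]
    time_window_s: tuple[float, float]  # absolute grid times
    clusters: list[TFCluster] = field(default_factory=list)

    def __post_init__(self):
        if len(self.channels) == 0:
            raise ValueError(f"component mask {self.name} has no channels")


def classify_single(
    cluster: TFCluster,
    grid,
    fifth_tone_onset_s: float,
    rules: ClassificationRules,
) -> str:
    lo, hi = cluster.band_hz(grid)
    _, peak = latency_estimates(cluster, grid, fifth_tone_onset_s)
    if cluster.sign == "pos" and lo >= rules.gamma_min_hz:
        return "PE1" if peak < rules.pe_split_s else "PE2"
    if (
        cluster.sign == "neg"
        and lo <= rules.pred_band_hz[1]
        and hi >= rules.pred_band_hz[0]
        and cluster.duration_s(grid) >= rules.pred_min_duration_s
    ):
        return "PRED"
    return "OTHER"


def classify_clusters(
    result: ClusterResult,
    fifth_tone_onset_s: float,
    rules: ClassificationRules = ClassificationRules(),
) -> tuple[dict[str, ComponentMask], pd.DataFrame]:
    """Label every significant cluster and build one mask per component.

    Returns (masks keyed by component name, per-cluster report including
    clusters matching no rule, which are labelled OTHER and retained)."""
    grid = result.grid
    rows = []
    grouped: dict[str, list[TFCluster]] = {}
    for c in result.significant:
        label = classify_single(c, grid, fifth_tone_onset_s, rules)
        lo, hi = c.band_hz(grid)
        onset, peak = latency_estimates(c, grid, fifth_tone_onset_s)
        rows.append(
            {"channel": c.channel, "label": label, "sign": c.sign, "p": c.p_value,
             "f_min": lo, "f_max": hi, "onset_ms": 1e3 * onset, "peak_ms": 1e3 * peak}
        )
        grouped.setdefault(label, []).append(c)
    masks = {}
    for name in COMPONENT_NAMES:
        if name not in grouped:
            continue
        cl = grouped[name]
        fi = np.concatenate([c.cells[:, 0] for c in cl])
        ti = np.concatenate([c.cells[:, 1] for c in cl])
        if rules.clamp_to_band:
            lo, hi = rules.band_for(name)
            t_lo, t_hi = rules.time_window_for(name)
            times = grid.times_s[ti] - fifth_tone_onset_s
            keep = (
                (grid.freqs_hz[fi] >= lo) & (grid.freqs_hz[fi] <= hi)
                & (times >= t_lo) & (times <= t_hi)
            )
            if keep.any():
                fi, ti = fi[keep], ti[keep]
        masks[name] = ComponentMask(
            name=name,
            channels=tuple(sorted({c.channel for c in cl})),
            freq_window_hz=(float(grid.freqs_hz[fi.min()]), float(grid.freqs_hz[fi.max()])),
            time_window_s=(float(grid.times_s[ti.min()]), float(grid.times_s[ti.max()])),
            clusters=cl,
        )
    report = pd.DataFrame(
        rows, columns=["channel", "label", "sign", "p", "f_min", "f_max",
                       "onset_ms", "peak_ms"]
    )
    return masks, report


@dataclass
class ComponentModel:
    mask: ComponentMask
    channel_idx: np.ndarray
    freq_idx: np.ndarray
    time_idx: np.ndarray
    a: np.ndarray  # channel loading, unit norm
    b: np.ndarray  # frequency loading, unit norm, sum >= 0
    c: np.ndarray  # time loading, unit norm, sum >= 0
    scale: float
    fit_quality: float  # explained-variance fraction
    converged: bool


def _mask_indices(tfrset: TFRSet, mask: ComponentMask):
    grid = tfrset.grid
    ch = np.asarray(mask.channels, dtype=int)
    fsel = np.where(
        (grid.freqs_hz >= mask.freq_window_hz[0])
        & (grid.freqs_hz <= mask.freq_window_hz[1])
    )[0]
    tsel = np.where(
        (grid.times_s >= mask.time_window_s[0] - 1e-9)
        & (grid.times_s <= mask.time_window_s[1] + 1e-9)
    )[0]
    return ch, fsel, tsel


def _als_rank1(X: np.ndarray, rng: np.random.Generator, tol: float, max_iter: int):
    """One rank-1 ALS run on a dense 3-way tensor.  Returns (a, b, c, lam,
    converged); loadings unit-norm."""
    b = rng.standard_normal(X.shape[1])
    c = rng.standard_normal(X.shape[2])
    b /= np.linalg.norm(b)
    c /= np.linalg.norm(c)
    a = np.zeros(X.shape[0])
    converged = False
    prev = None
    for _ in range(max_iter):
        a = np.einsum("ijk,j,k->i", X, b, c)
        na = np.linalg.norm(a)
        if na == 0:
            break
        a /= na
        b = np.einsum("ijk,i,k->j", X, a, c)
        b /= np.linalg.norm(b)
        c = np.einsum("ijk,i,j->k", X, a, b)
        lam = np.linalg.norm(c)
        c /= lam
        if prev is not None and abs(lam - prev) <= tol * max(abs(prev), 1e-30):
            converged = True
            break
        prev = lam
    lam = float(np.einsum("ijk,i,j,k", X, a, b, c))
    return a, b, c, lam, converged


def fit_pattern(
    tfrset: TFRSet,
    mask: ComponentMask,
    condition=None,
    role=None,
    n_restarts: int = 10,
    tol: float = 1e-10,
    max_iter: int = 200,
    seed: int | None = None,
) -> ComponentModel:
    """Fit the rank-1 channel x frequency x time pattern of a component.

    The tensor is the trial-averaged baseline-corrected power of the
    component's defining trial type (``condition``/``role`` selectors)
    restricted to the mask windows; grid times that are missing (epoch
    edge) for any masked cell are dropped."""
    sub = tfrset
    if condition is not None or role is not None:
        sub = tfrset.select(condition=condition, role=role)
    if sub.n_trials == 0:
        raise ValueError("no trials match the defining selectors")
    ch, fsel, tsel = _mask_indices(tfrset, mask)
    # robust trial average: single-trial relative power is heavy-tailed
    # (ratio statistic), and a mean tensor can be dominated by one extreme
    # trial, which the rank-1 fit would then reproduce
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        T = np.nanmedian(
            sub.power[:, ch][:, :, fsel][:, :, :, tsel].astype(np.float64), axis=0
        )
    valid_t = ~np.isnan(T).any(axis=(0, 1))
    tsel = tsel[valid_t]
    T = T[:, :, valid_t]
    if min(T.shape) < 2:
        raise ValueError(
            f"component tensor too small for a 3-way fit: shape {T.shape}"
        )
    norm2 = float(np.sum(T**2))
    if norm2 == 0:
        raise ValueError("component tensor is identically zero; nothing to fit")

    ss = np.random.SeedSequence(seed)
    best = None
    any_converged = False
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        a, b, c, lam, conv = _als_rank1(T, rng, tol, max_iter)
        ev = 1.0 - float(np.sum((T - lam * np.einsum("i,j,k->ijk", a, b, c)) ** 2)) / norm2
        any_converged |= conv
        if best is None or ev > best[-1]:
            best = (a, b, c, lam, ev)
    a, b, c, lam, ev = best
    # sign convention: frequency and time loadings sum >= 0; flips absorbed
    # into the channel loading / scale
    if b.sum() < 0:
        b, a = -b, -a
    if c.sum() < 0:
        c, a = -c, -a
    lam = float(np.einsum("ijk,i,j,k", T, a, b, c))
    return ComponentModel(
        mask=mask, channel_idx=ch, freq_idx=fsel, time_idx=tsel,
        a=a, b=b, c=c, scale=lam, fit_quality=ev, converged=any_converged,
    )


def trial_contributions(tfrset: TFRSet, model: ComponentModel) -> pd.Series:
    """Per-trial scalar contribution: <X_trial, a (x) b (x) c> / ||pattern||^2
    over the trial's valid masked cells (missing cells excluded from both
    inner products).  Trials with no valid masked cell get NaN."""
    X = tfrset.power[:, model.channel_idx][:, :, model.freq_idx][:, :, :, model.time_idx]
    X = X.astype(np.float64)
    P = np.einsum("i,j,k->ijk", model.a, model.b, model.c)
    flat = X.reshape(X.shape[0], -1)
    p = P.ravel()
    valid = np.isfinite(flat)
    num = np.where(valid, flat * p[None, :], 0.0).sum(axis=1)
    den = (valid * (p**2)[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = num / den
    contrib[den == 0] = np.nan
    return pd.Series(contrib, index=tfrset.trial_meta["trial_index"].to_numpy(),
                     name=model.mask.name)
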