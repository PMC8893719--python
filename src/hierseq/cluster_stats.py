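"""Nonparametric cluster-based permutation comparison of deviant vs
standard TFRs, per channel.

At every (frequency, time) cell a two-sample t statistic (pooled variance
by default) compares deviant against standard trials.  Supra-threshold
cells (|t| above the two-sided critical value at the cluster-forming alpha)
are partitioned into maximal 4-connected components of uniform sign; the
cluster statistic is the signed sum of t values (cluster mass).  The null
distribution is the maximum |mass| over clusters per label-shuffled
replicate (one null serves both signs), and cluster p-values carry the +1
correction: p = (1 + #{null >= |mass|}) / (n_perm + 1).  Correction is over
frequency x time within each channel only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .tfr import TFRGrid, TFRSet

__all__ = [
    "TFCluster",
    "ClusterResult",
    "tmap",
    "form_clusters",
    "permutation_test",
    "latency_estimates",
]

# 2D connectivity within a map, none across stacked replicates
_STRUCT_2D = ndimage.generate_binary_structure(2, 1)
_STRUCT_STACKED = np.zeros((3, 3, 3), dtype=bool)
_STRUCT_STACKED[1] = _STRUCT_2D


@dataclass
class TFCluster:
    channel: int
    cells: np.ndarray       # (n_cells, 2) of (freq_idx, time_idx)
    cell_t: np.ndarray      # t value per cell
    mass: float             # signed sum of t
    sign: str               # pos | neg
    p_value: float | None = None

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def freq_index_range(self) -> tuple[int, int]:
        return int(self.cells[:, 0].min()), int(self.cells[:, 0].max())

    def time_index_range(self) -> tuple[int, int]:
        return int(self.cells[:, 1].min()), int(self.cells[:, 1].max())

    def band_hz(self, grid: TFRGrid) -> tuple[float, float]:
        lo, hi = self.freq_index_range()
        return float(grid.freqs_hz[lo]), float(grid.freqs_hz[hi])

    def duration_s(self, grid: TFRGrid) -> float:
        lo, hi = self.time_index_range()
        return float(grid.times_s[hi] - grid.times_s[lo])


@dataclass
class ClusterResult:
    clusters: list[TFCluster]
    n_perm: int
    alpha: float
    cluster_alpha: float
    grid: TFRGrid
    channel_meta: pd.DataFrame
    df: int

    @property
    def significant(self) -> list[TFCluster]:
        return [c for c in self.clusters if c.p_value is not None and c.p_value < self.alpha]

    @property
    def responsive_channels(self) -> set[int]:
        return {c.channel for c in self.significant}

    def cluster_table(self, fifth_tone_onset_s: float) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            onset, peak = latency_estimates(c, self.grid, fifth_tone_onset_s)
            lo, hi = c.band_hz(self.grid)
            rows.append(
                {
                    "channel": c.channel,
                    "channel_name": str(self.channel_meta["name"].iloc[c.channel]),
                    "sign": c.sign,
                    "mass": c.mass,
                    "p": c.p_value,
                    "f_min": lo,
                    "f_max": hi,
                    "onset_ms": 1e3 * onset,
                    "peak_ms": 1e3 * peak,
                    "n_cells": c.n_cells,
                }
            )
        cols = ["channel", "channel_name", "sign", "mass", "p",
                "f_min", "f_max", "onset_ms", "peak_ms", "n_cells"]
        return pd.DataFrame(rows, columns=cols)


def tmap(tfr_deviant: TFRSet, tfr_standard: TFRSet, equal_var: bool = True):
    """Two-sample t statistic per (channel, freq, time) cell.

    Returns (t, df).  Missing cells propagate as NaN; cells with zero
    variance in both groups get t = 0."""
    a, b = tfr_deviant.power, tfr_standard.power
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 trials per group")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share channel/frequency/time grids")
    m1 = a.mean(axis=0, dtype=np.float64)
    m2 = b.mean(axis=0, dtype=np.float64)
    v1 = a.var(axis=0, ddof=1, dtype=np.float64)
    v2 = b.var(axis=0, ddof=1, dtype=np.float64)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    else:
        denom = np.sqrt(v1 / n1 + v2 / n2)
        df = n1 + n2 - 2  # conservative reporting df for thresholding
    diff = m1 - m2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / denom
    zero = (denom == 0) & np.isfinite(diff)
    t[zero] = 0.0  # degenerate cells (zero variance in both groups) flagged as 0
    return t, df


def _critical_t(cluster_alpha: float, df: int) -> float:
    return float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df))


def form_clusters(
    tmap_channel: np.ndarray,
    df: int,
    cluster_alpha: float = 0.05,
    channel: int = 0,
) -> list[TFCluster]:
    """Partition supra-threshold cells of one channel's (freq x time) t map
    into maximal 4-connected clusters of uniform sign."""
    thr = _critical_t(cluster_alpha, df)
    t = np.asarray(tmap_channel, dtype=float)
    clusters: list[TFCluster] = []
    for sign, mask in (("pos", t > thr), ("neg", t < -thr)):
        labels, n = ndimage.label(mask, structure=_STRUCT_2D)
        for lab in range(1, n + 1):
            cells = np.argwhere(labels == lab)
            vals = t[labels == lab]
            clusters.append(
                TFCluster(
                    channel=channel, cells=cells, cell_t=vals,
                    mass=float(vals.sum()), sign=sign,
                )
            )
    return clusters


def _max_cluster_masses(tstack: np.ndarray, thr: float) -> np.ndarray:
    """Max |cluster mass| per replicate for a stack of t maps
    (n_rep, F, T); clusters never connect across replicates.  0 when no
    cluster forms."""
    n_rep = tstack.shape[0]
    out = np.zeros(n_rep)
    rep_idx = np.broadcast_to(
        np.arange(n_rep)[:, None, None], tstack.shape
    )
    for signed in (tstack, -tstack):
        mask = signed > thr
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=_STRUCT_STACKED)
        if n == 0:
            continue
        flat_lab = labels.ravel()
        masses = np.bincount(flat_lab, weights=signed.ravel(), minlength=n + 1)
        owner = np.zeros(n + 1, dtype=int)
        owner[flat_lab] = rep_idx.ravel()
        np.maximum.at(out, owner[1:], masses[1:])
    return out


def permutation_test(
    tfr_dev: TFRSet,
    tfr_std: TFRSet,
    n_perm: int = 1000,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
    equal_var: bool = True,
    perm_chunk: int = 250,
) -> ClusterResult:
    """Cluster-based permutation test, channel by channel.

    The same label shuffles are applied to every channel; the null per
    channel is the max |cluster mass| over its own shuffled maps."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n1, n2 = tfr_dev.n_trials, tfr_std.n_trials
    n = n1 + n2
    if n < 4:
        raise ValueError("need at least 4 trials in total")
    t_obs, df = tmap(tfr_dev, tfr_std, equal_var=equal_var)
    thr = _critical_t(cluster_alpha, df)
    n_ch, n_f, n_t = t_obs.shape

    X = np.concatenate(
        [tfr_dev.power.astype(np.float64), tfr_std.power.astype(np.float64)], axis=0
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # boolean group-A membership per permutation
    P = np.zeros((n_perm, n), dtype=np.float64)
    for i in range(n_perm):
        P[i, rng.permutation(n)[:n1]] = 1.0

    clusters_all: list[TFCluster] = []
    for ch in range(n_ch):
        obs_clusters = form_clusters(t_obs[ch], df, cluster_alpha, channel=ch)
        Xc = X[:, ch].reshape(n, -1)
        valid = np.isfinite(Xc).all(axis=0)
        null = np.zeros(n_perm)
        if obs_clusters and valid.any():
            Xv = Xc[:, valid]
            Xv2 = Xv**2
            tot = Xv.sum(axis=0)
            tot2 = Xv2.sum(axis=0)
            for lo in range(0, n_perm, perm_chunk):
                Pc = P[lo:lo + perm_chunk]
                s1 = Pc @ Xv
                q1 = Pc @ Xv2
                s2 = tot[None, :] - s1
                q2 = tot2[None, :] - q1
                m1, m2 = s1 / n1, s2 / n2
                ss1 = q1 - n1 * m1**2
                ss2 = q2 - n2 * m2**2
                if equal_var:
                    sp2 = (ss1 + ss2) / (n - 2)
                    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
                else:
                    denom = np.sqrt(ss1 / (n1 - 1) / n1 + ss2 / (n2 - 1) / n2)
                with np.errstate(invalid="ignore", divide="ignore"):
                    tperm = (m1 - m2) / denom
                tperm[~np.isfinite(tperm)] = 0.0
                tfull = np.zeros((tperm.shape[0], n_f * n_t))
                tfull[:, valid] = tperm
                null[lo:lo + Pc.shape[0]] = _max_cluster_masses(
                    tfull.reshape(-1, n_f, n_t), thr
                )
            for c in obs_clusters:
                c.p_value = float((1 + np.sum(null >= abs(c.mass))) / (n_perm + 1))
        clusters_all.extend(obs_clusters)

    return ClusterResult(
        clusters=clusters_all, n_perm=n_perm, alpha=alpha,
        cluster_alpha=cluster_alpha, grid=tfr_dev.grid,
        channel_meta=tfr_dev.channel_meta.copy(), df=df,
    )


def latency_estimates(
    cluster: TFCluster, grid: TFRGrid, fifth_tone_onset_s: float
) -> tuple[float, float]:
    """(onset, peak) of a cluster in seconds after the fifth-tone onset:
    onset is the earliest cluster time, peak the time of max |t|."""
    times = grid.times_s[cluster.cells[:, 1]]
    onset = float(times.min() - fifth_tone_onset_s)
    peak = float(times[np.argmax(np.abs(cluster.cell_t))] - fifth_tone_onset_s)
    return onset, peak
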