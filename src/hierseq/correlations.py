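"""Within-trial and deviant -> post-deviant correlations between component
contributions.

Within a trial type, the per-trial contributions of two components are
compared by Pearson correlation.  Across trials, the prediction (beta)
contribution on each deviant is paired with the PE1/PE2 contribution on
the immediately following standard trial of the same block.  Electrode-set
pairing rules follow the analysis convention: a frontal prediction
component is correlated with PE contributions from all significant gamma
electrodes, while an auditory prediction component is correlated with PE
contributions from auditory significant gamma electrodes only.

p values are two-sided and uncorrected by default; an optional
Benjamini-Hochberg adjustment over a correlation panel is provided but off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationReport",
    "within_trial_corr",
    "pair_deviant_to_next",
    "across_trial_corr",
    "panel_frame",
    "benjamini_hochberg",
]

ELECTRODE_RULES = ("frontal_pred_vs_all_pe", "auditory_pred_vs_auditory_pe")


@dataclass(frozen=True)
class CorrelationReport:
    pair: tuple[str, str]
    mode: str                   # within_trial | across_trial
    trial_type: str
    n: int
    r: float
    p: float                    # NaN when undefined (n < 3)
    electrode_rule: str | None = None

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p) and self.p < 0.05)


def _pearson(x: np.ndarray, y: np.ndarray):
    ok = np.isfinite(x) & np.isfinite(y)  # pairwise deletion
    n = int(ok.sum())
    if n < 2:
        return n, np.nan, np.nan
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    if n < 3:
        return n, r, np.nan
    p = float(stats.pearsonr(x[ok], y[ok]).pvalue)
    return n, r, p


def within_trial_corr(
    contrib_a: pd.Series,
    contrib_b: pd.Series,
    trial_type: str,
    pair=("A", "B"),
) -> CorrelationReport:
    """Pearson correlation of two components' contributions over the same
    trials (aligned on trial index; missing values pairwise-deleted)."""
    common = contrib_a.index.intersection(contrib_b.index)
    x = contrib_a.loc[common].to_numpy(dtype=float)
    y = contrib_b.loc[common].to_numpy(dtype=float)
    n, r, p = _pearson(x, y)
    return CorrelationReport(tuple(pair), "within_trial", trial_type, n, r, p)


def pair_deviant_to_next(trial_meta: pd.DataFrame):
    """Pair each deviant with the immediately following standard trial of
    the same block.  Returns (pairs, dropped): pairs are
    (deviant_trial_index, standard_trial_index); deviants without an
    eligible follower are dropped with a log entry."""
    meta = trial_meta.sort_values("trial_index").reset_index(drop=True)
    pairs, dropped = [], []
    for i in range(len(meta)):
        if meta["role"].iloc[i] != "deviant":
            continue
        d_idx = int(meta["trial_index"].iloc[i])
        if i + 1 >= len(meta):
            dropped.append({"deviant": d_idx, "reason": "no_following_trial"})
            continue
        nxt = meta.iloc[i + 1]
        if nxt["role"] != "standard" or nxt["block"] != meta["block"].iloc[i]:
            dropped.append({"deviant": d_idx, "reason": "next_not_standard_same_block"})
            continue
        # the immediately following trial must be contiguous in run order
        if int(nxt["trial_index"]) != d_idx + 1:
            dropped.append({"deviant": d_idx, "reason": "next_trial_missing"})
            continue
        pairs.append((d_idx, d_idx + 1))
    return pairs, dropped


def across_trial_corr(
    pred_contrib_on_deviants: pd.Series,
    pe_contrib_on_standards: pd.Series,
    pairs,
    electrode_rule: str,
    pair=("PRED", "PE"),
    trial_type: str = "deviant->post-deviant",
) -> CorrelationReport:
    """Correlate prediction contributions on deviants with PE contributions
    on the paired post-deviant standards."""
    if electrode_rule not in ELECTRODE_RULES:
        raise ValueError(
            f"unknown electrode rule {electrode_rule!r}; valid: {ELECTRODE_RULES}"
        )
    x, y = [], []
    for d_idx, s_idx in pairs:
        if d_idx in pred_contrib_on_deviants.index and s_idx in pe_contrib_on_standards.index:
            x.append(float(pred_contrib_on_deviants.loc[d_idx]))
            y.append(float(pe_contrib_on_standards.loc[s_idx]))
    n, r, p = _pearson(np.asarray(x), np.asarray(y))
    return CorrelationReport(
        tuple(pair), "across_trial", trial_type, n, r, p, electrode_rule
    )


def panel_frame(reports: list[CorrelationReport], fdr: bool = False) -> pd.DataFrame:
    """One row per tested pair; optional Benjamini-Hochberg column."""
    rows = [
        {
            "pair": f"{rep.pair[0]}~{rep.pair[1]}",
            "mode": rep.mode,
            "electrode_rule": rep.electrode_rule or "n/a",
            "trial_type": rep.trial_type,
            "n": rep.n,
            "r": rep.r,
            "p": rep.p,
            "significant": rep.significant,
        }
        for rep in reports
    ]
    df = pd.DataFrame(
        rows, columns=["pair", "mode", "electrode_rule", "trial_type",
                       "n", "r", "p", "significant"]
    )
    if fdr and len(df):
        df["p_fdr"] = benjamini_hochberg(df["p"].to_numpy())
        df["significant_fdr"] = df["p_fdr"] < 0.05
    return df


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q)
    ranked = q[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out
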