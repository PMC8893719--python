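"""Desk-scale simulation experiments: latency recovery, contribution
recovery, coupling detection, and false-positive calibration.

These recipes run the full pipeline (simulate -> preprocess -> TFR ->
cluster permutation -> components) at a reduced problem size chosen for a
single CPU: 16 channels (ROI counts scaled from the 96-channel default),
one 25-trial test block per run, 2 Hz frequency spacing and 500
permutations.  The paradigm timing, component latencies/bands and noise
model are the full-scale study conditions; only the array size, block
count and grid density are scaled.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_stats import ClusterResult, latency_estimates, permutation_test
from .components import classify_clusters, fit_pattern, trial_contributions
from .correlations import (
    CorrelationReport,
    across_trial_corr,
    pair_deviant_to_next,
    within_trial_corr,
)
from .paradigm import ParadigmConfig, build_run
from .preprocess import Excluded, PreprocessConfig, preprocess_run
from .synth import (
    ComponentSpec,
    CouplingSpec,
    SyntheticRecording,
    default_components,
    default_layout,
    inject_components,
    omission_component,
    simulate_background,
)
from .tfr import TFRGrid, TFRSet, baseline_correct, tfr_multitaper

__all__ = [
    "ReducedScale",
    "simulate_task_run",
    "run_to_tfr",
    "latency_recovery",
    "contribution_recovery",
    "coupling_panel",
    "null_correlation_rate",
    "fwer_calibration",
]

#: reported component latencies used as injection/recovery targets (seconds
#: after the fifth-tone / omitted-tone onset)
PE1_PEAK_S = 0.074
PE2_PEAK_S = 0.242
OMISSION_ONSET_S = 0.048

REDUCED_ROI_COUNTS = {
    "auditory_core": 4,
    "auditory_belt_parabelt": 4,
    "STR": 2,
    "frontal": 4,
    "other": 2,
}


@dataclass(frozen=True)
class ReducedScale:
    roi_counts: dict = field(default_factory=lambda: dict(REDUCED_ROI_COUNTS))
    n_test_blocks: int = 1
    fstep: float = 2.0
    n_perm: int = 500
    fs: float = 1000.0

    @property
    def paradigm(self) -> ParadigmConfig:
        return ParadigmConfig(n_test_blocks=self.n_test_blocks)

    @property
    def grid(self) -> TFRGrid:
        return TFRGrid.default(self.paradigm.fifth_tone_onset_s, fstep=self.fstep)


def simulate_task_run(
    task: str,
    deviant_type: str | None,
    components: list[ComponentSpec],
    seed: int,
    coupling: CouplingSpec | None = None,
    paradigm: ParadigmConfig | None = None,
    roi_counts: dict | None = None,
    fs: float = 1000.0,
    exponent: float = 1.5,
    line_amplitude: float = 0.1,
) -> SyntheticRecording:
    """One run of the paradigm realized as a synthetic recording."""
    pcfg = paradigm or ParadigmConfig()
    ss = np.random.SeedSequence(seed)
    s_run, s_bg, s_inj = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    run = build_run(task, deviant_type, pcfg, seed=s_run)
    layout = default_layout(roi_counts)
    background = simulate_background(
        layout, run.duration_s + 2.0, fs, exponent=exponent,
        line_hz=50.0, line_amplitude=line_amplitude, seed=s_bg,
    )
    return inject_components(
        background, run, components, coupling, fs=fs, layout=layout, seed=s_inj
    )


def run_to_tfr(
    rec: SyntheticRecording,
    grid: TFRGrid,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    baseline_window=(-0.3, 0.0),
    drop_habituation: bool = False,
) -> TFRSet:
    """Preprocess one recording and return baseline-corrected power.

    ``drop_habituation`` removes habituation trials before the transform
    (they are excluded from the statistics anyway)."""
    with warnings.catch_warnings():
        # the first habituation epoch always starts at t=0 and cannot carry
        # a -1 s pre-stimulus window; it is dropped silently here
        warnings.simplefilter("ignore", UserWarning)
        ts = preprocess_run(rec, pre_cfg)
    if isinstance(ts, Excluded):
        raise RuntimeError(f"run excluded during preprocessing: {ts.reason}")
    if drop_habituation:
        keep = (ts.trial_meta["role"] != "habituation").to_numpy()
        ts = ts.copy_with(
            data=ts.data[keep],
            trial_meta=ts.trial_meta.loc[keep].reset_index(drop=True),
        )
    raw = tfr_multitaper(ts, grid)
    return baseline_correct(raw, baseline_window)


def _align_channels(a: TFRSet, b: TFRSet) -> tuple[TFRSet, TFRSet]:
    """Restrict two TFR sets (possibly from different runs with different
    rejected channels) to their common channel names."""
    names_a = list(a.channel_meta["name"])
    names_b = list(b.channel_meta["name"])
    common = [n for n in names_a if n in set(names_b)]

    def _sub(t: TFRSet, names: list[str]) -> TFRSet:
        idx = [list(t.channel_meta["name"]).index(n) for n in names]
        return TFRSet(
            t.power[:, idx], t.grid, t.trial_meta.copy(),
            t.channel_meta.iloc[idx].reset_index(drop=True),
            t.baseline_window_s, t.baseline_mode,
        )

    return _sub(a, common), _sub(b, common)


def _gamma_clusters(result: ClusterResult, gamma_min_hz: float = 40.0):
    out = []
    for c in result.significant:
        if c.sign == "pos" and c.band_hz(result.grid)[0] >= gamma_min_hz:
            out.append(c)
    return out


_KINDS = {
    # kind -> (task, deviant condition, standard condition, measure, pick)
    "pe1_peak": ("xx", "xY|xx", "xx|xx", "peak", "earliest"),
    "pe2_peak": ("xY", "xx|xY", "xY|xY", "peak", "largest"),
    "omission_onset": ("xY", "x_|xY", "xxxx_expected", "onset", "earliest"),
}


def _injection_for(kind: str) -> list[ComponentSpec]:
    """Single-component injections at the reported latency, zero jitter."""
    pe1, pe2, _ = default_components()
    if kind == "pe1_peak":
        return [dataclasses.replace(
            pe1, latency_mean_s=PE1_PEAK_S, latency_sd_s=0.0,
            active_conditions=("xY|xx",),
        )]
    if kind == "pe2_peak":
        return [dataclasses.replace(
            pe2, latency_mean_s=PE2_PEAK_S, latency_sd_s=0.0,
            active_conditions=("xx|xY",),
        )]
    if kind == "omission_onset":
        return [omission_component(OMISSION_ONSET_S)]
    raise ValueError(f"unknown recovery kind {kind!r}; valid: {tuple(_KINDS)}")


def latency_recovery(
    kind: str,
    n_runs: int = 20,
    seed: int = 0,
    scale: ReducedScale = ReducedScale(),
) -> dict:
    """Inject a component at its reported latency (zero latency jitter) and
    measure the latency the cluster pipeline recovers, over ``n_runs``
    simulated runs.

    ``pe1_peak``/``pe2_peak`` report the peak latency of the detected
    positive gamma cluster; ``omission_onset`` reports the onset latency of
    the earliest positive gamma cluster in the rare- vs expected-omission
    comparison (which requires a paired expected-omission block run).
    Returns per-run latencies (ms) and their mean over detected runs.
    """
    task, dev_cond, std_cond, measure, pick = _KINDS[kind]
    comps = _injection_for(kind)
    pcfg = scale.paradigm
    grid = scale.grid
    fifth = pcfg.fifth_tone_onset_s
    ss = np.random.SeedSequence(seed)
    latencies: list[float] = []
    detected = 0
    for rep_ss in ss.spawn(n_runs):
        s_dev, s_ref, s_perm = (
            int(c.generate_state(1)[0] % 2**31) for c in rep_ss.spawn(3)
        )
        rec = simulate_task_run(
            task, dev_cond, comps, seed=s_dev, paradigm=pcfg,
            roi_counts=scale.roi_counts, fs=scale.fs,
        )
        try:
            tfrset = run_to_tfr(rec, grid, drop_habituation=True)
        except RuntimeError:
            # the run fell under the minimum-deviant exclusion rule (an
            # artifact-rejected deviant trial); it contributes no estimate
            latencies.append(np.nan)
            continue
        dev_tfr = tfrset.select(condition=dev_cond, role="deviant")
        if std_cond == "xxxx_expected":
            ref_rec = simulate_task_run(
                "omission_block", None, [], seed=s_ref, paradigm=pcfg,
                roi_counts=scale.roi_counts, fs=scale.fs,
            )
            std_tfr = run_to_tfr(ref_rec, grid, drop_habituation=True).select(
                condition=std_cond, role="standard"
            )
        else:
            std_tfr = tfrset.select(condition=std_cond, role="standard")
        dev_tfr, std_tfr = _align_channels(dev_tfr, std_tfr)
        result = permutation_test(
            dev_tfr, std_tfr, n_perm=scale.n_perm, seed=s_perm
        )
        gam = _gamma_clusters(result)
        # response window of interest: clusters peaking after the (possibly
        # omitted) fifth-tone onset
        gam = [c for c in gam if latency_estimates(c, grid, fifth)[1] >= 0.0]
        if not gam:
            latencies.append(np.nan)
            continue
        lat_pairs = [latency_estimates(c, grid, fifth) for c in gam]
        if pick == "earliest":
            i = int(np.argmin([on for on, _ in lat_pairs]))
        else:  # largest cluster mass
            i = int(np.argmax([abs(c.mass) for c in gam]))
        onset, peak = lat_pairs[i]
        latencies.append(1e3 * (onset if measure == "onset" else peak))
        detected += 1
    arr = np.asarray(latencies)
    return {
        "kind": kind,
        "latencies_ms": arr,
        "mean_ms": float(np.nanmean(arr)) if detected else np.nan,
        "sd_ms": float(np.nanstd(arr)) if detected else np.nan,
        "n_runs": n_runs,
        "n_detected": detected,
    }


def contribution_recovery(
    seed: int = 0,
    n_runs: int = 2,
    scale: ReducedScale = ReducedScale(n_test_blocks=3),
    n_perm: int = 500,
) -> dict:
    """Full-pipeline recovery of per-trial component amplitudes on 3-block
    xx-task runs with the default component set: Pearson r between the
    PARAFAC contributions and the generator's ground-truth amplitudes, per
    component, pooled over ``n_runs`` runs (patterns fitted per run, as
    estimated channel sets differ across runs)."""
    ss = np.random.SeedSequence(seed)
    comps = default_components()
    pooled: dict[str, list] = {}
    ev: dict[str, float] = {}
    for run_ss in ss.spawn(n_runs):
        s_rec, s_perm, s_fit = (
            int(c.generate_state(1)[0] % 2**31) for c in run_ss.spawn(3)
        )
        rec = simulate_task_run(
            "xx", "xY|xx", comps, seed=s_rec, paradigm=scale.paradigm,
            roi_counts=scale.roi_counts, fs=scale.fs,
        )
        tfrset = run_to_tfr(rec, scale.grid, drop_habituation=True)
        dev = tfrset.select(condition="xY|xx", role="deviant")
        std = tfrset.select(condition="xx|xx", role="standard")
        result = permutation_test(dev, std, n_perm=n_perm, seed=s_perm)
        masks, _ = classify_clusters(result, scale.paradigm.fifth_tone_onset_s)
        gt = rec.ground_truth
        for i, (name, mask) in enumerate(sorted(masks.items())):
            model = fit_pattern(tfrset, mask, condition="xY|xx", seed=s_fit + i)
            contrib = trial_contributions(dev, model)
            truth = (
                gt[gt["component"] == name]
                .set_index("trial_index")["amplitude"]
                .reindex(contrib.index)
            )
            # per-run standardization before pooling (patterns differ in
            # scale between runs)
            c = contrib.to_numpy(dtype=float)
            tr = truth.to_numpy(dtype=float)
            ok = np.isfinite(c) & np.isfinite(tr)
            if ok.sum() < 3:
                continue
            c = (c[ok] - c[ok].mean()) / c[ok].std()
            tr_z = (tr[ok] - tr[ok].mean()) / tr[ok].std()
            pooled.setdefault(name, []).append(np.c_[c, tr_z])
            ev[name] = model.fit_quality
    out = {}
    for name, chunks in pooled.items():
        xy = np.concatenate(chunks, axis=0)
        out[name] = {
            "r": float(np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]),
            "n": int(xy.shape[0]),
            "explained_variance": ev[name],
        }
    return out


def coupling_panel(
    seed: int = 0,
    coupling: CouplingSpec = CouplingSpec(
        pe1_to_pe2_gain=1.0, pred_to_next_pe1_gain=0.25,
        pred_to_next_pe2_gain=0.25, noise_sd=0.015,
    ),
    scale: ReducedScale = ReducedScale(n_test_blocks=6),
    n_perm: int = 500,
) -> list[CorrelationReport]:
    """Within-trial (PE1~PE2 on deviants) and across-trial (PRED on
    deviants ~ PE1/PE2 on post-deviant standards) correlations recovered by
    the full pipeline on one coupled xx-task run."""
    ss = np.random.SeedSequence(seed)
    s_rec, s_perm, s_fit = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    rec = simulate_task_run(
        "xx", "xY|xx", default_components(), seed=s_rec, coupling=coupling,
        paradigm=scale.paradigm, roi_counts=scale.roi_counts, fs=scale.fs,
    )
    tfrset = run_to_tfr(rec, scale.grid, drop_habituation=True)
    dev = tfrset.select(condition="xY|xx", role="deviant")
    std = tfrset.select(condition="xx|xx", role="standard")
    result = permutation_test(dev, std, n_perm=n_perm, seed=s_perm)
    masks, _ = classify_clusters(result, scale.paradigm.fifth_tone_onset_s)
    models = {
        name: fit_pattern(tfrset, mask, condition="xY|xx", seed=s_fit + i)
        for i, (name, mask) in enumerate(sorted(masks.items()))
    }
    reports: list[CorrelationReport] = []
    if "PE1" in models and "PE2" in models:
        reports.append(
            within_trial_corr(
                trial_contributions(dev, models["PE1"]),
                trial_contributions(dev, models["PE2"]),
                "xY|xx", pair=("PE1", "PE2"),
            )
        )
    if "PRED" in models:
        pairs, _ = pair_deviant_to_next(tfrset.trial_meta)
        pred_c = trial_contributions(dev, models["PRED"])
        for pe in ("PE1", "PE2"):
            if pe not in models:
                continue
            pe_c = trial_contributions(std, models[pe])
            reports.append(
                across_trial_corr(
                    pred_c, pe_c, pairs, "frontal_pred_vs_all_pe",
                    pair=("PRED", pe), trial_type="xY|xx->xx|xx",
                )
            )
    return reports


def null_correlation_rate(
    n_sims: int = 1000, n_trials: int = 15, seed: int = 0, alpha: float = 0.05
) -> float:
    """Fraction of simulated datasets with p < alpha when two component
    contribution vectors are independent Gaussians (null calibration of
    the Pearson test at the contribution level)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hits = 0
    for i in range(n_sims):
        a = pd.Series(rng.standard_normal(n_trials), index=np.arange(n_trials))
        b = pd.Series(rng.standard_normal(n_trials), index=np.arange(n_trials))
        rep = within_trial_corr(a, b, "null")
        hits += rep.p < alpha
    return hits / n_sims


def _toy_tfrset(power: np.ndarray, grid: TFRGrid, n_ch: int) -> TFRSet:
    n_trials = power.shape[0]
    meta = pd.DataFrame(
        {"trial_index": np.arange(n_trials), "onset": np.zeros(n_trials),
         "condition": "toy", "role": "standard", "block": 0}
    )
    chans = pd.DataFrame({"name": [f"ch{i}" for i in range(n_ch)],
                          "roi": ["other"] * n_ch})
    return TFRSet(power.astype(np.float32), grid, meta, chans)


def fwer_calibration(
    n_datasets: int = 500,
    n_channels: int = 8,
    n_freqs: int = 20,
    n_times: int = 40,
    n1: int = 10,
    n2: int = 10,
    n_perm: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical family-wise error of the cluster permutation test under
    the global null (i.i.d. Gaussian cells, exchangeable trial labels).

    The correction operates per channel over frequency x time, so the
    calibrated quantity is the fraction of channel-tests owning at least
    one p < alpha cluster; with ``n_channels`` independent channels per
    dataset this pools n_datasets * n_channels tests."""
    grid = TFRGrid(
        np.arange(n_freqs) * 5.0 + 10.0, np.arange(n_times) * 0.02, 4.0, 0.5
    )
    ss = np.random.SeedSequence(seed)
    hits = 0
    n_tests = 0
    for d_ss in ss.spawn(n_datasets):
        s_data, s_perm = (int(c.generate_state(1)[0] % 2**31) for c in d_ss.spawn(2))
        rng = np.random.default_rng(s_data)
        a = _toy_tfrset(
            rng.standard_normal((n1, n_channels, n_freqs, n_times)), grid, n_channels
        )
        b = _toy_tfrset(
            rng.standard_normal((n2, n_channels, n_freqs, n_times)), grid, n_channels
        )
        result = permutation_test(a, b, n_perm=n_perm, alpha=alpha, seed=s_perm)
        sig = result.responsive_channels
        hits += len(sig)
        n_tests += n_channels
    rate = hits / n_tests
    se = float(np.sqrt(rate * (1 - rate) / n_tests)) if 0 < rate < 1 else float(
        np.sqrt(alpha * (1 - alpha) / n_tests)
    )
    return {"rate": rate, "se": se, "n_tests": n_tests, "n_datasets": n_datasets}
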