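"""End-to-end orchestration of the condition comparisons.

The condition labels (``xY|xx`` etc.) encode both the sequence type and the
task context, so a contrast is a pair of condition selectors.  The default
set mirrors the reported comparisons:

* ``local_novelty``   — conjunction of (xY|xx vs xx|xx) and (xY|xY vs xx|xY)
* ``global_only``     — xx|xY vs xY|xY
* ``local_and_global``— xY|xx vs xx|xx
* ``omission_xx``     — x_|xx vs expected omissions (xxxx block)
* ``omission_xY``     — x_|xY vs expected omissions
* ``omission_diff``   — x_|xY vs x_|xx

Conjunction is implemented as the intersection of per-channel
responsiveness with same-sign significant clusters across sub-contrasts (a
channel-space transplant of the imaging conjunction logic; flagged as such
in reports).  ``run_full_analysis`` chains preprocessing, TFR, contrasts,
component classification, per-trial contributions and the correlation
panel into a results bundle with a provenance block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cluster_stats import ClusterResult, permutation_test
from .components import (
    ClassificationRules,
    ComponentMask,
    classify_clusters,
    fit_pattern,
    trial_contributions,
)
from .correlations import (
    across_trial_corr,
    pair_deviant_to_next,
    panel_frame,
    within_trial_corr,
)
from .preprocess import Excluded, PreprocessConfig, preprocess_run, qc_report
from .tfr import TFRGrid, TFRSet, baseline_correct, concat_tfrsets, tfr_multitaper

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "StatsConfig",
    "default_contrasts",
    "run_contrast",
    "run_full_analysis",
    "ResultsBundle",
]


@dataclass(frozen=True)
class StatsConfig:
    n_perm: int = 1000
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    equal_var: bool = True


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    group_a: str | None = None  # deviant-side condition
    group_b: str | None = None  # standard-side condition
    combine: str = "single"     # single | conjunction
    sub_contrasts: tuple["ContrastSpec", ...] = ()

    def __post_init__(self):
        if self.combine == "single":
            if self.group_a is None or self.group_b is None:
                raise ValueError(f"single contrast {self.name} needs both groups")
            if self.group_a == self.group_b:
                raise ValueError(f"contrast {self.name}: groups must be disjoint")
        elif self.combine == "conjunction":
            if len(self.sub_contrasts) < 2:
                raise ValueError("conjunction needs >= 2 sub-contrasts")
        else:
            raise ValueError(f"unknown combine mode {self.combine!r}")

    @property
    def conditions(self) -> set[str]:
        if self.combine == "single":
            return {self.group_a, self.group_b}
        return set().union(*(s.conditions for s in self.sub_contrasts))


def default_contrasts() -> list[ContrastSpec]:
    return [
        ContrastSpec(
            "local_novelty", combine="conjunction",
            sub_contrasts=(
                ContrastSpec("local_novelty_xx_task", "xY|xx", "xx|xx"),
                ContrastSpec("local_novelty_xY_task", "xY|xY", "xx|xY"),
            ),
        ),
        ContrastSpec("global_only", "xx|xY", "xY|xY"),
        ContrastSpec("local_and_global", "xY|xx", "xx|xx"),
        ContrastSpec("omission_xx", "x_|xx", "xxxx_expected"),
        ContrastSpec("omission_xY", "x_|xY", "xxxx_expected"),
        ContrastSpec("omission_diff", "x_|xY", "x_|xx"),
    ]


@dataclass
class ContrastResult:
    spec: ContrastSpec
    results: list[ClusterResult]         # one per single / per sub-contrast
    responsive_channels: set[int]

    @property
    def primary(self) -> ClusterResult:
        return self.results[0]


def _select(tfrset: TFRSet, condition: str) -> TFRSet:
    out = tfrset.select(condition=condition, role=("standard", "deviant"))
    if out.n_trials == 0:
        raise ValueError(f"selector {condition!r} matches no trials")
    return out


def _signs_by_channel(res: ClusterResult) -> dict[int, set[str]]:
    out: dict[int, set[str]] = {}
    for c in res.significant:
        out.setdefault(c.channel, set()).add(c.sign)
    return out


def run_contrast(
    spec: ContrastSpec,
    tfrset: TFRSet,
    stats_cfg: StatsConfig = StatsConfig(),
    seed: int | None = None,
) -> ContrastResult:
    """Run one (possibly conjunction) contrast on a pooled TFR set."""
    if spec.combine == "single":
        res = permutation_test(
            _select(tfrset, spec.group_a), _select(tfrset, spec.group_b),
            n_perm=stats_cfg.n_perm, alpha=stats_cfg.alpha,
            cluster_alpha=stats_cfg.cluster_alpha, seed=seed,
            equal_var=stats_cfg.equal_var,
        )
        return ContrastResult(spec, [res], res.responsive_channels)
    ss = np.random.SeedSequence(seed)
    subs = [
        run_contrast(sub, tfrset, stats_cfg, seed=int(child.generate_state(1)[0] % 2**31))
        for sub, child in zip(spec.sub_contrasts, ss.spawn(len(spec.sub_contrasts)))
    ]
    sign_maps = [_signs_by_channel(s.primary) for s in subs]
    responsive = set()
    for ch in set().union(*(set(m) for m in sign_maps)) if sign_maps else set():
        shared = set.intersection(*(m.get(ch, set()) for m in sign_maps))
        if shared:
            responsive.add(ch)
    return ContrastResult(spec, [s.primary for s in subs], responsive)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class ResultsBundle:
    qc: dict[str, pd.DataFrame]
    cluster_tables: dict[str, pd.DataFrame]
    component_report: dict
    contributions: dict[str, pd.Series]
    correlation_panel: pd.DataFrame
    provenance: dict
    log: list[str] = field(default_factory=list)


def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_analysis(
    recordings: dict,
    grid: TFRGrid | None = None,
    pre_cfg: PreprocessConfig = PreprocessConfig(),
    stats_cfg: StatsConfig = StatsConfig(),
    rules: ClassificationRules = ClassificationRules(),
    contrasts: list[ContrastSpec] | None = None,
    baseline_window=(-0.3, 0.0),
    baseline_mode: str = "relchange",
    fifth_tone_onset_s: float = 0.8,
    seed: int = 0,
    fdr: bool = False,
) -> ResultsBundle:
    """Preprocess -> TFR -> contrasts -> components -> contributions ->
    correlation panel, over a dict of named recordings.

    Excluded runs are dropped and logged; zero usable runs is a hard error.
    Identical inputs and seed reproduce the bundle bit-for-bit.
    """
    log: list[str] = []
    qc: dict[str, pd.DataFrame] = {}
    tfrsets: dict[str, TFRSet] = {}
    if grid is None:
        grid = TFRGrid.default(fifth_tone_onset_s)

    for name, rec in recordings.items():
        result = preprocess_run(rec, pre_cfg)
        qc[name] = qc_report(result)
        if isinstance(result, Excluded):
            log.append(f"run {name} excluded: {result.reason}")
            continue
        raw = tfr_multitaper(result, grid)
        tfrsets[name] = baseline_correct(raw, baseline_window, baseline_mode)
        tfrsets[name].trial_meta["run"] = name
    if not tfrsets:
        raise RuntimeError("no usable runs after exclusion")

    # channel alignment: keep channels retained in every usable run
    name_sets = [set(t.channel_meta["name"]) for t in tfrsets.values()]
    common = set.intersection(*name_sets)
    for name, t in list(tfrsets.items()):
        keep = np.array([n in common for n in t.channel_meta["name"]])
        if not keep.all():
            log.append(f"run {name}: restricting to {int(keep.sum())} common channels")
        tfrsets[name] = TFRSet(
            t.power[:, keep], t.grid, t.trial_meta,
            t.channel_meta.loc[keep].reset_index(drop=True),
            t.baseline_window_s, t.baseline_mode,
        )
    pooled = concat_tfrsets(list(tfrsets.values()))
    available = set(pooled.trial_meta["condition"])

    ss = np.random.SeedSequence(seed)
    child_seed = iter(int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(64))

    contrast_results: dict[str, ContrastResult] = {}
    cluster_tables: dict[str, pd.DataFrame] = {}
    for spec in contrasts if contrasts is not None else default_contrasts():
        if not spec.conditions <= available:
            log.append(f"contrast {spec.name} skipped: missing conditions "
                       f"{sorted(spec.conditions - available)}")
            continue
        cres = run_contrast(spec, pooled, stats_cfg, seed=next(child_seed))
        contrast_results[spec.name] = cres
        tables = [r.cluster_table(fifth_tone_onset_s) for r in cres.results]
        cluster_tables[spec.name] = pd.concat(tables, ignore_index=True)

    # ---- component classification & patterns ----
    component_sources = {
        "PE1": ("local_and_global", "xY|xx"),
        "PE2": ("global_only", "xx|xY"),
        "PRED": ("local_and_global", "xY|xx"),
    }
    masks: dict[str, ComponentMask] = {}
    reports = {}
    for comp, (contrast_name, _) in component_sources.items():
        if contrast_name not in contrast_results:
            continue
        m, rep = classify_clusters(
            contrast_results[contrast_name].primary, fifth_tone_onset_s, rules
        )
        reports[contrast_name] = rep
        if comp in m:
            masks[comp] = m[comp]
        else:
            log.append(f"component {comp} not detected in contrast {contrast_name}")

    models = {}
    contributions: dict[str, pd.Series] = {}
    for comp, mask in masks.items():
        _, defining_cond = component_sources[comp]
        try:
            model = fit_pattern(
                pooled, mask, condition=defining_cond, seed=next(child_seed)
            )
        except ValueError as err:
            log.append(f"component {comp}: pattern fit failed ({err})")
            continue
        models[comp] = model
        contributions[comp] = trial_contributions(
            pooled.select(condition=defining_cond, role=("standard", "deviant")), model
        )

    # ---- correlation panel ----
    reports_corr = []
    roi_map = {
        "frontal": ("frontal",),
        "auditory": ("auditory_core", "auditory_belt_parabelt"),
    }

    def restricted_model(comp: str, rois) -> "object | None":
        mask = masks.get(comp)
        if mask is None:
            return None
        if rois is not None:
            ch_rois = pooled.channel_meta["roi"].to_numpy()
            keep = tuple(c for c in mask.channels if ch_rois[c] in rois)
            if not keep:
                return None
            mask = ComponentMask(mask.name, keep, mask.freq_window_hz,
                                 mask.time_window_s, mask.clusters)
        _, defining_cond = component_sources[comp]
        try:
            return fit_pattern(pooled, mask, condition=defining_cond,
                               seed=next(child_seed))
        except ValueError:
            return None

    # within-trial correlations on each global-deviant type
    for trial_type, pairs in (
        ("xY|xx", [("PE1", "PE2"), ("PE2", "PRED")]),
        ("xx|xY", [("PE2", "PRED")]),
    ):
        if trial_type not in available:
            continue
        trials = pooled.select(condition=trial_type)
        for a, b in pairs:
            if a not in models or b not in models:
                continue
            ca = trial_contributions(trials, models[a])
            cb = trial_contributions(trials, models[b])
            reports_corr.append(within_trial_corr(ca, cb, trial_type, pair=(a, b)))

    # across-trial: PRED on deviants vs PE on post-deviant standards, per run
    for run_name, t in tfrsets.items():
        dev_conds = set(t.trial_meta.loc[t.trial_meta["role"] == "deviant", "condition"])
        if not dev_conds or "PRED" not in masks:
            continue
        dev_cond = dev_conds.pop()
        pairs, _ = pair_deviant_to_next(t.trial_meta)
        if not pairs:
            continue
        for rule, pred_rois, pe_rois in (
            ("frontal_pred_vs_all_pe", roi_map["frontal"], None),
            ("auditory_pred_vs_auditory_pe", roi_map["auditory"], roi_map["auditory"]),
        ):
            pred_model = restricted_model("PRED", pred_rois)
            if pred_model is None:
                log.append(f"across-trial rule {rule} skipped in {run_name}: "
                           "empty PRED electrode set")
                continue
            pred_c = trial_contributions(t.select(role="deviant"), pred_model)
            for pe in ("PE1", "PE2"):
                pe_model = restricted_model(pe, pe_rois)
                if pe_model is None:
                    continue
                pe_c = trial_contributions(t.select(role="standard"), pe_model)
                reports_corr.append(
                    across_trial_corr(
                        pred_c, pe_c, pairs, rule, pair=("PRED", pe),
                        trial_type=f"{run_name}:{dev_cond}->post",
                    )
                )

    panel = panel_frame(reports_corr, fdr=fdr)

    component_report = {
        comp: {
            "channels": list(masks[comp].channels),
            "channel_names": [
                str(pooled.channel_meta["name"].iloc[c]) for c in masks[comp].channels
            ],
            "freq_window_hz": list(masks[comp].freq_window_hz),
            "time_window_s": list(masks[comp].time_window_s),
            "explained_variance": models[comp].fit_quality if comp in models else None,
            "contributions": {
                str(k): (None if not np.isfinite(v) else float(v))
                for k, v in contributions.get(comp, pd.Series(dtype=float)).items()
            },
        }
        for comp in masks
    }

    cfg_obj = {
        "pre": pre_cfg.__dict__, "stats": stats_cfg.__dict__,
        "rules": rules.__dict__, "baseline": [list(baseline_window), baseline_mode],
        "grid": {"fmin": float(grid.freqs_hz[0]), "fmax": float(grid.freqs_hz[-1]),
                 "n_freqs": int(grid.freqs_hz.size), "n_times": int(grid.times_s.size)},
    }
    provenance = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg_obj),
        "config": cfg_obj,
        "runs": sorted(recordings),
        "usable_runs": sorted(tfrsets),
    }
    return ResultsBundle(qc, cluster_tables, component_report, contributions,
                         panel, provenance, log)
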