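"""YAML configuration with strict schema validation, the miniature test
fixture, and bundle serialization.

The configuration is a nested mapping mirroring every stage's parameters;
unknown keys are rejected (all offending key paths listed) and all defaults
are materialized so the provenance block records the full effective
configuration.  Every random operation consumes a named child seed derived
from the global seed; no operation reads global random state.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

from .components import ClassificationRules
from .contrasts import ResultsBundle, StatsConfig
from .fileio import write_json, write_table
from .paradigm import ParadigmConfig, build_run
from .preprocess import PreprocessConfig
from .synth import (
    ComponentSpec,
    CouplingSpec,
    SyntheticRecording,
    default_layout,
    inject_components,
    simulate_background,
)

__all__ = ["DEFAULTS", "load_config", "child_seed", "fixture_small", "write_bundle"]

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "results",
    "paradigm": {
        "protocol": "ecog",
        "tone_duration_s": 0.050,
        "inter_tone_interval_s": 0.150,
        "inter_sequence_onset_s": 3.0,
        "freq_x_hz": 707.0,
        "freq_y_hz": 4000.0,
        "n_habituation": 20,
        "block_size": 25,
        "deviant_fraction": 0.2,
        "n_test_blocks": 3,
        "rest_s": 0.0,
    },
    "synth": {
        "fs": 1000.0,
        "exponent": 1.5,
        "line_hz": 50.0,
        "line_amplitude": 0.1,
        "rms": 1.0,
        "roi_counts": {
            "auditory_core": 12,
            "auditory_belt_parabelt": 16,
            "STR": 8,
            "frontal": 24,
            "other": 36,
        },
    },
    "coupling": {
        "pe1_to_pe2_gain": 0.0,
        "pred_to_next_pe1_gain": 0.0,
        "pred_to_next_pe2_gain": 0.0,
        "noise_sd": 0.02,
    },
    "preprocess": {
        "window_s": [-1.0, 2.0],
        "band": [1.0, 240.0],
        "order": 5,
        "target_fs": 500.0,
        "notch_hz": 50.0,
        "hf_band": [70.0, 240.0],
        "z_thresh": 5.0,
        "trial_fraction": 0.6,
        "amp_thresh_z": 8.0,
        "min_deviants": 5,
    },
    "tfr": {
        "fmin": 10.0,
        "fmax": 140.0,
        "fstep": 1.0,
        "tstep": 0.02,
        "tmin": -0.3,
        "post_fifth_s": 0.8,
        "window_cycles": 4.0,
        "smoothing_factor": 0.5,
        "baseline_window": [-0.3, 0.0],
        "baseline_mode": "relchange",
    },
    "stats": {
        "n_perm": 1000,
        "alpha": 0.05,
        "cluster_alpha": 0.05,
        "equal_var": True,
    },
    "components": {
        "gamma_min_hz": 40.0,
        "pe_split_s": 0.15,
        "pred_band_hz": [12.0, 30.0],
        "pred_min_duration_s": 0.3,
    },
    "correlations": {
        "fdr": False,
    },
}


def _merge(default, user, path, errors):
    if not isinstance(user, dict):
        errors.append(f"{path or '<root>'}: expected a mapping")
        return default
    out = copy.deepcopy(default)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in default:
            errors.append(f"unknown key {where!r}")
            continue
        if isinstance(default[key], dict) and not path.endswith("roi_counts"):
            out[key] = _merge(default[key], value, where, errors)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Load a YAML config against the schema; an empty/missing file yields
    all defaults.  Unknown keys raise with every offending key named."""
    user = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
    errors: list[str] = []
    cfg = _merge(DEFAULTS, user, "", errors)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg


def child_seed(seed: int, stream: str) -> int:
    """Named child seed derived from the global seed (stable across
    processes, < 2**31)."""
    import hashlib

    h = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence([seed, h])
    return int(ss.generate_state(1)[0] % 2**31)


def paradigm_config_from(cfg: dict) -> ParadigmConfig:
    p = cfg["paradigm"]
    return ParadigmConfig(**p)


def preprocess_config_from(cfg: dict) -> PreprocessConfig:
    p = cfg["preprocess"]
    return PreprocessConfig(
        window_s=tuple(p["window_s"]), band=tuple(p["band"]), order=p["order"],
        target_fs=p["target_fs"], notch_hz=p["notch_hz"],
        hf_band=tuple(p["hf_band"]), z_thresh=p["z_thresh"],
        trial_fraction=p["trial_fraction"], amp_thresh_z=p["amp_thresh_z"],
        min_deviants=p["min_deviants"],
    )


def stats_config_from(cfg: dict) -> StatsConfig:
    s = cfg["stats"]
    return StatsConfig(n_perm=s["n_perm"], alpha=s["alpha"],
                       cluster_alpha=s["cluster_alpha"], equal_var=s["equal_var"])


def rules_from(cfg: dict) -> ClassificationRules:
    r = cfg["components"]
    return ClassificationRules(
        gamma_min_hz=r["gamma_min_hz"], pe_split_s=r["pe_split_s"],
        pred_band_hz=tuple(r["pred_band_hz"]),
        pred_min_duration_s=r["pred_min_duration_s"],
    )


def fixture_small(seed: int = 20220217) -> SyntheticRecording:
    """Deterministic miniature recording for fast tests: 8 channels, one
    10-trial test block (2 deviants), short habituation, strong components
    with zero latency jitter."""
    pcfg = ParadigmConfig(
        n_habituation=4, block_size=10, deviant_fraction=0.2, n_test_blocks=1
    )
    run = build_run("xx", "xY|xx", pcfg, seed=child_seed(seed, "fixture-run"))
    layout = default_layout(
        {"frontal": 2, "auditory_core": 2, "auditory_belt_parabelt": 2,
         "STR": 1, "other": 1}
    )
    fs = 1000.0
    background = simulate_background(
        layout, run.duration_s + 2.0, fs, exponent=1.5,
        line_hz=50.0, line_amplitude=0.1,
        seed=child_seed(seed, "fixture-background"),
    )
    comps = [
        ComponentSpec(
            name="PE1", band_hz=(60.0, 110.0), latency_mean_s=0.074,
            latency_sd_s=0.0, envelope_duration_s=0.10,
            amplitude_mean=0.25, amplitude_sd=0.08,
            target_rois=("auditory_core", "auditory_belt_parabelt"),
            active_conditions=("xY|xx",),
        ),
        ComponentSpec(
            name="PRED", band_hz=(12.0, 30.0), latency_mean_s=0.15,
            latency_sd_s=0.0, envelope_duration_s=0.45,
            amplitude_mean=0.7, amplitude_sd=0.1, sign="decrease",
            latency_anchor="start",
            target_rois=("frontal", "auditory_belt_parabelt"),
            active_conditions=("xY|xx",),
        ),
    ]
    return inject_components(
        background, run, comps, CouplingSpec(), fs=fs, layout=layout,
        seed=child_seed(seed, "fixture-inject"),
    )


def write_bundle(bundle: ResultsBundle, out_dir) -> None:
    """Write the TSV/JSON artifacts of a results bundle plus a log file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for run, df in bundle.qc.items():
        write_table(df, out / f"qc_{run}.tsv")
    for name, df in bundle.cluster_tables.items():
        write_table(df, out / f"clusters_{name}.tsv")
    write_json(bundle.component_report, out / "components.json")
    write_table(bundle.correlation_panel, out / "correlation_panel.tsv")
    write_json(bundle.provenance, out / "provenance.json")
    (out / "analysis.log").write_text("\n".join(bundle.log) + "\n")
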