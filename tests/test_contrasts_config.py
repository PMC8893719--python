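import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest
import yaml

from hierseq.config import (
    DEFAULTS,
    child_seed,
    fixture_small,
    load_config,
    write_bundle,
)
from hierseq.contrasts import (
    ContrastSpec,
    StatsConfig,
    default_contrasts,
    run_contrast,
    run_full_analysis,
)
from hierseq.experiments import simulate_task_run
from hierseq.fileio import SchemaError, read_table, write_table
from hierseq.paradigm import ParadigmConfig
from hierseq.synth import default_components, omission_component
from hierseq.tfr import TFRGrid, concat_tfrsets

from conftest import make_tfrset


def test_contrast_spec_validation():
    with pytest.raises(ValueError, match="disjoint"):
        ContrastSpec("bad", "xx|xx", "xx|xx")
    with pytest.raises(ValueError, match="sub-contrasts"):
        ContrastSpec("bad", combine="conjunction", sub_contrasts=())
    names = {c.name for c in default_contrasts()}
    assert {"local_novelty", "global_only", "local_and_global",
            "omission_xx", "omission_xY", "omission_diff"} <= names


def _two_condition_pool(effect_channels_first, effect_channels_second, seed=0):
    """Pool with four conditions; listed channels carry a gamma-band effect
    in the (deviant - standard) direction of each sub-contrast."""
    rng = np.random.default_rng(seed)
    shape = (2, 10, 12)  # channels x freqs x times

    def group(cond, role, bump):
        x = rng.standard_normal((8,) + shape)
        for ch in bump:
            x[:, ch, 3:6, 4:8] += 3.0
        return make_tfrset(x, condition=cond, role=role)

    pool = concat_tfrsets([
        group("xY|xx", "deviant", effect_channels_first),
        group("xx|xx", "standard", []),
        group("xY|xY", "standard", effect_channels_second),
        group("xx|xY", "deviant", []),
    ])
    return pool


def test_conjunction_is_intersection_of_same_sign_responsiveness():
    # channel 0 responds in both sub-contrasts, channel 1 only in the first
    pool = _two_condition_pool([0, 1], [0])
    spec = ContrastSpec(
        "local_novelty", combine="conjunction",
        sub_contrasts=(ContrastSpec("s1", "xY|xx", "xx|xx"),
                       ContrastSpec("s2", "xY|xY", "xx|xY")),
    )
    res = run_contrast(spec, pool, StatsConfig(n_perm=200), seed=1)
    subs = [r.responsive_channels for r in res.results]
    assert res.responsive_channels <= subs[0] and res.responsive_channels <= subs[1]
    assert 0 in res.responsive_channels
    assert 1 not in res.responsive_channels


def test_empty_selector_raises():
    pool = _two_condition_pool([0], [0])
    with pytest.raises(ValueError, match="matches no trials"):
        run_contrast(ContrastSpec("x", "x_|xx", "xx|xx"), pool,
                     StatsConfig(n_perm=50), seed=0)


def _simulated_runs(seed=77):
    pcfg = ParadigmConfig(n_habituation=4, block_size=25, n_test_blocks=1)
    rois = {"frontal": 2, "auditory_core": 2, "auditory_belt_parabelt": 2,
            "STR": 1, "other": 1}
    comps = default_components()
    kw = dict(paradigm=pcfg, roi_counts=rois)
    return {
        "xx": simulate_task_run("xx", "xY|xx", comps,
                                seed=child_seed(seed, "xx"), **kw),
        "xY": simulate_task_run("xY", "xx|xY", comps,
                                seed=child_seed(seed, "xY"), **kw),
        "om_xY": simulate_task_run("xY", "x_|xY", [omission_component()],
                                   seed=child_seed(seed, "om"), **kw),
        "om_block": simulate_task_run("omission_block", None, [],
                                      seed=child_seed(seed, "blk"), **kw),
    }


@pytest.fixture(scope="module")
def small_bundle():
    recs = _simulated_runs()
    grid = TFRGrid.default(0.8, fstep=6.0)
    return recs, run_full_analysis(
        recs, grid=grid, stats_cfg=StatsConfig(n_perm=120), seed=5
    )


def test_full_analysis_detects_components_end_to_end(small_bundle):
    _, bundle = small_bundle
    assert "local_and_global" in bundle.cluster_tables
    assert "global_only" in bundle.cluster_tables
    assert "omission_xY" in bundle.cluster_tables
    # omission_xx has no matching run and is skipped with a log entry
    assert "omission_xx" not in bundle.cluster_tables
    assert any("omission_xx" in line for line in bundle.log)
    assert "PE1" in bundle.component_report
    assert bundle.component_report["PE1"]["channels"]
    assert "PE2" in bundle.component_report
    assert bundle.provenance["config_hash"]
    assert isinstance(bundle.correlation_panel, pd.DataFrame)


def test_full_analysis_is_reproducible(small_bundle):
    recs, bundle = small_bundle
    again = run_full_analysis(
        recs, grid=TFRGrid.default(0.8, fstep=6.0),
        stats_cfg=StatsConfig(n_perm=120), seed=5,
    )
    for name, table in bundle.cluster_tables.items():
        pdt.assert_frame_equal(table, again.cluster_tables[name])
    pdt.assert_frame_equal(bundle.correlation_panel, again.correlation_panel)
    assert bundle.provenance["config_hash"] == again.provenance["config_hash"]


def test_bundle_written_as_tables_and_json(small_bundle, tmp_path):
    _, bundle = small_bundle
    write_bundle(bundle, tmp_path)
    assert (tmp_path / "components.json").exists()
    assert (tmp_path / "correlation_panel.tsv").exists()
    assert (tmp_path / "provenance.json").exists()
    assert (tmp_path / "clusters_local_and_global.tsv").exists()
    assert (tmp_path / "analysis.log").exists()


# ---------------------------------------------------------------------------
# configuration and fixtures
# ---------------------------------------------------------------------------

def test_empty_config_yields_all_defaults(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("")
    assert load_config(path) == DEFAULTS
    assert load_config(None) == DEFAULTS


def test_unknown_keys_are_named(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump({"tfr": {"windowz": 3}, "nonsense": 1}))
    with pytest.raises(ValueError) as err:
        load_config(path)
    assert "tfr.windowz" in str(err.value)
    assert "nonsense" in str(err.value)


def test_partial_override_preserves_other_defaults(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump({"stats": {"n_perm": 200}}))
    cfg = load_config(path)
    assert cfg["stats"]["n_perm"] == 200
    assert cfg["stats"]["alpha"] == DEFAULTS["stats"]["alpha"]


def test_fixture_small_is_deterministic():
    a = fixture_small()
    b = fixture_small()
    np.testing.assert_array_equal(a.signal, b.signal)
    pdt.assert_frame_equal(a.events, b.events)
    pdt.assert_frame_equal(a.ground_truth, b.ground_truth)


def test_tsv_schema_validation(tmp_path):
    df = pd.DataFrame({"onset": [0.0], "duration": [0.05]})
    path = tmp_path / "t.tsv"
    write_table(df, path)
    with pytest.raises(SchemaError, match="frequency"):
        read_table(path, required=["onset", "duration", "frequency"])


def test_child_seed_is_stable_and_bounded():
    assert child_seed(1, "a") == child_seed(1, "a")
    assert child_seed(1, "a") != child_seed(1, "b")
    assert 0 <= child_seed(2**20, "stream") < 2**31
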