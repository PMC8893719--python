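import dataclasses

import h5py
import numpy as np
import pandas.testing as pdt
import pytest
from scipy import signal as sps

from hierseq.fileio import SchemaError
from hierseq.paradigm import ParadigmConfig, build_run
from hierseq.synth import (
    CouplingSpec,
    default_components,
    default_layout,
    inject_components,
    read_recording,
    simulate_background,
    write_recording,
)


def _psd_slope(x, fs, fmin=5.0, fmax=100.0):
    """Periodogram regression oracle: fitted log-log slope of the Welch PSD."""
    f, p = sps.welch(x, fs=fs, nperseg=4096)
    sel = (f >= fmin) & (f <= fmax)
    return np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]


@pytest.mark.parametrize("exponent,expected", [(0.0, 0.0), (1.0, -1.0)])
def test_background_psd_slope(exponent, expected):
    x = simulate_background(2, 120.0, 1000.0, exponent=exponent, seed=0)
    slope = np.mean([_psd_slope(ch, 1000.0) for ch in x])
    assert slope == pytest.approx(expected, abs=0.1)


def test_line_noise_shows_as_psd_peak():
    x = simulate_background(1, 60.0, 1000.0, exponent=0.0,
                            line_hz=50.0, line_amplitude=1.0, seed=1)
    f, p = sps.welch(x[0], fs=1000.0, nperseg=4096)
    assert f[np.argmax(p)] == pytest.approx(50.0, abs=0.5)


def test_background_determinism_and_validation():
    a = simulate_background(3, 5.0, 500.0, seed=9)
    b = simulate_background(3, 5.0, 500.0, seed=9)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        simulate_background(3, -1.0, 500.0, seed=0)


def _tiny_run(seed=0, task="xx", dev="xY|xx", n_blocks=1):
    cfg = ParadigmConfig(n_habituation=2, block_size=10, deviant_fraction=0.2,
                         n_test_blocks=n_blocks)
    return build_run(task, dev, cfg, seed=seed)


def _tiny_layout():
    return default_layout({"frontal": 2, "auditory_core": 2,
                           "auditory_belt_parabelt": 2, "STR": 1, "other": 1})


def test_zero_injection_leaves_background_untouched():
    run = _tiny_run()
    lay = _tiny_layout()
    bg = simulate_background(lay, run.duration_s + 2, 1000.0, seed=2)
    comps = [dataclasses.replace(default_components()[0],
                                 amplitude_mean=0.0, amplitude_sd=0.0)]
    rec = inject_components(bg, run, comps, CouplingSpec(), fs=1000.0,
                            layout=lay, seed=3)
    np.testing.assert_allclose(rec.signal, bg, atol=1e-12)


def test_deterministic_coupling_gives_perfect_amplitude_correlation():
    run = _tiny_run(n_blocks=3)
    lay = _tiny_layout()
    bg = simulate_background(lay, run.duration_s + 2, 1000.0, seed=2)
    pe1, pe2, _ = default_components()
    pe1 = dataclasses.replace(pe1, active_conditions=("xY|xx",), amplitude_sd=0.02)
    pe2 = dataclasses.replace(pe2, active_conditions=("xY|xx",))
    coupling = CouplingSpec(pe1_to_pe2_gain=1.0, noise_sd=0.0)
    rec = inject_components(bg, run, [pe1, pe2], coupling, fs=1000.0,
                            layout=lay, seed=4)
    gt = rec.ground_truth
    a1 = gt[gt["component"] == "PE1"].set_index("trial_index")["amplitude"]
    a2 = gt[gt["component"] == "PE2"].set_index("trial_index")["amplitude"]
    common = a1.index.intersection(a2.index)
    r = np.corrcoef(a1.loc[common], a2.loc[common])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-9)


def test_zero_latency_jitter_hits_reported_latency_exactly():
    run = _tiny_run()
    lay = _tiny_layout()
    bg = simulate_background(lay, run.duration_s + 2, 1000.0, seed=2)
    pe1 = dataclasses.replace(default_components()[0], latency_mean_s=0.074,
                              latency_sd_s=0.0, active_conditions=("xY|xx",))
    rec = inject_components(bg, run, [pe1], None, fs=1000.0, layout=lay, seed=5)
    gt = rec.ground_truth
    dev = gt[(gt["component"] == "PE1") & (gt["role"] == "deviant")]
    assert len(dev) == 2
    np.testing.assert_allclose(dev["latency_center_s"], 0.074)


def test_burst_energy_is_band_specific():
    """Energy a PE burst adds outside its band is < 5% of in-band energy."""
    run = _tiny_run()
    lay = _tiny_layout()
    bg = simulate_background(lay, run.duration_s + 2, 1000.0, seed=2)
    pe1 = dataclasses.replace(default_components()[0], latency_sd_s=0.0,
                              active_conditions=("xY|xx",))
    rec = inject_components(bg, run, [pe1], None, fs=1000.0, layout=lay, seed=6)
    diff = rec.signal - bg
    lo, hi = pe1.band_hz

    def band_energy(x, band):
        sos = sps.butter(4, band, btype="bandpass", fs=1000.0, output="sos")
        return float(np.sum(sps.sosfiltfilt(sos, x, axis=-1) ** 2))

    in_band = band_energy(diff, [lo - 5, hi + 5])
    out_band = band_energy(diff, [10, lo - 20]) + band_energy(diff, [hi + 25, 240])
    assert out_band < 0.05 * in_band


def test_ground_truth_amplitudes_match_configured_moments():
    """Over >=500 trials the realized amplitudes follow mean/SD within
    sampling error."""
    cfg = ParadigmConfig(n_habituation=2)
    lay = _tiny_layout()
    mean, sd = 0.5, 0.1
    pe1 = dataclasses.replace(
        default_components()[0], amplitude_mean=mean, amplitude_sd=sd,
        active_conditions=("xY|xY",),  # active on standards: many trials
    )
    amps = []
    for seed in range(9):
        run = build_run("xY", "xx|xY", cfg, seed=seed)
        bg = simulate_background(lay, run.duration_s + 2, 1000.0,
                                 exponent=0.0, seed=seed)
        rec = inject_components(bg, run, [pe1], None, fs=1000.0,
                                layout=lay, seed=100 + seed)
        amps.append(rec.ground_truth["amplitude"].to_numpy())
    amps = np.concatenate(amps)
    assert len(amps) >= 500
    se = sd / np.sqrt(len(amps))
    assert amps.mean() == pytest.approx(mean, abs=4 * se)
    assert amps.std() == pytest.approx(sd, rel=0.15)


def test_band_above_nyquist_rejected():
    run = _tiny_run()
    lay = _tiny_layout()
    bg = simulate_background(lay, run.duration_s + 2, 200.0, seed=2)
    bad = dataclasses.replace(default_components()[0], band_hz=(60.0, 110.0))
    with pytest.raises(ValueError, match="Nyquist"):
        inject_components(bg, run, [bad], None, fs=200.0, layout=lay, seed=0)


def test_recording_roundtrip_is_bitwise(tmp_path, fixture_rec):
    path = tmp_path / "rec.h5"
    write_recording(fixture_rec, path)
    back = read_recording(path)
    np.testing.assert_array_equal(back.signal, fixture_rec.signal)
    assert back.fs == fixture_rec.fs
    pdt.assert_frame_equal(back.events, fixture_rec.events, check_dtype=False)
    pdt.assert_frame_equal(back.ground_truth, fixture_rec.ground_truth,
                           check_dtype=False)
    assert tuple(back.layout.roi) == tuple(fixture_rec.layout.roi)


def test_missing_ground_truth_group_warns(tmp_path, fixture_rec):
    path = tmp_path / "rec.h5"
    write_recording(fixture_rec, path)
    with h5py.File(path, "a") as f:
        del f["ground_truth"]
    with pytest.warns(UserWarning, match="ground_truth"):
        back = read_recording(path)
    assert back.ground_truth.empty


def test_corrupted_events_table_names_missing_column(tmp_path, fixture_rec):
    path = tmp_path / "rec.h5"
    write_recording(fixture_rec, path)
    with h5py.File(path, "a") as f:
        del f["events"]["condition"]
    with pytest.raises(SchemaError, match="condition"):
        read_recording(path)


def test_null_runs_yield_nominal_cluster_rate():
    """With components off, the deviant-vs-standard cluster test flags
    channels at roughly the nominal rate (per-channel correction)."""
    from hierseq.cluster_stats import permutation_test
    from hierseq.experiments import ReducedScale, run_to_tfr, simulate_task_run

    sc = ReducedScale()
    hits = tests = 0
    for seed in range(5):
        rec = simulate_task_run("xx", "xY|xx", [], seed=seed,
                                paradigm=sc.paradigm,
                                roi_counts={"auditory_core": 4, "frontal": 4})
        t = run_to_tfr(rec, sc.grid, drop_habituation=True)
        dev = t.select(condition="xY|xx")
        std = t.select(condition="xx|xx")
        res = permutation_test(dev, std, n_perm=200, seed=1000 + seed)
        hits += len(res.responsive_channels)
        tests += t.n_channels
    # binomial(40, 0.05): P(>=8) < 1e-3
    assert hits / tests <= 0.2
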