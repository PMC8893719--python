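import itertools

import numpy as np
import pytest
from scipy import stats

from hierseq.cluster_stats import (
    TFCluster,
    form_clusters,
    latency_estimates,
    permutation_test,
    tmap,
)

from conftest import make_grid, make_tfrset


# ---------------------------------------------------------------------------
# t map
# ---------------------------------------------------------------------------

def test_identical_groups_give_zero_t():
    x = np.random.default_rng(0).standard_normal((4, 2, 5, 6))
    t, df = tmap(make_tfrset(x), make_tfrset(x.copy()))
    np.testing.assert_allclose(t, 0.0, atol=1e-5)
    assert df == 6


def test_t_sign_follows_mean_difference():
    rng = np.random.default_rng(1)
    base = rng.standard_normal((6, 1, 3, 3)) * 0.01
    t, _ = tmap(make_tfrset(base + 1.0), make_tfrset(base.copy()))
    assert np.all(t > 0)


def test_t_matches_hand_computed_pooled_formula():
    a_vals = np.array([1.2, 0.7, 1.9])
    b_vals = np.array([0.1, -0.4, 0.6])
    a = np.zeros((3, 1, 1, 1), dtype=np.float32)
    b = np.zeros((3, 1, 1, 1), dtype=np.float32)
    a[:, 0, 0, 0] = a_vals
    b[:, 0, 0, 0] = b_vals
    t, df = tmap(make_tfrset(a), make_tfrset(b))
    # textbook pooled two-sample t
    sp2 = (a_vals.var(ddof=1) * 2 + b_vals.var(ddof=1) * 2) / 4
    expected = (a_vals.mean() - b_vals.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert t[0, 0, 0] == pytest.approx(expected, rel=1e-5)
    assert df == 4
    # cross-check against scipy
    assert t[0, 0, 0] == pytest.approx(
        stats.ttest_ind(a_vals, b_vals, equal_var=True).statistic, rel=1e-5
    )


def test_degenerate_zero_variance_cell_flagged_as_zero():
    a = np.ones((3, 1, 2, 2), dtype=np.float32)
    t, _ = tmap(make_tfrset(a), make_tfrset(a * 1.0))
    np.testing.assert_array_equal(t, 0.0)


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def _flood_fill_oracle(mask):
    """Independent 4-connectivity component count by breadth-first search."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for i, j in np.argwhere(mask):
        if seen[i, j]:
            continue
        stack, cells = [(i, j)], []
        seen[i, j] = True
        while stack:
            y, x = stack.pop()
            cells.append((y, x))
            for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ny, nx = y + dy, x + dx
                if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                        and mask[ny, nx] and not seen[ny, nx]):
                    seen[ny, nx] = True
                    stack.append((ny, nx))
        comps.append(sorted(cells))
    return comps


def test_single_suprathreshold_cell_is_its_own_cluster():
    t = np.zeros((5, 5))
    t[2, 3] = 7.5
    clusters = form_clusters(t, df=10, cluster_alpha=0.05)
    assert len(clusters) == 1
    assert clusters[0].n_cells == 1
    assert clusters[0].mass == pytest.approx(7.5)
    assert clusters[0].sign == "pos"


def test_diagonal_cells_form_two_clusters():
    t = np.zeros((4, 4))
    t[1, 1] = 5.0
    t[2, 2] = 5.0
    assert len(form_clusters(t, df=10)) == 2


def test_opposite_sign_cell_splits_block_matching_flood_fill():
    t = np.full((3, 3), 6.0)
    t[1, 1] = -6.0
    clusters = form_clusters(t, df=20)
    pos = [c for c in clusters if c.sign == "pos"]
    neg = [c for c in clusters if c.sign == "neg"]
    assert len(neg) == 1 and neg[0].n_cells == 1
    oracle = _flood_fill_oracle(t > 0)
    assert len(pos) == len(oracle)
    assert sorted(c.n_cells for c in pos) == sorted(len(o) for o in oracle)
    assert sum(c.mass for c in pos) == pytest.approx(6.0 * 8)


def test_no_suprathreshold_cells_is_empty_list():
    assert form_clusters(np.zeros((4, 4)), df=10) == []


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _effect_data(delta, seed=0, n1=6, n2=6, shape=(8, 10)):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n1, 1) + shape)
    b = rng.standard_normal((n2, 1) + shape)
    a[:, 0, 3:5, 4:7] += delta
    return make_tfrset(a), make_tfrset(b)


def test_permutation_is_deterministic_under_seed():
    a, b = _effect_data(3.0)
    r1 = permutation_test(a, b, n_perm=200, seed=5)
    r2 = permutation_test(a, b, n_perm=200, seed=5)
    assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]
    r3 = permutation_test(a, b, n_perm=200, seed=6)
    assert [tuple(map(tuple, c.cells)) for c in r1.clusters] == [
        tuple(map(tuple, c.cells)) for c in r3.clusters
    ]


def test_observed_clusters_invariant_to_trial_order():
    a, b = _effect_data(3.0)
    perm = np.random.default_rng(2).permutation(a.n_trials)
    a_shuf = make_tfrset(a.power[perm])
    r1 = permutation_test(a, b, n_perm=100, seed=1)
    r2 = permutation_test(a_shuf, b, n_perm=100, seed=1)
    assert sorted(round(c.mass, 6) for c in r1.clusters) == sorted(
        round(c.mass, 6) for c in r2.clusters
    )


def test_scaling_an_effect_up_never_raises_its_p():
    ps = []
    for delta in (1.5, 4.0):
        a, b = _effect_data(delta, seed=3)
        res = permutation_test(a, b, n_perm=300, seed=9)
        ps.append(min(c.p_value for c in res.clusters))
    assert ps[1] <= ps[0]


def test_overwhelming_effect_reaches_minimum_p():
    a, b = _effect_data(25.0, seed=4)
    res = permutation_test(a, b, n_perm=500, seed=2)
    assert min(c.p_value for c in res.clusters) == pytest.approx(1 / 501)


def test_input_validation():
    a, b = _effect_data(1.0)
    with pytest.raises(ValueError, match="n_perm"):
        permutation_test(a, b, n_perm=0)
    tiny = make_tfrset(a.power[:1])
    with pytest.raises(ValueError):
        permutation_test(tiny, make_tfrset(b.power[:1]), n_perm=10)


def _max_cluster_mass_oracle(a_vals, b_vals, thr):
    """Plain-python max |cluster mass| for one labeled split."""
    n1 = a_vals.shape[0]
    m1, m2 = a_vals.mean(0), b_vals.mean(0)
    v1, v2 = a_vals.var(0, ddof=1), b_vals.var(0, ddof=1)
    n2 = b_vals.shape[0]
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t[~np.isfinite(t)] = 0.0
    best = 0.0
    for sign in (1, -1):
        for comp in _flood_fill_oracle(sign * t > thr):
            mass = abs(sum(t[c] for c in comp))
            best = max(best, mass)
    return best


def test_monte_carlo_p_matches_exhaustive_enumeration():
    """3 vs 3 toy data: the Monte-Carlo cluster p agrees with the exact p
    from all 20 label assignments within Monte-Carlo error."""
    rng = np.random.default_rng(7)
    shape = (4, 5)
    # single precision throughout: the TFR container stores float32, and
    # the enumeration oracle must see the identical values
    a_vals = (rng.standard_normal((3,) + shape) + 1.6).astype(np.float32).astype(float)
    b_vals = rng.standard_normal((3,) + shape).astype(np.float32).astype(float)
    a = make_tfrset(a_vals[:, None])
    b = make_tfrset(b_vals[:, None])
    n_perm = 2000
    res = permutation_test(a, b, n_perm=n_perm, seed=11)
    assert res.clusters, "toy effect should form at least one cluster"
    obs = max(abs(c.mass) for c in res.clusters)
    p_mc = min(c.p_value for c in res.clusters if abs(c.mass) == obs)

    thr = stats.t.ppf(0.975, 4)
    pooled = np.concatenate([a_vals, b_vals])
    count = 0
    for pick in itertools.combinations(range(6), 3):
        rest = [i for i in range(6) if i not in pick]
        null = _max_cluster_mass_oracle(pooled[list(pick)], pooled[rest], thr)
        count += null >= obs - 1e-4 * max(obs, 1.0)
    p_exact = count / 20
    mc_se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
    assert abs(p_mc - p_exact) <= 2 * mc_se + 2 / n_perm


# ---------------------------------------------------------------------------
# latency estimates
# ---------------------------------------------------------------------------

def _cluster(cells, t_vals):
    cells = np.asarray(cells)
    t_vals = np.asarray(t_vals, float)
    return TFCluster(channel=0, cells=cells, cell_t=t_vals,
                     mass=float(t_vals.sum()), sign="pos")


def test_latency_onset_and_peak_arithmetic():
    grid = make_grid(times=np.arange(0.0, 2.0, 0.02))
    # cells at grid times 0.90..1.10, max |t| at 1.00; fifth tone at 0.80
    idx = np.arange(45, 56)
    cells = np.c_[np.zeros_like(idx), idx]
    t_vals = np.where(idx == 50, 9.0, 3.0)
    onset, peak = latency_estimates(_cluster(cells, t_vals), grid, 0.80)
    assert onset == pytest.approx(0.10)
    assert peak == pytest.approx(0.20)


def test_single_cell_cluster_onset_equals_peak():
    grid = make_grid(times=np.arange(0.0, 2.0, 0.02))
    onset, peak = latency_estimates(_cluster([[0, 50]], [4.0]), grid, 0.80)
    assert onset == peak == pytest.approx(0.20)


def test_peak_invariant_to_weak_neighbours():
    grid = make_grid(times=np.arange(0.0, 2.0, 0.02))
    base = _cluster([[0, 50]], [8.0])
    grown = _cluster([[0, 49], [0, 50], [0, 51]], [2.1, 8.0, 2.1])
    assert latency_estimates(base, grid, 0.8)[1] == latency_estimates(
        grown, grid, 0.8
    )[1]
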