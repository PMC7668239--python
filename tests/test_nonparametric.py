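"""Rank statistics against independent oracles (scipy, brute force, closed form)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pbroutes import nonparametric as NP


# -- midranks ---------------------------------------------------------------

@pytest.mark.parametrize(
    "x, expected",
    [
        ((10, 20, 30), (1, 2, 3)),
        ((5, 5, 9), (1.5, 1.5, 3)),
        ((7, 7, 7, 7), (2.5, 2.5, 2.5, 2.5)),
    ],
)
def test_midranks_examples(x, expected):
    assert NP.midranks(x).ranks.tolist() == list(expected)


@settings(max_examples=100)
@given(st.lists(st.integers(min_value=-20, max_value=20), min_size=1, max_size=30))
def test_midranks_match_scipy_and_sum_rule(values):
    ranked = NP.midranks(values)
    n = len(values)
    assert ranked.ranks.sum() == pytest.approx(n * (n + 1) / 2)
    np.testing.assert_allclose(ranked.ranks, sps.rankdata(values))


def test_midranks_reject_nonfinite():
    with pytest.raises(ValueError):
        NP.midranks([1.0, float("nan")])


# -- Spearman ---------------------------------------------------------------

def test_spearman_study_correlations(study_workers, study_hand_sums):
    """Blood Pb vs hand dose sums: rho 0.964 (left), 0.893 (right), exact p."""
    blood = study_workers.set_index("worker_id")["blood_pb_ugdl"]
    blood = blood.reindex(study_hand_sums.index).to_numpy()
    left = NP.spearman(blood, study_hand_sums["left"].to_numpy())
    right = NP.spearman(blood, study_hand_sums["right"].to_numpy())
    assert left.statistic == pytest.approx(1 - 6 * 2 / (7 * 48))   # d2 = 2
    assert right.statistic == pytest.approx(1 - 6 * 6 / (7 * 48))  # d2 = 6
    assert left.p_value == pytest.approx(14 / 5040)
    assert right.p_value == pytest.approx(62 / 5040)


def test_spearman_exact_p_matches_brute_force_oracle(study_workers, study_hand_sums):
    """Independent enumeration via the d-squared formula over all 7! permutations."""
    blood = study_workers.set_index("worker_id")["blood_pb_ugdl"]
    blood = blood.reindex(study_hand_sums.index).to_numpy()
    y = study_hand_sums["left"].to_numpy()
    rx = sps.rankdata(blood)
    ry = sps.rankdata(y)
    n = len(rx)

    def rho_d2(perm):
        d2 = sum((a - b) ** 2 for a, b in zip(rx, perm))
        return 1 - 6 * d2 / (n * (n**2 - 1))

    obs = abs(rho_d2(ry))
    hits = sum(
        abs(rho_d2(p)) >= obs - 1e-12 for p in itertools.permutations(ry)
    )
    result = NP.spearman(blood, y)
    assert result.p_value == pytest.approx(hits / math.factorial(n))
    assert hits == 14


def test_spearman_identity_and_constant():
    x = np.array([3.0, 1.0, 7.0, 5.0])
    assert NP.spearman(x, x).statistic == pytest.approx(1.0)
    with pytest.raises(ValueError):
        NP.spearman(x, np.ones_like(x))


def test_spearman_rho_matches_scipy_with_ties():
    rng = np.random.default_rng(7)
    x = rng.integers(0, 5, size=15).astype(float)
    y = rng.integers(0, 5, size=15).astype(float)
    ours = NP.spearman(x, y)
    ref_rho, ref_p = sps.spearmanr(x, y)
    assert ours.statistic == pytest.approx(ref_rho)
    assert ours.method == "spearman-t-approximation"
    assert ours.p_value == pytest.approx(ref_p, rel=1e-6)


@pytest.mark.parametrize("transform", [np.exp, lambda v: v**3, lambda v: 5 * v - 2])
def test_spearman_invariant_under_monotone_transform(transform, study_workers, study_hand_sums):
    blood = study_workers.set_index("worker_id")["blood_pb_ugdl"]
    blood = blood.reindex(study_hand_sums.index).to_numpy()
    y = study_hand_sums["left"].to_numpy()
    base = NP.spearman(blood, y)
    moved = NP.spearman(blood, transform(y))
    assert moved.statistic == pytest.approx(base.statistic)
    assert moved.p_value == pytest.approx(base.p_value)


def test_spearman_exact_and_t_agree_in_rejection_at_study_size(study_workers, study_hand_sums):
    blood = study_workers.set_index("worker_id")["blood_pb_ugdl"]
    blood = blood.reindex(study_hand_sums.index).to_numpy()
    for hand in ("left", "right"):
        y = study_hand_sums[hand].to_numpy()
        exact = NP.spearman(blood, y)
        approx = NP.spearman(blood, y, exact_max_n=0)
        assert (exact.p_value < 0.05) == (approx.p_value < 0.05)


# -- Kruskal-Wallis ---------------------------------------------------------

def test_kruskal_wallis_identical_groups():
    res = NP.kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kruskal_wallis_fully_separated_groups_direct_rank_value():
    res = NP.kruskal_wallis([[1, 2, 3, 4], [11, 12, 13, 14], [21, 22, 23, 24]])
    h_direct = 12 / (12 * 13) * 4 * ((2.5 - 6.5) ** 2 + 0 + (10.5 - 6.5) ** 2)
    assert res.statistic == pytest.approx(h_direct)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.lists(st.integers(0, 8), min_size=2, max_size=8),
        min_size=2, max_size=4,
    )
)
def test_kruskal_wallis_matches_scipy_with_ties(groups):
    pooled = [v for g in groups for v in g]
    if len(set(pooled)) <= 1:
        res = NP.kruskal_wallis(groups)
        assert res.statistic == 0.0
        return
    res = NP.kruskal_wallis(groups)
    ref = sps.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)
    assert res.statistic >= 0


def test_kruskal_wallis_two_groups_maps_to_rank_sum():
    """For two groups H equals the squared standardised Wilcoxon rank-sum z."""
    rng = np.random.default_rng(11)
    a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
    h = NP.kruskal_wallis([a, b]).statistic
    mw = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                          use_continuity=False)
    z = sps.norm.isf(mw.pvalue / 2)
    assert h == pytest.approx(z**2, rel=1e-6)


# -- Dunn's test ------------------------------------------------------------

def test_dunn_identical_groups_all_p_one():
    res = NP.dunns_test([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
    assert all(d["p_adjusted"] == 1.0 for d in res.comparisons.values())


def test_dunn_adjusted_at_least_raw_and_order_invariant():
    rng = np.random.default_rng(3)
    groups = [rng.normal(loc, 1, 5) for loc in (0, 1, 3)]
    res = NP.dunns_test(groups, labels=["a", "b", "c"])
    for d in res.comparisons.values():
        assert d["p_adjusted"] >= d["p_raw"]
    permuted = NP.dunns_test(groups[::-1], labels=["c", "b", "a"])
    for (a, b), d in res.comparisons.items():
        key = (a, b) if (a, b) in permuted.comparisons else (b, a)
        assert permuted.comparisons[key]["p_adjusted"] == pytest.approx(d["p_adjusted"])


def test_dunn_two_groups_equals_closed_form_z():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    b = [101.0, 102.0, 103.0, 104.0, 105.0]
    res = NP.dunns_test([a, b], labels=["lo", "hi"])
    d = res.comparisons[("lo", "hi")]
    n = 10
    z_expected = (3.0 - 8.0) / math.sqrt(n * (n + 1) / 12 * (1 / 5 + 1 / 5))
    assert d["z"] == pytest.approx(z_expected)
    assert d["p_adjusted"] == pytest.approx(d["p_raw"])  # single comparison


def test_dunn_holm_dominates_raw():
    rng = np.random.default_rng(5)
    groups = [rng.normal(loc, 1, 6) for loc in (0, 0.5, 2)]
    res = NP.dunns_test(groups, adjust="holm")
    ps = [d for d in res.comparisons.values()]
    assert all(d["p_adjusted"] >= d["p_raw"] for d in ps)


def test_dunn_index_vs_wrist_contrasts_significant(study_doses):
    """Both hands show more Pb on the index finger than the wrist."""
    groups, labels = [], []
    for hand in ("left", "right"):
        for site in ("palm", "wrist", "index"):
            sel = study_doses[(study_doses["hand"] == hand) & (study_doses["site"] == site)]
            groups.append(sel["dose_ug_cm2"].to_numpy(dtype=float))
            labels.append(f"{hand}:{site}")
    res = NP.dunns_test(
        groups, labels=labels,
        pairs=[("left:wrist", "left:index"), ("right:wrist", "right:index")],
    )
    for (a, b), d in res.comparisons.items():
        assert d["p_adjusted"] < 0.05
        assert d["z"] < 0  # wrist mean rank below index mean rank
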