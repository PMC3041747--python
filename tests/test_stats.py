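from itertools import combinations, product
from types import SimpleNamespace

import numpy as np
import pytest

from splicegc import stats as st


# --- independent oracles -----------------------------------------------------


def brute_rank_sum_p(a, b, alternative="two-sided"):
    """Exact p via direct enumeration of group assignments, scored with the
    pairwise-comparison (Mann-Whitney U) formulation rather than rank sums."""

    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
        return u

    pooled = list(a) + list(b)
    na = len(a)
    u_obs = u_stat(a, b)
    mean_u = na * len(b) / 2.0
    us = []
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    eps = 1e-9
    if alternative == "greater":
        return float(np.mean(us >= u_obs - eps))
    if alternative == "less":
        return float(np.mean(us <= u_obs + eps))
    return float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - eps))


def brute_signed_rank_p(diffs, alternative="two-sided"):
    from scipy.stats import rankdata

    nz = [d for d in diffs if d != 0]
    ranks = rankdata(np.abs(nz))
    w_obs = sum(r for r, d in zip(ranks, nz) if d > 0)
    total = ranks.sum()
    ws = []
    for signs in product([0, 1], repeat=len(nz)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    eps = 1e-9
    if alternative == "greater":
        return float(np.mean(ws >= w_obs - eps))
    if alternative == "less":
        return float(np.mean(ws <= w_obs + eps))
    center = total / 2.0
    return float(np.mean(np.abs(ws - center) >= abs(w_obs - center) - eps))


# --- rank-sum ----------------------------------------------------------------


def test_rank_sum_spec_example():
    r = st.rank_sum_test([1, 2, 3], [4, 5, 6])
    assert r.p_value == pytest.approx(0.1)
    assert r.n_a == r.n_b == 3


def test_rank_sum_identical_samples():
    r = st.rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert r.p_value == 1.0


def test_rank_sum_exact_matches_bruteforce(rng):
    for _ in range(25):
        na = int(rng.integers(2, 6))
        nb = int(rng.integers(2, 13 - na))
        # integer draws force ties into the enumeration
        a = rng.integers(0, 6, na).astype(float).tolist()
        b = rng.integers(0, 6, nb).astype(float).tolist()
        for alt in ("two-sided", "greater", "less"):
            got = st.rank_sum_test(a, b, alternative=alt).p_value
            want = brute_rank_sum_p(a, b, alt)
            assert got == pytest.approx(want, abs=1e-12), (a, b, alt)


def test_rank_sum_large_sample_approximation(rng):
    a = rng.normal(0, 1, 200)
    b = rng.normal(1, 1, 200)
    r = st.rank_sum_test(a, b, alternative="less")
    assert r.p_value < 1e-6
    assert r.n_a == 200


def test_rank_sum_power_at_planted_shift(rng):
    # rejection rate under a 1-sd shift, n=30/30, should be near its
    # simulated power (~0.96 at alpha=0.05); allow Monte-Carlo slack
    rej = 0
    for _ in range(100):
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        if st.rank_sum_test(a, b).p_value < 0.05:
            rej += 1
    assert 85 <= rej <= 100


def test_rank_sum_input_validation():
    with pytest.raises(ValueError):
        st.rank_sum_test([1.0], [2.0, 3.0])
    with pytest.raises(ValueError):
        st.rank_sum_test([1, 2], [3, 4], alternative="bogus")


# --- signed-rank -------------------------------------------------------------


def test_signed_rank_all_positive_exact():
    r = st.signed_rank_test(list(range(1, 11)), alternative="greater")
    assert r.p_value == pytest.approx(1 / 2**10)


def test_signed_rank_zeros_only():
    assert st.signed_rank_test([0.0, 0.0, 0.0]).p_value == 1.0


def test_signed_rank_antisymmetric_diffs():
    diffs = [1.5, -1.5, 2.5, -2.5, 3.5, -3.5]
    r = st.signed_rank_test(diffs)
    ranks_total = sum(range(1, 7))
    assert r.statistic == pytest.approx(ranks_total / 2)
    assert r.p_value == 1.0


def test_signed_rank_exact_matches_bruteforce(rng):
    for _ in range(20):
        n = int(rng.integers(3, 12))
        diffs = rng.integers(-5, 6, n).astype(float).tolist()
        if all(d == 0 for d in diffs):
            continue
        for alt in ("two-sided", "greater", "less"):
            got = st.signed_rank_test(diffs, alternative=alt).p_value
            want = brute_signed_rank_p(diffs, alt)
            assert got == pytest.approx(want, abs=1e-12), (diffs, alt)


def test_signed_rank_large_sample(rng):
    diffs = rng.normal(0.5, 1.0, 100)
    r = st.signed_rank_test(diffs, alternative="greater")
    assert r.p_value < 0.01


def test_signed_rank_empty_raises():
    with pytest.raises(ValueError):
        st.signed_rank_test([])


# --- regression --------------------------------------------------------------


def test_regression_exact_line():
    r = st.gc_energy_regression([(0, 0), (1, -2), (2, -4)])
    assert r.slope == pytest.approx(-2.0)
    assert r.pearson_r == pytest.approx(-1.0)
    assert r.r_squared == pytest.approx(1.0)


def test_regression_sign_consistency(rng):
    pts = [(g, -0.5 * g + rng.normal(0, 1)) for g in rng.uniform(0, 100, 50)]
    r = st.gc_energy_regression(pts)
    assert np.sign(r.pearson_r) == np.sign(r.slope)
    assert r.r_squared == pytest.approx(r.pearson_r**2)


def test_regression_constant_gc_raises():
    with pytest.raises(ValueError):
        st.gc_energy_regression([(1, 0), (1, 1), (1, 2)])
    with pytest.raises(ValueError):
        st.gc_energy_regression([(1, 0), (2, 1)])


# --- GC-matched bins ---------------------------------------------------------


def test_gc_matched_null_mostly_nonsignificant(rng):
    ps = []
    for rep in range(10):
        groups = {
            "x": [(int(g), float(rng.normal(-30, 3))) for g in rng.normal(65, 10, 300)],
            "y": [(int(g), float(rng.normal(-30, 3))) for g in rng.normal(65, 10, 300)],
        }
        for _, res in st.gc_matched_compare(groups):
            if res is not None:
                ps.append(res.p_value)
    assert np.mean(np.array(ps) > 0.05) >= 0.8


def test_gc_matched_empty_bin_reported():
    groups = {
        "x": [(50, -1.0), (50, -2.0), (70, -1.0), (70, -2.0)],
        "y": [(50, -1.5), (50, -2.5)],
    }
    out = st.gc_matched_compare(groups, bins=[(49, 51), (69, 71)])
    assert out[0][1] is not None
    assert out[1][1] is None  # y has no windows there -> skipped


def test_gc_matched_no_testable_bin_raises():
    groups = {"x": [(10, -1.0)], "y": [(90, -1.0)]}
    with pytest.raises(ValueError):
        st.gc_matched_compare(groups, bins=[(49, 51)])


# --- distance-controlled pairing --------------------------------------------


def _site(pos, seq_name="s", strand="+"):
    return SimpleNamespace(seq_name=seq_name, strand=strand, junction_pos=pos)


def test_distance_pairs_threshold():
    alt = [(_site(10_000), -40.0)] * 8
    ref_near = [(_site(12_900), -35.0)]
    pairs, res = st.distance_controlled_pairs(alt, ref_near)
    assert len(pairs) == 8
    ref_far = [(_site(13_100), -35.0)]
    with pytest.raises(ValueError):
        st.distance_controlled_pairs(alt, ref_far)


def test_distance_pairs_tie_breaks_upstream():
    alt = [(_site(5_000), -40.0)] * 6
    refs = [(_site(4_800), -35.0), (_site(5_200), -36.0)]
    pairs, _ = st.distance_controlled_pairs(alt, refs)
    assert all(ref.junction_pos == 4_800 for _, ref in pairs)


def test_distance_pairs_respect_seq_and_strand():
    alt = [(_site(1_000), -40.0)] * 6
    refs = [(_site(1_100, strand="-"), -30.0), (_site(1_100, seq_name="t"), -30.0)]
    with pytest.raises(ValueError):
        st.distance_controlled_pairs(alt, refs)


# --- tissue rule -------------------------------------------------------------


def _event(*rows):
    return st.TissueEvent("e", "s", tuple(("t%d" % i, d, p) for i, (d, p) in enumerate(rows)))


@pytest.mark.parametrize(
    "rows,expected",
    [
        ([(0.12, 0.2)], "tissue_specific"),
        ([(0.03, 0.5), (0.03, 0.5)], "non_tissue_specific"),
        ([(0.07, 0.2)], "unclassified"),
        ([(0.10, 0.2)], "tissue_specific"),  # delta boundary is inclusive
        ([(0.10, 0.3)], "unclassified"),  # p boundary is strict both ways
        ([(0.04, 0.9)], "non_tissue_specific"),
        ([(0.2, 0.9)], "non_tissue_specific"),  # big delta, hopeless p
        ([(0.05, 0.2)], "unclassified"),
        ([(0.03, 0.1), (0.15, 0.1)], "tissue_specific"),  # ANY quantifier
    ],
)
def test_tissue_rule(rows, expected):
    assert st.classify_tissue_specific(_event(*rows)) == expected


def test_tissue_rule_partitions(rng):
    classes = set()
    for _ in range(300):
        rows = [(float(rng.uniform(0, 0.2)), float(rng.uniform(0, 1)))
                for _ in range(int(rng.integers(1, 5)))]
        classes.add(st.classify_tissue_specific(_event(*rows)))
    assert classes <= {"tissue_specific", "non_tissue_specific", "unclassified"}


def test_tissue_rule_validation():
    with pytest.raises(ValueError):
        st.TissueEvent("e", "s", ())
    with pytest.raises(ValueError):
        st.classify_tissue_specific(_event((0.1, 0.1)), delta_hi=1.5)


def test_comparison_result_p_range():
    with pytest.raises(ValueError):
        st.ComparisonResult("a", "b", 2, 2, 0, 0, 0, 1.5, False)
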