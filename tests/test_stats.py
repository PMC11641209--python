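"""Rank regression, slope-difference statistic and resampling inference."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from amphid import (
    LayoutParams,
    angle_anova,
    build_rank_table,
    cohort_regression,
    expected_pair_distance,
    generate_cohort,
    make_template,
    permutation_test,
    rank_means,
    slope_difference,
)
from amphid.exceptions import DegenerateRegressionError, EmptyCohortError, ValidationError
from conftest import make_rank_table, table_from_rank_values


def test_build_rank_table_covers_the_rank_multiset(clean_cohort):
    table = build_rank_table(clean_cohort[0][:1])
    assert sorted(table.records["rank"]) == [1, 2, 3, 3, 4, 4, 5, 5, 6, 6, 6]
    assert len(table.records) == 11


def test_incomplete_pairs_are_skipped(clean_cohort):
    worm = clean_cohort[0][0]
    import pandas as pd

    from amphid import WormSample

    df = worm.nuclei.copy()
    df = df[~((df["class"] == "AWC") & (df["side"] == "L"))]
    table = build_rank_table([WormSample("w", "WT", "microfluidic", df)])
    assert 2 not in set(table.records["rank"])
    assert len(table.records) == 10


def test_zero_noise_distances_match_generator_closed_form(template):
    params = LayoutParams(true_angle_deg=20.0, rank_displacement={4: 1.0}, n_worms=2, seed=3)
    cohort, _ = generate_cohort(params, template)
    table = build_rank_table(cohort)
    hinge = max(s.template_dv for s in template)
    expected = {s.name: expected_pair_distance(params, s, hinge) for s in template}
    for _, row in table.records.iterrows():
        assert row["distance_um"] == pytest.approx(expected[row["neuron_class"]], abs=1e-9)


def test_empty_cohort_rejected():
    with pytest.raises(EmptyCohortError):
        build_rank_table([])


def test_regression_exact_line_and_constant_cases():
    t = table_from_rank_values("t", {1: [10.0], 2: [12.0], 3: [14.0]})
    fit = cohort_regression(t)
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(8.0)
    flat = table_from_rank_values("f", {1: [5.0], 4: [5.0], 6: [5.0]})
    assert cohort_regression(flat).slope == pytest.approx(0.0)
    with pytest.raises(DegenerateRegressionError):
        cohort_regression(table_from_rank_values("d", {3: [1.0, 2.0]}))


def test_regression_matches_longhand_ols():
    rng = np.random.default_rng(11)
    t = make_rank_table("t", rng, n_worms=8)
    means = rank_means(t)
    x = np.array(sorted(means), float)
    y = np.array([means[int(r)] for r in x])
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    fit = cohort_regression(t)
    assert fit.slope == pytest.approx(slope, rel=1e-12)
    assert fit.rank_means == pytest.approx(means)


def test_per_worm_pooling_differs_when_worms_are_unbalanced():
    t = table_from_rank_values("t", {1: [10.0, 10.0, 16.0], 2: [5.0]})
    # pooled mean of rank 1 = 12; per-worm mean = (10+10+16)/3 with one worm each
    assert rank_means(t, "pooled")[1] == pytest.approx(12.0)
    with pytest.raises(ValidationError):
        rank_means(t, "median")


def test_slope_difference_identity_and_antisymmetry():
    rng = np.random.default_rng(21)
    a = make_rank_table("a", rng)
    b = make_rank_table("b", rng, rank_shift={2: 3.0, 3: 3.0, 4: 3.0})
    d = slope_difference(a, b)
    assert slope_difference(b, a) == pytest.approx(-d, rel=1e-12)
    assert slope_difference(a, a) == pytest.approx(0.0, abs=1e-12)
    # identity with difference-of-slopes when rank coverage matches
    assert d == pytest.approx(cohort_regression(a).slope - cohort_regression(b).slope, rel=1e-9)


def test_mutant_pattern_gives_positive_statistic():
    """Inner ranks (2-4) more separated in the mutant push the
    reference-minus-mutant slope positive, since they lie below the
    midpoint of the rank axis."""
    rng = np.random.default_rng(22)
    wt = make_rank_table("wt", rng, sd=0.0)
    mut = make_rank_table("mut", rng, sd=0.0, rank_shift={2: 3.0, 3: 3.0, 4: 3.0})
    assert slope_difference(wt, mut) > 0


def test_permutation_p_matches_exhaustive_enumeration():
    """Tiny two-rank instance: every within-rank reassignment enumerated."""
    wt = table_from_rank_values("wt", {1: [1.0, 2.0], 2: [3.0, 7.0]})
    mut = table_from_rank_values("mut", {1: [4.0, 6.0], 2: [2.0, 5.0]})
    res = permutation_test(wt, mut, n_perm=100_000, seed=0, alternative="less")
    ranks = np.array([1.0, 2.0])
    w = (ranks - ranks.mean()) / ((ranks - ranks.mean()) ** 2).sum()
    pools = {1: [1.0, 2.0, 4.0, 6.0], 2: [3.0, 7.0, 2.0, 5.0]}
    obs = res.observed
    count = total = 0
    for idx1 in itertools.combinations(range(4), 2):
        for idx2 in itertools.combinations(range(4), 2):
            d = []
            for rank, idx in ((1, idx1), (2, idx2)):
                pool = pools[rank]
                a = [pool[i] for i in idx]
                b = [pool[i] for i in range(4) if i not in idx]
                d.append(np.mean(a) - np.mean(b))
            slope = float(w @ np.array(d))
            total += 1
            count += slope <= obs + 1e-12
    exact = count / total
    assert res.p_value == pytest.approx(exact, abs=0.01)


def test_permutation_self_comparison_is_null():
    rng = np.random.default_rng(33)
    t = make_rank_table("t", rng)
    res = permutation_test(t, t, n_perm=4000, seed=1, alternative="greater")
    assert res.observed == pytest.approx(0.0, abs=1e-12)
    assert 0.4 < res.p_value <= 0.6
    assert 0 < res.p_value <= 1
    assert res.percentile_5 < 0 < res.percentile_95


def test_permutation_is_reproducible_and_alternatives_consistent():
    rng = np.random.default_rng(44)
    a = make_rank_table("a", rng)
    b = make_rank_table("b", rng, rank_shift={2: 2.0, 3: 2.0, 4: 2.0})
    r1 = permutation_test(a, b, n_perm=1000, seed=5)
    r2 = permutation_test(a, b, n_perm=1000, seed=5)
    assert r1.p_value == r2.p_value
    assert np.array_equal(r1.null_slopes, r2.null_slopes)
    less = permutation_test(a, b, n_perm=1000, seed=5, alternative="less")
    # add-one convention in both directions
    n_le = int(np.count_nonzero(r1.null_slopes <= r1.observed))
    n_ge = int(np.count_nonzero(r1.null_slopes >= r1.observed))
    assert less.p_value == pytest.approx((1 + n_le) / 1001)
    assert r1.p_value == pytest.approx((1 + n_ge) / 1001)


def test_bootstrap_mode_shares_the_statistic_and_is_valid():
    """The with-replacement mode is a sensitivity option: same observed
    statistic, valid p in (0, 1], reproducible under a fixed seed."""
    rng = np.random.default_rng(55)
    a = make_rank_table("a", rng)
    b = make_rank_table("b", rng, rank_shift={2: 3.0, 3: 3.0, 4: 3.0})
    perm = permutation_test(a, b, n_perm=2000, seed=2)
    boot = permutation_test(a, b, n_perm=2000, seed=2, method="bootstrap")
    assert boot.observed == perm.observed
    assert 0 < boot.p_value <= 1
    boot2 = permutation_test(a, b, n_perm=2000, seed=2, method="bootstrap")
    assert boot2.p_value == boot.p_value


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_slope_difference_antisymmetric_property(seed):
    rng = np.random.default_rng(seed)
    a = make_rank_table("a", rng, n_worms=4)
    b = make_rank_table("b", rng, n_worms=5)
    assert slope_difference(a, b) == pytest.approx(-slope_difference(b, a), rel=1e-9, abs=1e-12)


def test_permutation_power_under_the_inner_rank_pattern():
    """+3 µm at ranks 2-4, sigma 2 µm, 59 vs 70 worms: rejection > 0.8."""
    rng = np.random.default_rng(99)
    hits = 0
    reps = 60
    for _ in range(reps):
        wt = make_rank_table("wt", rng, n_worms=70, sd=2.0)
        mut = make_rank_table("mut", rng, n_worms=59, sd=2.0, rank_shift={2: 3.0, 3: 3.0, 4: 3.0})
        res = permutation_test(wt, mut, n_perm=500, seed=int(rng.integers(2**31)))
        hits += res.p_value < 0.05
    assert hits / reps > 0.8


def test_anova_examples_and_longhand_oracle():
    res = angle_anova({"a": [10.0, 12.0, 14.0], "b": [10.0, 12.0, 14.0]})
    assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    groups = {"g1": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0], "g2": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0], "g3": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]}
    res = angle_anova(groups)
    arrs = [np.array(v, float) for v in groups.values()]
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    f = (ssb / 2) / (ssw / (18 - 3))
    assert res.f_statistic == pytest.approx(f, rel=1e-12)
    assert res.group_sizes == {"g1": 6, "g2": 6, "g3": 6}
    with pytest.raises(ValidationError):
        angle_anova({"a": [1.0, 2.0]})
    with pytest.raises(ValidationError):
        angle_anova({"a": [1.0, 2.0], "b": [1.0]})


def test_anova_null_p_values_are_uniform():
    rng = np.random.default_rng(7)
    reps, n = 400, 12
    ps = []
    for _ in range(reps):
        g = {k: rng.normal(10, 3, n) for k in ("a", "b", "c")}
        ps.append(angle_anova(g).p_value)
    assert sps.kstest(ps, "uniform").pvalue > 0.01
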