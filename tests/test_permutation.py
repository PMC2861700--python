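"""Mate-vs-non-mate statistic, permutation test, aggregation, corrections."""

from __future__ import annotations

import math

import numpy as np
import pytest

from matekin import (
    Couple,
    CoupleSet,
    RelativePair,
    ScoringConfig,
    SimConfig,
    cohort_baseline,
    compute_identity,
    dunn_sidak,
    exhaustive_test,
    leave_one_out,
    mate_statistic,
    mc_standard_error,
    permutation_test,
    relatedness,
    run_aggregate,
    simulate_cohort,
)
from matekin.relatedness import CohortBaseline, IdentityMatrix, RelatednessMatrix

S10 = ScoringConfig(1.0)


def _relmatrix_from_couple_values(mate_r, cross_r):
    """2-couple relatedness matrix: diag(m x f) = mates, off-diag = cross."""
    ids = ("m1", "m2", "f1", "f2")
    r = np.full((4, 4), np.nan)
    vals = {
        ("m1", "f1"): mate_r[0],
        ("m2", "f2"): mate_r[1],
        ("m1", "f2"): cross_r[0],
        ("m2", "f1"): cross_r[1],
        ("m1", "m2"): 0.0,
        ("f1", "f2"): 0.0,
    }
    idx = {s: i for i, s in enumerate(ids)}
    for (a, b), v in vals.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    baseline = CohortBaseline(0.5, 6, ids)
    return RelatednessMatrix(ids, r, baseline), CoupleSet(
        [Couple("c1", "m1", "f1"), Couple("c2", "m2", "f2")]
    )


def test_mate_statistic_hand_example():
    rel, couples = _relmatrix_from_couple_values([-0.1, -0.3], [0.1, 0.3])
    s = mate_statistic(rel, couples)
    assert s.r_mean_mates == pytest.approx(-0.2)
    assert s.r_mean_nonmates == pytest.approx(0.2)
    sd = np.std([0.1, 0.3], ddof=1)
    assert s.r_sd_nonmates == pytest.approx(sd)
    assert s.z_score == pytest.approx(-0.4 / sd)
    assert s.n_couples == 2


def test_mate_statistic_degenerate_and_sign():
    rel, couples = _relmatrix_from_couple_values([0.2, 0.2], [0.2, 0.2])
    s = mate_statistic(rel, couples)
    assert s.r_mean_mates == pytest.approx(s.r_mean_nonmates)
    assert not s.z_defined  # zero non-mate SD
    rel2, couples2 = _relmatrix_from_couple_values([-0.5, -0.4], [0.1, 0.2])
    assert mate_statistic(rel2, couples2).z_score < 0  # mates below all non-mates


def test_median_statistic_variant():
    rel, couples = _relmatrix_from_couple_values([-0.1, -0.3], [0.1, 0.3])
    s = mate_statistic(rel, couples, statistic="median")
    assert s.r_mean_mates == pytest.approx(np.median([-0.1, -0.3]))
    p_med = permutation_test(rel, couples, n_trials=500, seed=1, statistic="median")
    assert 0.0 <= p_med.p_value <= 1.0


@pytest.mark.parametrize(
    "alpha,n,expected",
    [
        (0.05, 1000, 0.0068920),  # approximately 14% of alpha
        (0.05, 100_000, 0.00068920),  # 100x trials -> SE / 10
        (0.5, 1, 0.5),  # maximal variance
    ],
)
def test_mc_standard_error(alpha, n, expected):
    assert mc_standard_error(alpha, n) == pytest.approx(expected, rel=1e-4)


def test_mc_standard_error_is_14pct_of_alpha():
    assert 100 * mc_standard_error(0.05, 1000) / 0.05 == pytest.approx(14, abs=0.3)


@pytest.mark.parametrize(
    "alpha,k,expected4dp",
    [(0.05, 2, 0.0253), (0.05, 4, 0.0127), (0.05, 1, 0.05), (0.01, 3, 0.0033)],
)
def test_dunn_sidak(alpha, k, expected4dp):
    spec = dunn_sidak(alpha, k)
    assert round(spec.alpha_prime, 4) == expected4dp
    assert spec.alpha_prime <= alpha
    assert spec.alpha_prime == pytest.approx(1 - (1 - alpha) ** (1 / k))


def test_two_couples_exhaustive_vs_monte_carlo():
    rel, couples = _relmatrix_from_couple_values([-0.1, -0.3], [0.1, 0.3])
    exact = exhaustive_test(rel, couples)  # only 2 pairings exist
    mc = permutation_test(rel, couples, n_trials=10_000, seed=5).p_value
    assert abs(mc - exact) <= 3 * math.sqrt(exact * (1 - exact) / 10_000) + 1e-9


@pytest.mark.parametrize("sidedness", ["two", "one-low", "one-high"])
def test_small_cohort_exhaustive_oracle(small_cohort, sidedness):
    """Monte-Carlo P converges to the exact all-pairings P for 5 couples."""
    panel, _, _, couples = small_cohort
    identity = compute_identity(panel, S10, couples.members)
    rel = relatedness(identity, cohort_baseline(identity, couples.members))
    exact = exhaustive_test(rel, couples, sidedness=sidedness)
    n = 10_000
    mc = permutation_test(rel, couples, n_trials=n, sidedness=sidedness, seed=9)
    tol = 3 * math.sqrt(max(exact * (1 - exact), 1e-9) / n)
    assert abs(mc.p_value - exact) <= tol
    assert mc.mc_se == pytest.approx(
        math.sqrt(mc.p_value * (1 - mc.p_value) / n), abs=1e-12
    )


def test_sidedness_agrees_with_z_direction(small_cohort):
    panel, _, _, couples = small_cohort
    identity = compute_identity(panel, S10, couples.members)
    rel = relatedness(identity, cohort_baseline(identity, couples.members))
    s = mate_statistic(rel, couples)
    p_low = exhaustive_test(rel, couples, sidedness="one-low")
    p_high = exhaustive_test(rel, couples, sidedness="one-high")
    if s.r_mean_mates < s.r_mean_nonmates:
        assert p_low <= p_high
    elif s.r_mean_mates > s.r_mean_nonmates:
        assert p_high <= p_low


def test_permutation_determinism_and_identity_exclusion():
    rel, couples = _relmatrix_from_couple_values([-0.1, -0.3], [0.1, 0.3])
    a = permutation_test(rel, couples, n_trials=2000, seed=123)
    b = permutation_test(rel, couples, n_trials=2000, seed=123)
    assert a == b
    # with the real pairing disallowed and k=2, every trial is the swap
    swapped = permutation_test(
        rel, couples, n_trials=500, seed=1, allow_real_couples=False
    )
    assert swapped.p_value in (0.0, 1.0)
    # with real couples allowed, P is bounded below by the identity frequency
    allowed = permutation_test(rel, couples, n_trials=2000, seed=2)
    assert allowed.p_value > 0


def _cohort_with_cross_couple_relative():
    panel, sheet, truth = simulate_cohort(
        SimConfig(n_couples=8, n_snps=600, planted_relatives=("full-sib",), seed=11)
    )
    couples = CoupleSet.from_sample_sheet(sheet)
    a, b, _ = truth.relative_pairs[0]
    return panel, couples, [RelativePair(a, b, 0.5, 0.2)]


def test_run_aggregate_no_relatives_equals_single(small_cohort):
    panel, _, _, couples = small_cohort
    agg = run_aggregate(panel, S10, couples, [], None, n_trials=500, seed=4)
    assert len(agg.records) == 1
    assert agg.aggregate_p == agg.records[0].test.p_value
    assert agg.aggregate_z == agg.records[0].summary.z_score
    assert agg.p_range == (agg.aggregate_p, agg.aggregate_p)


def test_run_aggregate_mean_and_range_over_permutations():
    panel, couples, relatives = _cohort_with_cross_couple_relative()
    agg = run_aggregate(panel, S10, couples, relatives, None, n_trials=400, seed=8)
    assert len(agg.records) == 2  # either sib's couple can be excluded
    ps = [r.test.p_value for r in agg.records]
    zs = [r.summary.z_score for r in agg.records]
    assert agg.aggregate_p == pytest.approx(np.mean(ps))
    assert agg.aggregate_z == pytest.approx(np.mean(zs))
    assert agg.p_range == (min(ps), max(ps))
    assert min(ps) <= agg.aggregate_p <= max(ps)
    for rec in agg.records:
        assert rec.summary.n_couples == 7


def test_run_aggregate_deterministic_rerun():
    panel, couples, relatives = _cohort_with_cross_couple_relative()
    a = run_aggregate(panel, S10, couples, relatives, None, n_trials=300, seed=21)
    b = run_aggregate(panel, S10, couples, relatives, None, n_trials=300, seed=21)
    assert a.to_frame().equals(b.to_frame())
    assert (a.aggregate_p, a.aggregate_z) == (b.aggregate_p, b.aggregate_z)


def test_run_aggregate_maf_timing_after_recomputes_per_permutation():
    panel, couples, relatives = _cohort_with_cross_couple_relative()
    before = run_aggregate(
        panel, S10, couples, relatives, None, n_trials=200, seed=2,
        maf_threshold=0.05, maf_timing="before",
    )
    after = run_aggregate(
        panel, S10, couples, relatives, None, n_trials=200, seed=2,
        maf_threshold=0.05, maf_timing="after",
    )
    assert len(before.records) == len(after.records) == 2
    # both modes produce finite, comparable results on the same cohort
    assert abs(before.aggregate_z - after.aggregate_z) < 0.5


def _identity_with_planted_dissimilar_couple(k=8, seed=0):
    """Hand-built Q matrix: homogeneous cohort, one extreme-dissimilar couple."""
    rng = np.random.default_rng(seed)
    ids = tuple(f"m{i}" for i in range(k)) + tuple(f"f{i}" for i in range(k))
    n = 2 * k
    q = 0.7 + 0.01 * rng.standard_normal((n, n))
    q = (q + q.T) / 2
    idx = {s: i for i, s in enumerate(ids)}
    q[idx["m0"], idx["f0"]] = q[idx["f0"], idx["m0"]] = 0.5  # planted outlier
    np.fill_diagonal(q, np.nan)
    m = IdentityMatrix(ids, q, np.full((n, n), 100), S10)
    couples = CoupleSet([Couple(f"c{i}", f"m{i}", f"f{i}") for i in range(k)])
    return m, couples


def test_leave_one_out_identifies_planted_outlier():
    identity, couples = _identity_with_planted_dissimilar_couple()
    res = leave_one_out(identity, couples, n_trials=1500, seed=13)
    assert len(res.table) == len(couples)  # one row per dropped couple
    assert res.most_dissimilar_couple == "c0"
    assert res.most_extreme_couple == "c0"
    full_identity = identity
    baseline = cohort_baseline(full_identity, couples.members)
    rel = relatedness(full_identity, baseline)
    p_full = permutation_test(rel, couples, n_trials=1500, seed=13).p_value
    p_by_couple = dict(zip(res.table["dropped_couple"], res.table["p"]))
    moved = {c: abs(p - 0.5) for c, p in p_by_couple.items()}
    # dropping the planted couple moves P toward 0.5 more than any other drop
    assert moved["c0"] == min(moved.values())
    assert abs(p_by_couple["c0"] - 0.5) < abs(p_full - 0.5)


def test_leave_one_out_requires_three_couples():
    rel, couples = _relmatrix_from_couple_values([-0.1, -0.3], [0.1, 0.3])
    identity = IdentityMatrix(rel.sample_ids, rel.r, np.full((4, 4), 10), S10)
    with pytest.raises(ValueError, match="at least 3"):
        leave_one_out(identity, couples, n_trials=10, seed=0)
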