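"""Identity coefficients Q, cohort baseline, and normalized relatedness R."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from matekin import (
    ScoringConfig,
    cohort_baseline,
    compute_identity,
    per_snp_identity,
    relatedness,
    self_identity,
)

from conftest import brute_force_q, build_panel

S05 = ScoringConfig(0.5)
S10 = ScoringConfig(1.0)


@pytest.mark.parametrize(
    "a,b,scoring,expected",
    [
        (("A", "A"), ("A", "A"), S05, 1.0),
        (("A", "G"), ("A", "G"), S05, 0.5),  # het-het = 50% variant
        (("A", "G"), ("A", "G"), S10, 1.0),  # het-het = 100% variant
        (("A", "A"), ("A", "G"), S05, 0.5),
        (("A", "A"), ("A", "G"), S10, 0.5),  # hom-het unaffected by s
        (("A", "A"), ("G", "G"), S05, 0.0),
        (("G", "A"), ("A", "G"), S10, 1.0),  # unordered
        (None, ("A", "A"), S05, None),
        (("A", "A"), None, S10, None),
    ],
)
def test_per_snp_identity_table(a, b, scoring, expected):
    assert per_snp_identity(a, b, scoring) == expected


def test_scoring_config_bounds():
    ScoringConfig(0.0)
    ScoringConfig(0.75)
    with pytest.raises(ValueError):
        ScoringConfig(2.0)
    with pytest.raises(ValueError):
        ScoringConfig(-0.1)


def _two_sample_panel():
    # a = {AA, AG, GG}, b = {AA, GG, AG}
    return build_panel(
        [("rs1", "6", 1, "A", "G"), ("rs2", "6", 2, "A", "G"), ("rs3", "6", 3, "A", "G")],
        ["a", "b"],
        [[0, 1, 2], [0, 2, 1]],
    )


def test_compute_identity_hand_example():
    m = compute_identity(_two_sample_panel(), S05)
    assert m.value("a", "b") == pytest.approx((1 + 0.5 + 0.5) / 3)
    assert m.count("a", "b") == 3


def test_self_identity_diagnostic():
    panel = build_panel(
        [("rs1", "6", 1, "A", "G"), ("rs2", "6", 2, "C", "T")],
        ["hom", "het"],
        [[0, 2], [1, 1]],
    )
    diag10 = self_identity(panel, S10)
    assert diag10["hom"] == 1.0 and diag10["het"] == 1.0
    diag05 = self_identity(panel, S05)
    assert diag05["hom"] == 1.0
    assert diag05["het"] == 0.5  # all-het individual scores s against itself


def test_empty_panel_errors():
    panel = build_panel([], ["a", "b"], np.empty((2, 0)))
    with pytest.raises(ValueError, match="empty"):
        compute_identity(panel, S10)


def test_missing_calls_skipped_pairwise():
    panel = build_panel(
        [("rs1", "6", 1, "A", "G"), ("rs2", "6", 2, "A", "G")],
        ["a", "b"],
        [[0, -1], [0, 2]],
    )
    m = compute_identity(panel, S10)
    assert m.count("a", "b") == 1
    assert m.value("a", "b") == 1.0
    all_missing = build_panel([("rs1", "6", 1, "A", "G")], ["a", "b"], [[-1], [0]])
    m2 = compute_identity(all_missing, S10)
    assert np.isnan(m2.value("a", "b"))
    assert m2.undefined_pairs() == [("a", "b")]


@given(
    dosages=st.lists(
        st.lists(st.integers(-1, 2), min_size=1, max_size=10),
        min_size=2,
        max_size=5,
    ),
    s=st.sampled_from([0.0, 0.5, 1.0]),
)
def test_identity_matches_brute_force_oracle(dosages, s):
    n_snps = len(dosages[0])
    dosages = [row[:n_snps] + [0] * (n_snps - len(row)) for row in dosages]
    meta = [(f"rs{i}", "6", i + 1, "A", "G") for i in range(n_snps)]
    samples = [f"s{i}" for i in range(len(dosages))]
    panel = build_panel(meta, samples, dosages)
    scoring = ScoringConfig(s)
    m = compute_identity(panel, scoring)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            expected = brute_force_q(panel, samples[i], samples[j], scoring)
            got = m.value(samples[i], samples[j])
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)


@given(
    dosages=st.lists(
        st.lists(st.integers(-1, 2), min_size=4, max_size=4), min_size=2, max_size=4
    ),
    seed=st.integers(0, 100),
)
def test_q_invariant_to_snp_order_and_allele_swap(dosages, seed):
    n = 4
    meta = [(f"rs{i}", "6", i + 1, "A", "G") for i in range(n)]
    samples = [f"s{i}" for i in range(len(dosages))]
    panel = build_panel(meta, samples, dosages)
    base = compute_identity(panel, S05).q

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    reordered = panel.subset_snps(order)
    np.testing.assert_allclose(
        base, compute_identity(reordered, S05).q, atol=1e-12, equal_nan=True
    )

    g = np.array(dosages, dtype=np.int8)
    flip = rng.random(n) < 0.5
    g_sw = g.copy()
    g_sw[:, flip] = np.where(g[:, flip] == -1, -1, 2 - g[:, flip])
    meta_sw = [
        (r, c, p, (b if f else a), (a if f else b))
        for (r, c, p, a, b), f in zip(meta, flip)
    ]
    swapped = build_panel(meta_sw, samples, g_sw)
    np.testing.assert_allclose(
        base, compute_identity(swapped, S05).q, atol=1e-12, equal_nan=True
    )


@given(
    dosages=st.lists(
        st.lists(st.integers(0, 2), min_size=3, max_size=8), min_size=2, max_size=4
    )
)
def test_q_monotone_in_het_het_score(dosages):
    n_snps = len(dosages[0])
    dosages = [row[:n_snps] + [0] * (n_snps - len(row)) for row in dosages]
    meta = [(f"rs{i}", "6", i + 1, "A", "G") for i in range(n_snps)]
    samples = [f"s{i}" for i in range(len(dosages))]
    panel = build_panel(meta, samples, dosages)
    q_lo = compute_identity(panel, S05).q
    q_hi = compute_identity(panel, S10).q
    g = np.array(dosages)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            assert q_hi[i, j] >= q_lo[i, j] - 1e-12
            has_het_het = bool(((g[i] == 1) & (g[j] == 1)).any())
            if has_het_het:
                assert q_hi[i, j] > q_lo[i, j]
            else:
                assert q_hi[i, j] == pytest.approx(q_lo[i, j], abs=1e-12)


def test_cohort_baseline_examples():
    # 3 members with pair Qs {0.6, 0.7, 0.8} -> mean 0.7
    panel = _two_sample_panel()
    m = compute_identity(panel, S05)
    b2 = cohort_baseline(m, ["a", "b"])
    assert b2.q_mean == pytest.approx(m.value("a", "b"))
    q = np.array([[np.nan, 0.6, 0.7], [0.6, np.nan, 0.8], [0.7, 0.8, np.nan]])
    from matekin.relatedness import IdentityMatrix

    m3 = IdentityMatrix(("x", "y", "z"), q, np.full((3, 3), 5), S05)
    b3 = cohort_baseline(m3, ["x", "y", "z"])
    assert b3.q_mean == pytest.approx(0.7)
    assert b3.n_pairs == 3
    with pytest.raises(KeyError):
        cohort_baseline(m3, ["x", "y", "missing"])
    with pytest.raises(ValueError, match="at least 2"):
        cohort_baseline(m3, ["x"])
    b_excl = cohort_baseline(m3, ["x", "y", "z"], exclude_pairs=[("y", "z")])
    assert b_excl.q_mean == pytest.approx(0.65)


def test_relatedness_transform_and_ranking():
    from matekin.relatedness import CohortBaseline, IdentityMatrix

    q = np.array([[np.nan, 0.6, 0.7, 1.0], [0.6, np.nan, 0.9, 0.2],
                  [0.7, 0.9, np.nan, 0.5], [1.0, 0.2, 0.5, np.nan]])
    m = IdentityMatrix(("a", "b", "c", "d"), q, np.full((4, 4), 10), S05)
    baseline = CohortBaseline(0.6, 6, ("a", "b", "c", "d"))
    rel = relatedness(m, baseline)
    assert rel.value("a", "b") == pytest.approx(0.0)  # Q = q_mean centers at 0
    assert rel.value("a", "d") == pytest.approx(1.0)  # Q = 1 fixed point
    assert rel.value("a", "c") == pytest.approx(0.25)  # (0.7-0.6)/(1-0.6)
    iu = np.triu_indices(4, 1)
    assert np.array_equal(np.argsort(q[iu]), np.argsort(rel.r[iu]))  # rank preserved
    with pytest.raises(ValueError):
        CohortBaseline(1.0, 6, ("a",))


def test_identity_matrix_tsv_round_trip(tmp_path, small_cohort):
    import pandas as pd

    panel, _, _, couples = small_cohort
    m = compute_identity(panel, S10, couples.members)
    path = tmp_path / "q.tsv"
    m.write_tsv(path)
    back = pd.read_csv(path, sep="\t", index_col="sample_id")
    np.testing.assert_allclose(back.to_numpy(), m.q, equal_nan=True)
    assert list(back.columns) == list(m.sample_ids)
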