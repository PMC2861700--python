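"""Mate-vs-non-mate permutation test and multiple-testing utilities.

The test asks whether mated couples are more (or less) related than random
male-female pairings of the same parents.  The observed statistic is the
mean (or median) relatedness R over the real couples; the null is built by
re-pairing the male set with uniformly random permutations of the female
set.  The empirical P counts trials whose statistic is at least as extreme
as the observed one (ties count).  A Z score summarizes the effect size
against the non-mate pair distribution:

    Z = (loc(R_mates) - loc(R_non-mates)) / sd(R_non-mates)

Because different choices of couples excluded for relatedness give slightly
different answers, the test is run for every minimal exclusion permutation
and the per-permutation P and Z are aggregated (arithmetic mean, with the
full per-permutation table and min-max range retained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel, RegionSpec, compute_maf, filter_maf, subset_region
from .qc import CoupleSet, ExclusionPermutation, RelativePair, enumerate_exclusions
from .relatedness import (
    CohortBaseline,
    IdentityMatrix,
    RelatednessMatrix,
    ScoringConfig,
    cohort_baseline,
    compute_identity,
    relatedness,
)

SIDEDNESS = ("two", "one-low", "one-high")
STATISTICS = ("mean", "median")


def _location(values: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return float(np.mean(values))
    if statistic == "median":
        return float(np.median(values))
    raise ValueError(f"unknown statistic {statistic!r}; use one of {STATISTICS}")


@dataclass(frozen=True)
class RelatednessSummary:
    """Mate vs non-mate relatedness location/spread and the Z effect size."""

    r_mean_mates: float
    r_sd_mates: float
    r_mean_nonmates: float
    r_sd_nonmates: float
    z_score: float  # NaN when sd of non-mates is zero
    n_couples: int
    locus_tag: str = ""
    statistic: str = "mean"

    @property
    def z_defined(self) -> bool:
        return math.isfinite(self.z_score)


def _couple_matrix(relmatrix: RelatednessMatrix, couples: CoupleSet) -> np.ndarray:
    """R for males (rows) x females (cols); diagonal = the real couples."""
    m = relmatrix.submatrix(couples.males, couples.females)
    if np.isnan(m).any():
        raise ValueError("undefined relatedness among couple members")
    return m


def mate_statistic(
    relmatrix: RelatednessMatrix,
    couples: CoupleSet,
    statistic: str = "mean",
    locus_tag: str = "",
) -> RelatednessSummary:
    """Summarize mate-pair vs non-mate-pair relatedness.

    Non-mates are every male-female pair among the couples' members except
    the real couples.  ``sd`` uses the sample (n-1) denominator.
    """
    if len(couples) < 2:
        raise ValueError("need at least 2 couples")
    m = _couple_matrix(relmatrix, couples)
    k = len(couples)
    mates = np.diag(m)
    off = ~np.eye(k, dtype=bool)
    nonmates = m[off]
    sd_non = float(np.std(nonmates, ddof=1))
    loc_mates = _location(mates, statistic)
    loc_non = _location(nonmates, statistic)
    z = (loc_mates - loc_non) / sd_non if sd_non > 0 else float("nan")
    return RelatednessSummary(
        r_mean_mates=loc_mates,
        r_sd_mates=float(np.std(mates, ddof=1)),
        r_mean_nonmates=loc_non,
        r_sd_nonmates=sd_non,
        z_score=z,
        n_couples=k,
        locus_tag=locus_tag,
        statistic=statistic,
    )


def mc_standard_error(alpha: float, n_trials: int) -> float:
    """Binomial standard error of an empirical P near ``alpha``:
    sqrt(alpha * (1 - alpha) / n_trials)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return math.sqrt(alpha * (1.0 - alpha) / n_trials)


@dataclass(frozen=True)
class PermutationResult:
    """Empirical P with its Monte-Carlo precision.

    ``mc_se`` is the binomial standard error evaluated at the estimate
    itself; ``mc_se_nominal`` evaluates it at the nominal alpha (0.05) for
    comparability across runs.
    """

    p_value: float
    sidedness: str
    n_trials: int
    mc_se: float
    mc_se_nominal: float
    seed: int | None
    allow_real_couples: bool
    observed: float
    statistic: str = "mean"


def _random_pairings(rng: np.random.Generator, k: int, n_trials: int, allow_identity: bool) -> np.ndarray:
    """(n_trials, k) array of female-index permutations."""
    perms = np.argsort(rng.random((n_trials, k)), axis=1)
    if not allow_identity:
        ident = np.arange(k)
        bad = np.nonzero((perms == ident).all(axis=1))[0]
        while bad.size:
            perms[bad] = np.argsort(rng.random((bad.size, k)), axis=1)
            bad = bad[(perms[bad] == ident).all(axis=1)]
    return perms


def permutation_test(
    relmatrix: RelatednessMatrix,
    couples: CoupleSet,
    n_trials: int = 100_000,
    sidedness: str = "two",
    allow_real_couples: bool = True,
    seed: int | np.random.Generator | None = None,
    statistic: str = "mean",
    nominal_alpha: float = 0.05,
) -> PermutationResult:
    """Empirical P of the observed mate statistic under random re-pairing.

    Each trial pairs the male set with a uniform random permutation of the
    female set; the trial statistic is the mean (or median) R over trial
    pairs.  Two-sided P is the fraction of trials with |stat| >= |observed|;
    one-low / one-high are the fractions <= / >= the observed value.  Ties
    count toward P.  With ``allow_real_couples=False`` trials reproducing
    the identity pairing are redrawn.
    """
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if len(couples) < 2:
        raise ValueError("need at least 2 couples")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), seed
    m = _couple_matrix(relmatrix, couples)
    k = len(couples)
    observed = _location(np.diag(m), statistic)
    perms = _random_pairings(rng, k, n_trials, allow_real_couples)
    drawn = m[np.arange(k)[None, :], perms]
    if statistic == "mean":
        stats = drawn.mean(axis=1)
    else:
        stats = np.median(drawn, axis=1)
    if sidedness == "two":
        hits = np.abs(stats) >= abs(observed)
    elif sidedness == "one-low":
        hits = stats <= observed
    else:
        hits = stats >= observed
    p = float(hits.mean())
    se = math.sqrt(p * (1.0 - p) / n_trials)
    return PermutationResult(
        p_value=p,
        sidedness=sidedness,
        n_trials=n_trials,
        mc_se=se,
        mc_se_nominal=mc_standard_error(nominal_alpha, n_trials),
        seed=seed_out,
        allow_real_couples=allow_real_couples,
        observed=observed,
        statistic=statistic,
    )


def exhaustive_test(
    relmatrix: RelatednessMatrix,
    couples: CoupleSet,
    sidedness: str = "two",
    statistic: str = "mean",
) -> float:
    """Exact P over all k! pairings (small k only); the Monte-Carlo oracle."""
    from itertools import permutations as iperm

    m = _couple_matrix(relmatrix, couples)
    k = len(couples)
    if k > 8:
        raise ValueError("exhaustive enumeration is limited to <= 8 couples")
    observed = _location(np.diag(m), statistic)
    rows = np.arange(k)
    hits = total = 0
    for perm in iperm(range(k)):
        stat = _location(m[rows, list(perm)], statistic)
        if sidedness == "two":
            hit = abs(stat) >= abs(observed)
        elif sidedness == "one-low":
            hit = stat <= observed
        else:
            hit = stat >= observed
        hits += hit
        total += 1
    return hits / total


@dataclass(frozen=True)
class CorrectionSpec:
    """Dunn-Sidak family-wise correction: alpha' = 1 - (1-alpha)^(1/k)."""

    alpha: float
    k: int
    alpha_prime: float


def dunn_sidak(alpha: float, k: int) -> CorrectionSpec:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    # clamp fp noise so alpha' <= alpha holds exactly at k = 1
    return CorrectionSpec(alpha, k, min(alpha, 1.0 - (1.0 - alpha) ** (1.0 / k)))


@dataclass
class PermutationRecord:
    permutation: ExclusionPermutation
    summary: RelatednessSummary
    test: PermutationResult
    baseline: CohortBaseline


@dataclass
class AggregateResult:
    """Per-exclusion-permutation results with mean-aggregated P and Z."""

    records: list[PermutationRecord]
    aggregate_z: float
    aggregate_p: float
    z_range: Tuple[float, float]
    p_range: Tuple[float, float]
    locus_tag: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "permutation": rec.permutation.label,
                    "locus": rec.summary.locus_tag,
                    "n_couples": rec.summary.n_couples,
                    "q_mean_cohort": rec.baseline.q_mean,
                    "r_mates": rec.summary.r_mean_mates,
                    "r_sd_mates": rec.summary.r_sd_mates,
                    "r_nonmates": rec.summary.r_mean_nonmates,
                    "r_sd_nonmates": rec.summary.r_sd_nonmates,
                    "z": rec.summary.z_score,
                    "p": rec.test.p_value,
                    "n_trials": rec.test.n_trials,
                    "sidedness": rec.test.sidedness,
                }
            )
        return pd.DataFrame(rows)


def run_aggregate(
    panel: GenotypePanel,
    scoring: ScoringConfig,
    couples: CoupleSet,
    relatives: Sequence[RelativePair],
    region: RegionSpec | None,
    n_trials: int = 100_000,
    seed: int | None = None,
    sidedness: str = "two",
    statistic: str = "mean",
    allow_real_couples: bool = True,
    maf_threshold: float | None = None,
    maf_timing: str = "before",
    exclusion_cap: int = 64,
    locus_tag: str | None = None,
) -> AggregateResult:
    """Run the mate test for every exclusion permutation and aggregate.

    For each minimal exclusion of couples touching a relative pair, the
    cohort baseline, relatedness and permutation test are recomputed on the
    remaining parents.  Aggregate P and Z are the arithmetic means across
    permutations; min-max ranges are reported alongside.

    ``maf_threshold`` optionally applies the MAF filter here: timing
    ``"before"`` computes MAF once on all panel samples (children included);
    ``"after"`` recomputes it per permutation on the remaining parents.
    """
    if maf_timing not in ("before", "after"):
        raise ValueError("maf_timing must be 'before' or 'after'")
    if locus_tag is None:
        locus_tag = (
            f"{region.chromosome}:{region.start}-{region.end}" if region else "autosomal"
        )
    work = subset_region(panel, region) if region is not None else panel
    if work.n_snps == 0:
        raise ValueError("no SNPs in the requested region")
    if maf_threshold is not None and maf_timing == "before":
        work = filter_maf(compute_maf(work), maf_threshold)

    perms = enumerate_exclusions(couples, relatives, cap=exclusion_cap)
    seeds = np.random.SeedSequence(seed).generate_state(len(perms)) >> 1

    shared_identity: IdentityMatrix | None = None
    if not (maf_threshold is not None and maf_timing == "after"):
        shared_identity = compute_identity(work, scoring, couples.members)

    records = []
    for perm, sub_seed in zip(perms, seeds):
        remaining = perm.remaining
        members = remaining.members
        if maf_threshold is not None and maf_timing == "after":
            filt = filter_maf(compute_maf(work, members), maf_threshold)
            identity = compute_identity(filt, scoring, members)
        else:
            identity = shared_identity
        baseline = cohort_baseline(identity, members)
        rel = relatedness(identity, baseline)
        summary = mate_statistic(rel, remaining, statistic, locus_tag)
        test = permutation_test(
            rel,
            remaining,
            n_trials=n_trials,
            sidedness=sidedness,
            allow_real_couples=allow_real_couples,
            seed=int(sub_seed),
            statistic=statistic,
        )
        records.append(PermutationRecord(perm, summary, test, baseline))

    zs = np.array([r.summary.z_score for r in records])
    ps = np.array([r.test.p_value for r in records])
    return AggregateResult(
        records=records,
        aggregate_z=float(np.nanmean(zs)),
        aggregate_p=float(ps.mean()),
        z_range=(float(np.nanmin(zs)), float(np.nanmax(zs))),
        p_range=(float(ps.min()), float(ps.max())),
        locus_tag=locus_tag,
    )


@dataclass
class LeaveOneOutResult:
    table: pd.DataFrame
    most_dissimilar_couple: str  # lowest full-cohort mate R
    most_extreme_couple: str  # largest |full-cohort mate R|


def leave_one_out(
    identity: IdentityMatrix,
    couples: CoupleSet,
    n_trials: int = 10_000,
    seed: int | None = None,
    sidedness: str = "two",
    statistic: str = "mean",
    allow_real_couples: bool = True,
) -> LeaveOneOutResult:
    """Re-run the test dropping each couple in turn.

    The baseline is recomputed without the dropped couple's members each
    time.  Couples are ranked by their full-cohort mate relatedness to
    identify the most dissimilar (lowest R) and most extreme (largest |R|)
    couple.
    """
    if len(couples) < 3:
        raise ValueError("leave-one-out needs at least 3 couples")
    full_baseline = cohort_baseline(identity, couples.members)
    full_rel = relatedness(identity, full_baseline)
    mate_r = {c.couple_id: full_rel.value(c.male_id, c.female_id) for c in couples}

    seeds = np.random.SeedSequence(seed).generate_state(len(couples)) >> 1
    rows = []
    for couple, sub_seed in zip(couples, seeds):
        remaining = couples.drop([couple.couple_id])
        baseline = cohort_baseline(identity, remaining.members)
        rel = relatedness(identity, baseline)
        summary = mate_statistic(rel, remaining, statistic)
        test = permutation_test(
            rel,
            remaining,
            n_trials=n_trials,
            sidedness=sidedness,
            allow_real_couples=allow_real_couples,
            seed=int(sub_seed),
            statistic=statistic,
        )
        rows.append(
            {
                "dropped_couple": couple.couple_id,
                "dropped_mate_r": mate_r[couple.couple_id],
                "z": summary.z_score,
                "p": test.p_value,
                "n_trials": test.n_trials,
            }
        )
    table = pd.DataFrame(rows)
    most_dissimilar = min(mate_r, key=mate_r.get)
    most_extreme = max(mate_r, key=lambda c: abs(mate_r[c]))
    return LeaveOneOutResult(table, most_dissimilar, most_extreme)
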