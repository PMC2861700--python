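"""Pairwise allele-identity coefficients and cohort-normalized relatedness.

For two individuals at one biallelic SNP the identity score is the fraction
of shared alleles of the unordered genotypes (1 for identical homozygotes,
0.5 for homozygote vs heterozygote, 0 for opposite homozygotes), except that
a heterozygote-heterozygote comparison is credited a configurable score
``s`` (0.5 or 1 in the two conventional variants).  The identity coefficient
Q of a pair is the mean score over SNPs where both calls are present.

Relatedness centers and scales Q by the cohort mean::

    R = (Q - Q_mean) / (1 - Q_mean)

so R = 0 is cohort-average similarity and R = 1 is complete identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

SKIP = None


@dataclass(frozen=True)
class ScoringConfig:
    """Identity scoring rule; ``het_het_score`` is the credit for het-het."""

    het_het_score: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_het_score <= 1.0:
            raise ValueError(
                f"het_het_score must be in [0, 1], got {self.het_het_score}"
            )


def per_snp_identity(call_a, call_b, scoring: ScoringConfig = ScoringConfig()):
    """Identity score of two unordered genotype calls, or SKIP if either is missing.

    Calls are 2-tuples of allele symbols (order irrelevant) or None.
    """
    if call_a is None or call_b is None:
        return SKIP
    a1, a2 = call_a
    b1, b2 = call_b
    het_a = a1 != a2
    het_b = b1 != b2
    if het_a and het_b:
        if {a1, a2} != {b1, b2}:
            raise ValueError(f"calls {call_a} and {call_b} use different allele alphabets")
        return scoring.het_het_score
    # shared-allele count with multiplicity, over the union of symbols
    shared = 0
    for sym in {a1, a2, b1, b2}:
        shared += min((a1 == sym) + (a2 == sym), (b1 == sym) + (b2 == sym))
    return shared / 2.0


@dataclass
class IdentityMatrix:
    """Symmetric Q matrix with the per-pair count of SNPs used.

    The diagonal is NaN by default; self-identity is a diagnostic computed
    via :meth:`self_identity` (with ``het_het_score < 1`` it is below one for
    heterozygous individuals).
    """

    sample_ids: Tuple[str, ...]
    q: np.ndarray
    counts: np.ndarray
    scoring: ScoringConfig
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def value(self, a: str, b: str) -> float:
        return float(self.q[self._index[a], self._index[b]])

    def count(self, a: str, b: str) -> int:
        return int(self.counts[self._index[a], self._index[b]])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        n = len(self.sample_ids)
        iu = np.triu_indices(n, k=1)
        bad = np.argwhere(self.counts[iu] == 0).ravel()
        return [(self.sample_ids[iu[0][k]], self.sample_ids[iu[1][k]]) for k in bad]

    def submatrix_indices(self, members: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[m] for m in members], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in identity matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def _one_hot(g: np.ndarray):
    valid = (g != MISSING).astype(np.float64)
    a0 = (g == 0).astype(np.float64)
    a1 = (g == 1).astype(np.float64)
    a2 = (g == 2).astype(np.float64)
    return valid, a0, a1, a2


def compute_identity(
    panel: GenotypePanel,
    scoring: ScoringConfig = ScoringConfig(),
    sample_ids: Sequence[str] | None = None,
    with_diagonal: bool = False,
) -> IdentityMatrix:
    """All-pairs identity coefficients over the panel's SNPs.

    Q for a pair is averaged over SNPs where neither call is missing; pairs
    with zero usable SNPs are NaN and reported by ``undefined_pairs()``.
    """
    if panel.n_snps == 0:
        raise ValueError("cannot compute identity on an empty panel")
    if sample_ids is None:
        sample_ids = panel.samples
    g = panel.genotypes[panel.sample_indices(sample_ids)]
    valid, a0, a1, a2 = _one_hot(g)
    counts = valid @ valid.T
    # sum over SNPs of |dosage difference|; score per SNP is 1 - |d|/2 with a
    # het-het override subtracting (1 - s)
    cross01 = a0 @ a1.T
    cross12 = a1 @ a2.T
    cross02 = a0 @ a2.T
    abs_diff = cross01 + cross01.T + cross12 + cross12.T + 2.0 * (cross02 + cross02.T)
    het_het = a1 @ a1.T
    score_sum = counts - 0.5 * abs_diff - (1.0 - scoring.het_het_score) * het_het
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(counts > 0, score_sum / np.maximum(counts, 1), np.nan)
    q = 0.5 * (q + q.T)  # exact symmetry despite fp rounding
    if not with_diagonal:
        np.fill_diagonal(q, np.nan)
    counts_i = counts.astype(np.int64)
    return IdentityMatrix(tuple(sample_ids), q, counts_i, scoring)


def self_identity(panel: GenotypePanel, scoring: ScoringConfig = ScoringConfig()) -> pd.Series:
    """Self-self Q per sample (the diagonal diagnostic)."""
    m = compute_identity(panel, scoring, with_diagonal=True)
    return pd.Series(np.diag(m.q), index=list(m.sample_ids))


def pair_snp_scores(
    panel: GenotypePanel,
    pairs: Sequence[Tuple[str, str]],
    scoring: ScoringConfig = ScoringConfig(),
):
    """Per-SNP identity scores for explicit sample pairs.

    Returns ``(scores, valid)`` of shape (n_pairs, n_snps); ``scores`` is 0
    where ``valid`` is False.  Used by the segment scan to aggregate Q over
    arbitrary SNP windows without recomputing genotype comparisons.
    """
    idx_a = panel.sample_indices([p[0] for p in pairs])
    idx_b = panel.sample_indices([p[1] for p in pairs])
    ga = panel.genotypes[idx_a].astype(np.int16)
    gb = panel.genotypes[idx_b].astype(np.int16)
    valid = (ga != MISSING) & (gb != MISSING)
    scores = 1.0 - np.abs(ga - gb) / 2.0
    het_het = (ga == 1) & (gb == 1)
    scores = np.where(het_het, scoring.het_het_score, scores)
    scores = np.where(valid, scores, 0.0).astype(np.float32)
    return scores, valid


@dataclass(frozen=True)
class CohortBaseline:
    """Mean Q over all unordered within-cohort pairs (relatives excludable)."""

    q_mean: float
    n_pairs: int
    members: Tuple[str, ...]
    excluded_pairs: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.q_mean < 1.0:
            raise ValueError("baseline q_mean must be < 1 for relatedness to be defined")


def cohort_baseline(
    identity: IdentityMatrix,
    members: Sequence[str],
    exclude_pairs: Iterable[Tuple[str, str]] = (),
) -> CohortBaseline:
    """Mean Q over all unordered pairs within ``members``.

    Both same-sex and opposite-sex pairs enter the mean; the diagonal never
    does.  ``exclude_pairs`` removes known relative pairs from the average.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("cohort baseline needs at least 2 members")
    idx = identity.submatrix_indices(members)
    sub = identity.q[np.ix_(idx, idx)]
    n = len(members)
    mask = np.zeros((n, n), dtype=bool)
    iu = np.triu_indices(n, k=1)
    mask[iu] = True
    pos = {m: i for i, m in enumerate(members)}
    excluded = []
    for a, b in exclude_pairs:
        if a in pos and b in pos:
            i, j = pos[a], pos[b]
            mask[min(i, j), max(i, j)] = False
            excluded.append((a, b))
    vals = sub[mask]
    if np.isnan(vals).any():
        undef = [
            (members[iu[0][k]], members[iu[1][k]])
            for k in np.argwhere(np.isnan(sub[iu]) & mask[iu]).ravel()
        ]
        raise ValueError(f"undefined Q for pairs: {undef[:10]}")
    return CohortBaseline(float(vals.mean()), int(mask.sum()), tuple(members), tuple(excluded))


@dataclass
class RelatednessMatrix:
    """Entrywise ``(Q - q_mean)/(1 - q_mean)`` with its baseline reference."""

    sample_ids: Tuple[str, ...]
    r: np.ndarray
    baseline: CohortBaseline
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def value(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def submatrix(self, rows: Sequence[str], cols: Sequence[str]) -> np.ndarray:
        ri = np.array([self._index[s] for s in rows], dtype=int)
        ci = np.array([self._index[s] for s in cols], dtype=int)
        return self.r[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def relatedness(identity: IdentityMatrix, baseline: CohortBaseline) -> RelatednessMatrix:
    """Normalize Q by the cohort baseline: R = (Q - q_mean)/(1 - q_mean)."""
    denom = 1.0 - baseline.q_mean
    if denom <= 0:
        raise ValueError("baseline q_mean must be < 1")
    r = (identity.q - baseline.q_mean) / denom
    return RelatednessMatrix(identity.sample_ids, r, baseline)
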