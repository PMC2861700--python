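"""Cohort quality control: couples, close-relative detection, exclusions.

Close relatives inflate the cohort baseline and contaminate the non-mate
null, so couples touching a flagged relative pair are excluded before the
mate test.  When several different exclusions would do, every *minimal* set
of couples whose removal clears all relative pairs is enumerated, and the
downstream test is run once per exclusion permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence, Tuple

import pandas as pd

from .genotype_io import SampleSheet
from .relatedness import RelatednessMatrix


@dataclass(frozen=True)
class Couple:
    couple_id: str
    male_id: str
    female_id: str

    @property
    def members(self) -> Tuple[str, str]:
        return (self.male_id, self.female_id)


class CoupleSet:
    """Mated male-female pairs; each sample belongs to at most one couple."""

    def __init__(self, couples: Sequence[Couple]):
        self.couples = list(couples)
        ids = [c.couple_id for c in self.couples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated couple ids")
        members = [m for c in self.couples for m in c.members]
        if len(set(members)) != len(members):
            raise ValueError("a sample appears in more than one couple")

    @classmethod
    def from_sample_sheet(cls, sheet: SampleSheet, cohort_tag: str | None = None) -> "CoupleSet":
        """Couples = families with both a father and a mother present."""
        table = sheet.table
        if cohort_tag is not None:
            table = table[table["cohort_tag"] == cohort_tag]
        couples = []
        for fam, grp in table.groupby("family_id", sort=True):
            fathers = grp.loc[grp["role"] == "father", "sample_id"]
            mothers = grp.loc[grp["role"] == "mother", "sample_id"]
            if len(fathers) == 1 and len(mothers) == 1:
                couples.append(Couple(str(fam), fathers.iloc[0], mothers.iloc[0]))
        return cls(couples)

    def __len__(self) -> int:
        return len(self.couples)

    def __iter__(self):
        return iter(self.couples)

    @property
    def males(self) -> list[str]:
        return [c.male_id for c in self.couples]

    @property
    def females(self) -> list[str]:
        return [c.female_id for c in self.couples]

    @property
    def members(self) -> list[str]:
        return [m for c in self.couples for m in c.members]

    def mate_pairs(self) -> list[Tuple[str, str]]:
        return [c.members for c in self.couples]

    def drop(self, couple_ids: Iterable[str]) -> "CoupleSet":
        drop = set(couple_ids)
        unknown = drop - {c.couple_id for c in self.couples}
        if unknown:
            raise KeyError(f"unknown couple ids: {sorted(unknown)}")
        return CoupleSet([c for c in self.couples if c.couple_id not in drop])

    def couples_containing(self, sample_id: str) -> list[str]:
        return [c.couple_id for c in self.couples if sample_id in c.members]


@dataclass(frozen=True)
class RelativePair:
    sample_a: str
    sample_b: str
    r_value: float
    threshold: float


def flag_relatives(
    relmatrix: RelatednessMatrix,
    members: Sequence[str],
    threshold: float = 0.2,
    couples: CoupleSet | None = None,
    exclude_mate_pairs: bool = False,
) -> list[RelativePair]:
    """All unordered pairs within ``members`` with R >= threshold.

    Mate pairs themselves are flaggable by default (two related mates are a
    real relative pair); ``exclude_mate_pairs=True`` skips them, which
    requires ``couples``.
    """
    if threshold <= 0:
        raise ValueError("relative threshold must be > 0")
    mates = set()
    if exclude_mate_pairs:
        if couples is None:
            raise ValueError("exclude_mate_pairs requires couples")
        mates = {frozenset(c.members) for c in couples}
    out = []
    for a, b in combinations(members, 2):
        if frozenset((a, b)) in mates:
            continue
        r = relmatrix.value(a, b)
        if r >= threshold:
            out.append(RelativePair(a, b, float(r), threshold))
    return out


@dataclass(frozen=True)
class ExclusionPermutation:
    """One minimal set of excluded couples and the couples that remain."""

    excluded: Tuple[str, ...]
    remaining: CoupleSet

    @property
    def label(self) -> str:
        return "+".join(self.excluded) if self.excluded else "none"


def _pair_cover(couples: CoupleSet, pair: RelativePair) -> frozenset:
    cover = set(couples.couples_containing(pair.sample_a))
    cover |= set(couples.couples_containing(pair.sample_b))
    return frozenset(cover)


def relative_pairs_among(
    relatives: Iterable[RelativePair], couples: CoupleSet
) -> list[RelativePair]:
    """Relative pairs with both members among the couples' parents."""
    members = set(couples.members)
    return [p for p in relatives if p.sample_a in members and p.sample_b in members]


def enumerate_exclusions(
    couples: CoupleSet,
    relatives: Sequence[RelativePair],
    cap: int = 64,
) -> list[ExclusionPermutation]:
    """All minimal couple sets whose removal leaves no live relative pair.

    A relative pair is "live" when both members are parents of remaining
    couples; removing any couple containing either member resolves it.  The
    enumeration is an exact minimal-hitting-set search on the conflict
    structure, returned in lexicographic order of the excluded ids.
    """
    for pair in relatives:
        if not _pair_cover(couples, pair):
            raise ValueError(
                f"relative pair ({pair.sample_a}, {pair.sample_b}) touches no couple"
            )
    # only pairs with BOTH members among the couples' parents constrain the
    # exclusion (a pair involving a non-parent can never survive downstream)
    live = relative_pairs_among(relatives, couples)
    covers = [_pair_cover(couples, pair) for pair in live]
    if not covers:
        return [ExclusionPermutation((), couples)]

    hitting_sets: set[frozenset] = set()

    def recurse(chosen: frozenset) -> None:
        uncovered = [c for c in covers if not (c & chosen)]
        if not uncovered:
            hitting_sets.add(chosen)
            return
        if len(hitting_sets) > 4 * cap:  # safety valve for pathological inputs
            raise ValueError(
                f"exclusion enumeration exceeded cap ({cap}); "
                "review the relative-detection threshold"
            )
        branch = min(uncovered, key=len)
        for cid in sorted(branch):
            recurse(chosen | {cid})

    recurse(frozenset())
    minimal = [
        s for s in hitting_sets if not any(t < s for t in hitting_sets if t is not s)
    ]
    if len(minimal) > cap:
        raise ValueError(
            f"{len(minimal)} exclusion permutations exceed the cap ({cap}); "
            "review the relative-detection threshold"
        )
    perms = [
        ExclusionPermutation(tuple(sorted(s)), couples.drop(s)) for s in minimal
    ]
    perms.sort(key=lambda p: p.excluded)
    return perms


def exclusions_to_frame(perms: Sequence[ExclusionPermutation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "permutation": [p.label for p in perms],
            "n_excluded": [len(p.excluded) for p in perms],
            "n_remaining": [len(p.remaining) for p in perms],
            "excluded_couples": [",".join(p.excluded) for p in perms],
        }
    )
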