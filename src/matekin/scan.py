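"""Genome-wide tiled-segment relatedness scan with recombination rates.

The genome is tiled into fixed-length segments (3.6 Mbp every 300 kbp by
default).  For each retained segment the mean mate-pair and non-mate-pair
relatedness is computed from the SNPs inside the segment, normalizing Q by
the single population-wide cohort baseline (all panel SNPs, relatives
excluded from the mean).  The query locus (the MHC in the motivating use
case) is then placed within the genome-wide distribution: the fraction of
retained segments whose mean relatedness is greater than or equal to the
query's, overall and restricted to segments with recombination rate at or
below the query's.  A query that is extreme for mates but ordinary for
non-mates is a mating signal; a query extreme for both is better explained
by locus diversity than by mate choice.

Segments are excluded when truncated at a chromosome end, overlapping a
centromere or the query locus, containing fewer than ``min_snps`` SNPs, or
lacking two genetic-map points for a recombination rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel, RegionSpec, normalize_chrom
from .qc import CoupleSet, RelativePair
from .relatedness import (
    ScoringConfig,
    cohort_baseline,
    compute_identity,
    pair_snp_scores,
)

DEFAULT_SEG_LEN = 3_600_000
DEFAULT_STEP = 300_000


class GeneticMap:
    """Per-chromosome cumulative genetic positions (bp -> cM).

    ``points[chrom] = (positions, cum_cm)`` with positions strictly
    increasing and cM non-decreasing.
    """

    def __init__(self, points: Mapping[str, Tuple[np.ndarray, np.ndarray]]):
        self.points = {}
        for chrom, (pos, cm) in points.items():
            pos = np.asarray(pos, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            if pos.shape != cm.shape:
                raise ValueError(f"chrom {chrom}: position/cM length mismatch")
            if (np.diff(pos) <= 0).any():
                raise ValueError(f"chrom {chrom}: map positions must strictly increase")
            if (np.diff(cm) < -1e-9).any():
                raise ValueError(f"chrom {chrom}: cumulative cM must be non-decreasing")
            self.points[normalize_chrom(chrom)] = (pos, cm)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        """Read a 4-column map TSV (chromosome, position, rate, cumulative cM);
        the cumulative column is the one used."""
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:4])
        points = {}
        for chrom, grp in df.groupby(cols[0], sort=True):
            grp = grp.sort_values(cols[1])
            points[str(chrom)] = (grp[cols[1]].to_numpy(), grp[cols[3]].to_numpy())
        return cls(points)

    def to_tsv(self, path) -> None:
        rows = []
        for chrom in sorted(self.points):
            pos, cm = self.points[chrom]
            rate = np.empty_like(cm)
            # local rate from consecutive points, cM/Mbp; last point repeats
            d_cm = np.diff(cm)
            d_mb = np.diff(pos) / 1e6
            rate[:-1] = np.divide(d_cm, d_mb, out=np.zeros_like(d_cm), where=d_mb > 0)
            rate[-1] = rate[-2] if len(rate) > 1 else 0.0
            for p, r, c in zip(pos, rate, cm):
                rows.append((chrom, int(p), float(r), float(c)))
        pd.DataFrame(rows, columns=["chrom", "pos", "rate_cm_per_mbp", "cum_cm"]).to_csv(
            path, sep="\t", index=False
        )

    def chrom_length(self, chrom: str) -> int:
        return int(self.points[normalize_chrom(chrom)][0][-1])


def read_centromeres(path) -> dict[str, Tuple[int, int]]:
    """3-column interval TSV (chromosome, start, end) -> {chrom: (start, end)}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = {}
    for _, row in df.iterrows():
        out[normalize_chrom(row.iloc[0])] = (int(row.iloc[1]), int(row.iloc[2]))
    return out


@dataclass(frozen=True)
class Segment:
    chromosome: str
    start: int
    end: int
    truncated: bool


def tile_segments(
    chrom_lengths: Mapping[str, int],
    seg_len: int = DEFAULT_SEG_LEN,
    step: int = DEFAULT_STEP,
) -> list[Segment]:
    """Tile each chromosome with segments starting at 1, 1+step, 1+2*step, ...

    Segments running past the chromosome end are clipped and flagged as
    truncated (the fixed-length recombination denominator presumes
    full-length segments, so truncated tails are excluded downstream).
    """
    if seg_len < step:
        raise ValueError("seg_len must be >= step")
    segments = []
    for chrom, length in chrom_lengths.items():
        chrom = normalize_chrom(chrom)
        start = 1
        while start <= length:
            end = start + seg_len - 1
            truncated = end > length
            segments.append(Segment(chrom, start, min(end, length), truncated))
            start += step
    return segments


def segment_recomb_rate(
    gmap: GeneticMap,
    chrom: str,
    start: int,
    end: int,
    denom_mbp: float | None = None,
) -> float:
    """cM/Mbp over a segment from the two interior map points nearest its ends.

    The numerator is the cumulative-cM difference between the map points
    closest to the segment end and start, considering only points inside
    the segment; the denominator is the nominal segment length in Mbp
    (3.6 by default), not the inter-point distance.  Returns NaN with fewer
    than two interior points.
    """
    chrom = normalize_chrom(chrom)
    if chrom not in gmap.points:
        return float("nan")
    pos, cm = gmap.points[chrom]
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="right")
    if hi - lo < 2:
        return float("nan")
    if denom_mbp is None:
        denom_mbp = (end - start + 1) / 1e6
    return float((cm[hi - 1] - cm[lo]) / denom_mbp)


@dataclass
class ScanResult:
    """Per-segment table, the query-locus record, and placement fractions.

    ``placement[stat]["fraction_segments_ge"]`` is the fraction of retained
    segments whose r_mean is >= the query's (ties count), i.e. the query is
    "lower than or equal to" that fraction of the genome;
    ``fraction_segments_ge_low_recomb`` restricts to segments with
    recombination rate <= the query's.
    """

    segments: pd.DataFrame
    query: dict
    placement: dict
    baseline_q_mean: float

    def write(self, seg_path, summary_path) -> None:
        import json

        self.segments.to_csv(seg_path, sep="\t", index=False)
        with open(summary_path, "w") as fh:
            json.dump(
                {
                    "query": self.query,
                    "placement": self.placement,
                    "baseline_q_mean": self.baseline_q_mean,
                    "n_retained_segments": int(self.segments["retained"].sum()),
                },
                fh,
                indent=2,
            )


def _window_means(
    scores: np.ndarray, valid: np.ndarray, lo: int, hi: int
) -> np.ndarray:
    """Per-pair Q over SNP columns [lo, hi); NaN for pairs with no data."""
    s = scores[:, lo:hi].sum(axis=1, dtype=np.float64)
    n = valid[:, lo:hi].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, s / np.maximum(n, 1), np.nan)


def scan(
    panel: GenotypePanel,
    couples: CoupleSet,
    gmap: GeneticMap,
    query: RegionSpec,
    scoring: ScoringConfig = ScoringConfig(),
    centromeres: Mapping[str, Tuple[int, int]] | None = None,
    relatives: Sequence[RelativePair] = (),
    chrom_lengths: Mapping[str, int] | None = None,
    min_snps: int = 1000,
    seg_len: int = DEFAULT_SEG_LEN,
    step: int = DEFAULT_STEP,
) -> ScanResult:
    """Place the query locus in the genome-wide segment distribution.

    Relatedness uses a single population-wide baseline: mean Q over all
    pairs of mated parents across all panel SNPs, with flagged relative
    pairs left out of the mean.  Relative pairs are also excluded from the
    non-mate pair set.  Segments overlapping the query locus are excluded
    from the distribution the query is ranked against.
    """
    panel = panel.sorted_by_position()
    centromeres = centromeres or {}
    if chrom_lengths is None:
        chrom_lengths = {c: gmap.chrom_length(c) for c in gmap.points}

    members = couples.members
    rel_pairs = {
        frozenset((p.sample_a, p.sample_b))
        for p in relatives
        if p.sample_a in set(members) and p.sample_b in set(members)
    }

    identity = compute_identity(panel, scoring, members)
    baseline = cohort_baseline(
        identity, members, exclude_pairs=[tuple(p) for p in rel_pairs]
    )
    denom = 1.0 - baseline.q_mean

    mate_pairs = couples.mate_pairs()
    nonmate_pairs = [
        (m, f)
        for m in couples.males
        for f in couples.females
        if (m, f) not in set(mate_pairs) and frozenset((m, f)) not in rel_pairs
    ]
    pairs = mate_pairs + nonmate_pairs
    n_mates = len(mate_pairs)
    scores, valid = pair_snp_scores(panel, pairs, scoring)

    chrom_arr = panel.snps["chrom"].to_numpy()
    pos_arr = panel.snps["pos"].to_numpy()
    chrom_offsets = {}
    for chrom in np.unique(chrom_arr):
        idx = np.nonzero(chrom_arr == chrom)[0]
        chrom_offsets[chrom] = (idx[0], pos_arr[idx[0] : idx[-1] + 1])

    def snp_range(chrom: str, start: int, end: int) -> Tuple[int, int]:
        if chrom not in chrom_offsets:
            return 0, 0
        off, cpos = chrom_offsets[chrom]
        lo = off + int(np.searchsorted(cpos, start, side="left"))
        hi = off + int(np.searchsorted(cpos, end, side="right"))
        return lo, hi

    def pair_means(lo: int, hi: int) -> Tuple[float, float]:
        q = _window_means(scores, valid, lo, hi)
        r = (q - baseline.q_mean) / denom
        return float(np.nanmean(r[:n_mates])), float(np.nanmean(r[n_mates:]))

    rows = []
    for seg in tile_segments(chrom_lengths, seg_len, step):
        lo, hi = snp_range(seg.chromosome, seg.start, seg.end)
        n_snps = hi - lo
        cent = centromeres.get(seg.chromosome)
        cent_overlap = bool(cent and seg.start <= cent[1] and seg.end >= cent[0])
        query_overlap = query.overlaps(seg.chromosome, seg.start, seg.end)
        rate = segment_recomb_rate(
            gmap, seg.chromosome, seg.start, seg.end, denom_mbp=seg_len / 1e6
        )
        retained = (
            not seg.truncated
            and not cent_overlap
            and not query_overlap
            and n_snps >= min_snps
            and np.isfinite(rate)
        )
        r_mates = r_nonmates = float("nan")
        if retained:
            r_mates, r_nonmates = pair_means(lo, hi)
        rows.append(
            {
                "chrom": seg.chromosome,
                "start": seg.start,
                "end": seg.end,
                "n_snps": n_snps,
                "recomb_rate": rate,
                "r_mean_mates": r_mates,
                "r_mean_nonmates": r_nonmates,
                "truncated": seg.truncated,
                "centromere_overlap": cent_overlap,
                "query_overlap": query_overlap,
                "too_few_snps": n_snps < min_snps,
                "retained": retained,
            }
        )
    segments = pd.DataFrame(rows)

    qlo, qhi = snp_range(query.chromosome, query.start, query.end)
    if qhi - qlo == 0:
        raise ValueError("query region contains no SNPs")
    q_rate = segment_recomb_rate(
        gmap, query.chromosome, query.start, query.end, denom_mbp=query.length / 1e6
    )
    q_mates, q_nonmates = pair_means(qlo, qhi)
    query_rec = {
        "chrom": query.chromosome,
        "start": query.start,
        "end": query.end,
        "n_snps": int(qhi - qlo),
        "recomb_rate": q_rate,
        "r_mean_mates": q_mates,
        "r_mean_nonmates": q_nonmates,
    }

    kept = segments[segments["retained"]]
    placement = {}
    for stat, q_val in (("mates", q_mates), ("nonmates", q_nonmates)):
        col = kept[f"r_mean_{stat}"].to_numpy()
        frac_ge = float(np.mean(col >= q_val)) if len(col) else float("nan")
        low_rec = kept[kept["recomb_rate"] <= q_rate][f"r_mean_{stat}"].to_numpy()
        frac_ge_low = float(np.mean(low_rec >= q_val)) if len(low_rec) else float("nan")
        placement[stat] = {
            "fraction_segments_ge": frac_ge,
            "fraction_segments_ge_low_recomb": frac_ge_low,
            "n_segments": int(len(col)),
            "n_segments_low_recomb": int(len(low_rec)),
        }
    return ScanResult(segments, query_rec, placement, baseline.q_mean)
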