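"""Synthetic trio cohorts with controlled mating structure.

The generator emulates the inputs of a trio-cohort mate-choice analysis:
unlinked biallelic SNPs with a configurable minor-allele-frequency
spectrum, parents drawn under Hardy-Weinberg equilibrium, children by
Mendelian transmission with independent assortment, missing calls, planted
close-relative pairs, and an optional locus-dependent mating preference.

The mating model is rejection/softmax pairing on locus identity: a male is
matched to a remaining female with probability proportional to
``exp(-beta * z)``, where ``z`` is the pair's locus identity coefficient
standardized against all candidate male-female pairs.  ``beta`` is thus a
dimensionless dissimilarity-preference strength in units of the locus
identity standard deviation; ``beta = 0`` is uniform random mating and
``beta`` around 8 is near-deterministic preference for the most dissimilar
available partner.

Every stochastic choice derives from the single seed in :class:`SimConfig`,
so identical configurations reproduce identical panels byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel, RegionSpec, SampleSheet, normalize_chrom
from .scan import GeneticMap

_RELATIVE_KINDS = ("duplicate", "parent-offspring", "full-sib")
_ALLELES = np.array(list("ACGT"))

DEFAULT_MHC = RegionSpec("6", 29_700_000, 33_300_000)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate a single trio cohort: 30 mated couples genotyped at
    2,000 unlinked SNPs spread over a 36-Mbp chromosome carrying a
    3.6-Mbp MHC-like locus (so roughly 200 SNPs fall inside it), MAF drawn
    uniformly on [0.01, 0.5], and a 1% missing-call rate typical of
    unphased genotype releases.
    """

    n_couples: int = 30
    n_snps: int = 2000
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: {"6": 36_000_000})
    mhc_region: RegionSpec | None = DEFAULT_MHC
    maf_dist: Tuple = ("uniform", 0.01, 0.5)
    mhc_maf_dist: Tuple | None = None  # optional override inside mhc_region
    missing_rate: float = 0.01
    mating_beta: float = 0.0
    mating_locus: RegionSpec | None = None  # defaults to mhc_region when beta > 0
    planted_relatives: Tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_couples < 2:
            raise ValueError("need at least 2 couples")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.mating_beta < 0:
            raise ValueError("mating_beta must be >= 0")
        for kind in self.planted_relatives:
            if kind not in _RELATIVE_KINDS:
                raise ValueError(f"unknown relative kind {kind!r}")
        if 2 * len(self.planted_relatives) > self.n_couples:
            raise ValueError("too many planted relative pairs for the cohort size")
        if self.mating_beta > 0 and self.mating_locus is None and self.mhc_region is None:
            raise ValueError("mating_beta > 0 requires a mating locus")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    mate_assignment: list
    relative_pairs: list  # (sample_a, sample_b, kind)
    allele_freq_b: np.ndarray  # per-SNP true frequency of allele_b
    beta: float
    mating_locus: RegionSpec | None

    def to_json(self, path) -> None:
        locus = None
        if self.mating_locus is not None:
            locus = {
                "chromosome": self.mating_locus.chromosome,
                "start": self.mating_locus.start,
                "end": self.mating_locus.end,
            }
        with open(path, "w") as fh:
            json.dump(
                {
                    "mate_assignment": [list(p) for p in self.mate_assignment],
                    "relative_pairs": [list(p) for p in self.relative_pairs],
                    "allele_freq_b": self.allele_freq_b.tolist(),
                    "beta": self.beta,
                    "mating_locus": locus,
                },
                fh,
            )


def _draw_freqs(dist: Tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    name = dist[0]
    if name == "uniform":
        lo, hi = dist[1], dist[2]
        return rng.uniform(lo, hi, size=n)
    if name == "two_point":
        # mixture of two uniform bands, e.g. a low-MAF-rich vs common-rich chip
        (_, band1, band2, w) = dist
        pick = rng.random(n) < w
        f = np.empty(n)
        f[pick] = rng.uniform(band1[0], band1[1], size=int(pick.sum()))
        f[~pick] = rng.uniform(band2[0], band2[1], size=int((~pick).sum()))
        return f
    raise ValueError(f"unknown MAF distribution {name!r}")


def _positions(chrom_lengths: Mapping[str, int], n_snps: int, rng: np.random.Generator):
    """Evenly spaced, jittered SNP positions; counts proportional to length."""
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(n_snps * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-(n_snps * lengths / lengths.sum() - counts)):
        if counts.sum() >= n_snps:
            break
        counts[i] += 1
    out_chrom, out_pos = [], []
    for chrom, count, length in zip(chroms, counts, lengths):
        spacing = length / max(count, 1)
        jitter = rng.uniform(0.05, 0.95, size=count)
        pos = np.floor((np.arange(count) + jitter) * spacing).astype(np.int64) + 1
        pos = np.clip(pos, 1, int(length))
        out_chrom.extend([chrom] * count)
        out_pos.append(pos)
    return np.array(out_chrom), np.concatenate(out_pos) if out_pos else np.array([], int)


def _mendelian_child(
    father: np.ndarray, mother: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Child dosage by independent transmission: allele b passed w.p. dosage/2."""
    from_f = rng.random(father.shape) < father / 2.0
    from_m = rng.random(mother.shape) < mother / 2.0
    return (from_f.astype(np.int8) + from_m.astype(np.int8))


def _locus_identity(gm: np.ndarray, gf: np.ndarray) -> np.ndarray:
    """Pairwise locus Q (het-het score 1) between male and female dosage blocks."""
    n_m, n_f = len(gm), len(gf)
    q = np.empty((n_m, n_f))
    for i in range(n_m):
        q[i] = 1.0 - np.abs(gm[i][None, :] - gf).mean(axis=1) / 2.0
    return q


def _match_couples(
    gm_locus: np.ndarray,
    gf_locus: np.ndarray,
    beta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign each male a female; returns female index per male."""
    k = len(gm_locus)
    if beta == 0:
        return rng.permutation(k)
    q = _locus_identity(gm_locus, gf_locus)
    mu, sd = q.mean(), q.std()
    z = (q - mu) / sd if sd > 0 else np.zeros_like(q)
    assignment = np.full(k, -1, dtype=int)
    free = list(range(k))
    for male in rng.permutation(k):
        w = np.exp(-beta * z[male, free])
        w /= w.sum()
        pick = rng.choice(len(free), p=w)
        assignment[male] = free.pop(pick)
    return assignment


def simulate_cohort(config: SimConfig):
    """Generate ``(GenotypePanel, SampleSheet, SimTruth)`` for one cohort."""
    root = np.random.SeedSequence(config.seed)
    r_snp, r_geno, r_rel, r_mate, r_child, r_miss = (
        np.random.default_rng(s) for s in root.spawn(6)
    )
    k = config.n_couples
    n = config.n_snps

    chrom, pos = _positions(config.chrom_lengths, n, r_snp)
    freqs = _draw_freqs(config.maf_dist, n, r_snp)
    if config.mhc_maf_dist is not None and config.mhc_region is not None:
        in_mhc = np.array(
            [config.mhc_region.contains(c, p) for c, p in zip(chrom, pos)]
        )
        freqs[in_mhc] = _draw_freqs(config.mhc_maf_dist, int(in_mhc.sum()), r_snp)
    allele_idx = np.array([r_snp.choice(4, size=2, replace=False) for _ in range(n)])
    allele_a = _ALLELES[allele_idx[:, 0]] if n else np.array([], dtype="U1")
    allele_b = _ALLELES[allele_idx[:, 1]] if n else np.array([], dtype="U1")

    males = r_geno.binomial(2, freqs, size=(k, n)).astype(np.int8)
    females = r_geno.binomial(2, freqs, size=(k, n)).astype(np.int8)

    # planted relatives occupy successive male slots (always distinct couples)
    relative_slots = []
    slot = 0
    for kind in config.planted_relatives:
        a, b = slot, slot + 1
        slot += 2
        if kind == "duplicate":
            males[b] = males[a]
        elif kind == "parent-offspring":
            hidden = r_rel.binomial(2, freqs, size=n).astype(np.int8)
            males[b] = _mendelian_child(males[a], hidden, r_rel)
        elif kind == "full-sib":
            hp1 = r_rel.binomial(2, freqs, size=n).astype(np.int8)
            hp2 = r_rel.binomial(2, freqs, size=n).astype(np.int8)
            males[a] = _mendelian_child(hp1, hp2, r_rel)
            males[b] = _mendelian_child(hp1, hp2, r_rel)
        relative_slots.append((a, b, kind))

    locus = config.mating_locus
    if locus is None and config.mating_beta > 0:
        locus = config.mhc_region
    if config.mating_beta > 0:
        in_locus = np.array([locus.contains(c, p) for c, p in zip(chrom, pos)])
        if not in_locus.any():
            raise ValueError("mating locus contains no SNPs")
        assignment = _match_couples(
            males[:, in_locus], females[:, in_locus], config.mating_beta, r_mate
        )
    else:
        assignment = _match_couples(males, females, 0.0, r_mate)

    fam_ids = [f"FAM{i + 1:03d}" for i in range(k)]
    sample_rows = []
    geno_rows = []
    father_ids = []
    for i, fam in enumerate(fam_ids):
        f_id, m_id, c_id = f"{fam}_fa", f"{fam}_mo", f"{fam}_ch"
        father = males[i]
        mother = females[assignment[i]]
        child = _mendelian_child(father, mother, r_child)
        child_sex = "M" if r_child.random() < 0.5 else "F"
        sample_rows += [
            (f_id, fam, "father", "M", "SIM"),
            (m_id, fam, "mother", "F", "SIM"),
            (c_id, fam, "child", child_sex, "SIM"),
        ]
        geno_rows += [father, mother, child]
        father_ids.append(f_id)

    genotypes = np.array(geno_rows, dtype=np.int8)
    if config.missing_rate > 0:
        mask = r_miss.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:06d}" for i in range(n)],
            "chrom": chrom,
            "pos": pos,
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    samples = [row[0] for row in sample_rows]
    panel = GenotypePanel(snps, samples, genotypes)
    sheet = SampleSheet(pd.DataFrame(sample_rows, columns=[
        "sample_id", "family_id", "role", "sex", "cohort_tag"
    ]))

    female_of = {i: f"FAM{i + 1:03d}_mo" for i in range(k)}
    mate_assignment = [(father_ids[i], female_of[i]) for i in range(k)]
    relative_pairs = [
        (father_ids[a], father_ids[b], kind) for a, b, kind in relative_slots
    ]
    truth = SimTruth(
        mate_assignment=mate_assignment,
        relative_pairs=relative_pairs,
        allele_freq_b=freqs,
        beta=config.mating_beta,
        mating_locus=locus if config.mating_beta > 0 else None,
    )
    return panel, sheet, truth


def simulate_map(
    chrom_lengths: Mapping[str, int],
    base_rate: float = 1.0,
    hotspot: Tuple[RegionSpec, float] | None = None,
    point_spacing: int = 100_000,
) -> GeneticMap:
    """Piecewise-linear genetic map at ``base_rate`` cM/Mbp.

    ``hotspot`` multiplies the local rate inside one region, producing a
    steeper cumulative-cM slope there.
    """
    points = {}
    for chrom, length in chrom_lengths.items():
        pos = np.arange(1, length + 1, point_spacing, dtype=np.int64)
        if pos[-1] != length:
            pos = np.append(pos, length)
        cm = np.empty(len(pos))
        prev_cm = 0.0
        prev_pos = pos[0]
        cm[0] = 0.0
        for i in range(1, len(pos)):
            a, b = prev_pos, pos[i]
            seg_cm = base_rate * (b - a) / 1e6
            if hotspot is not None:
                region, mult = hotspot
                if region.chromosome == normalize_chrom(chrom):
                    ov = max(0, min(b, region.end) - max(a, region.start))
                    seg_cm += base_rate * (mult - 1.0) * ov / 1e6
            prev_cm += seg_cm
            cm[i] = prev_cm
            prev_pos = b
        points[str(chrom)] = (pos, cm)
    return GeneticMap(points)
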