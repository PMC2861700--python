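"""Genotype panel input/output, allele-frequency computation, and SNP filters.

A :class:`GenotypePanel` holds a samples x SNPs matrix of unordered biallelic
genotypes.  Internally each call is stored as the dosage of the SNP's second
allele (``allele_b``): 0, 1 or 2, with ``-1`` marking a missing call.  This
encoding makes allele-sharing computations pure integer arithmetic while the
readers/writers speak the two text dialects used for legacy trio panels:

``hapmap_text``
    whitespace-delimited, header ``rs# alleles chrom pos <sample ids...>``,
    one row per SNP with two-letter genotype tokens (``AG``), missing ``NN``.
``matrix_tsv``
    TSV with columns ``snp_id  chrom  pos  alleleA  alleleB`` followed by one
    column per sample, same genotype tokens.

Coordinates are 1-based and region endpoints are inclusive on both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
_MISSING_CHAR = "N"
_AUTOSOMES = frozenset(str(i) for i in range(1, 23))

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label by stripping any leading ``chr`` prefix."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def is_autosome(label: str) -> bool:
    return normalize_chrom(label) in _AUTOSOMES


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based, both-ends-inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        if self.start < 1:
            raise ValueError(f"region start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == self.chromosome and self.start <= pos <= self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return (
            normalize_chrom(chrom) == self.chromosome
            and start <= self.end
            and end >= self.start
        )

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse ``chr6:29700000-33300000`` style strings."""
        chrom, _, span = text.partition(":")
        lo, _, hi = span.partition("-")
        return cls(chrom, int(lo.replace(",", "")), int(hi.replace(",", "")))


class GenotypePanel:
    """Samples x SNPs genotype matrix with per-SNP metadata.

    Parameters
    ----------
    snps:
        DataFrame with columns ``snp_id, chrom, pos, allele_a, allele_b`` and
        optionally ``maf`` (NaN until computed).
    samples:
        Ordered sample identifiers.
    genotypes:
        int8 array of shape ``(n_samples, n_snps)`` holding allele-b dosages
        in {0, 1, 2} or :data:`MISSING`.
    """

    def __init__(self, snps: pd.DataFrame, samples: Sequence[str], genotypes: np.ndarray):
        snps = snps.reset_index(drop=True).copy()
        missing_cols = [c for c in SNP_COLUMNS if c not in snps.columns]
        if missing_cols:
            raise ValueError(f"snp table missing columns: {missing_cols}")
        if "maf" not in snps.columns:
            snps["maf"] = np.nan
        snps["chrom"] = snps["chrom"].map(normalize_chrom)
        if snps["snp_id"].duplicated().any():
            dups = snps.loc[snps["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicated SNP ids: {dups}")
        if (snps["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1")
        if (snps["allele_a"] == snps["allele_b"]).any():
            bad = snps.loc[snps["allele_a"] == snps["allele_b"], "snp_id"].tolist()
            raise ValueError(f"SNPs with identical allele symbols: {bad}")
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(samples), len(snps)):
            raise ValueError(
                f"genotype matrix shape {genotypes.shape} does not match "
                f"{len(samples)} samples x {len(snps)} SNPs"
            )
        if genotypes.size and (
            (genotypes < MISSING).any() or (genotypes > 2).any()
        ):
            raise ValueError("genotype dosages must be in {-1, 0, 1, 2}")
        self.snps = snps
        self.samples = list(samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")
        self.genotypes = genotypes

    # -- basic introspection -------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in panel") from None

    def subset_snps(self, mask_or_index) -> "GenotypePanel":
        idx = np.arange(self.n_snps)[mask_or_index]
        return GenotypePanel(
            self.snps.iloc[idx], self.samples, self.genotypes[:, idx]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypePanel":
        idx = self.sample_indices(sample_ids)
        return GenotypePanel(self.snps, list(sample_ids), self.genotypes[idx])

    def sorted_by_position(self) -> "GenotypePanel":
        order = np.lexsort((self.snps["pos"].to_numpy(), self.snps["chrom"].to_numpy()))
        return self.subset_snps(order)

    def call_strings(self) -> np.ndarray:
        """Genotype tokens (``'AG'``/``'NN'``) as a samples x SNPs array."""
        a = self.snps["allele_a"].to_numpy(dtype="U1")
        b = self.snps["allele_b"].to_numpy(dtype="U1")
        g = self.genotypes
        tokens = np.empty(g.shape, dtype="U2")
        tokens[g == 0] = np.broadcast_to(np.char.add(a, a), g.shape)[g == 0]
        tokens[g == 1] = np.broadcast_to(np.char.add(a, b), g.shape)[g == 1]
        tokens[g == 2] = np.broadcast_to(np.char.add(b, b), g.shape)[g == 2]
        tokens[g == MISSING] = _MISSING_CHAR * 2
        return tokens

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypePanel({self.n_samples} samples x {self.n_snps} SNPs)"


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "family_id", "role", "sex", "cohort_tag"]
_ROLES = {"father", "mother", "child"}
_SEXES = {"M", "F"}


class SampleSheet:
    """Per-sample metadata for trio cohorts (id, family, role, sex, cohort)."""

    def __init__(self, table: pd.DataFrame):
        table = table.reset_index(drop=True).copy()
        missing = [c for c in SHEET_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if table["sample_id"].duplicated().any():
            raise ValueError("duplicated sample ids in sample sheet")
        bad_roles = set(table["role"]) - _ROLES
        if bad_roles:
            raise ValueError(f"unknown roles: {bad_roles}")
        bad_sex = set(table["sex"]) - _SEXES
        if bad_sex:
            raise ValueError(f"unknown sex codes: {bad_sex}")
        for role, sex in (("father", "M"), ("mother", "F")):
            sub = table[table["role"] == role]
            if (sub["sex"] != sex).any():
                raise ValueError(f"{role} rows must have sex {sex}")
            if sub["family_id"].duplicated().any():
                raise ValueError(f"family with more than one {role}")
        self.table = table

    def parents(self) -> pd.DataFrame:
        return self.table[self.table["role"].isin(["father", "mother"])]

    def role_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["role"].iloc[0]


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel readers / writers
# ---------------------------------------------------------------------------

def _tokens_to_dosage(tokens: np.ndarray, allele_a: np.ndarray, allele_b: np.ndarray) -> np.ndarray:
    """Vectorized genotype-token decoding.

    ``tokens`` is (n_snps, n_samples) of 2-char strings; alleles are per-SNP.
    Tokens containing the missing character become MISSING; any other token
    not written in the SNP's two alleles is an error.
    """
    tokens = np.ascontiguousarray(tokens, dtype="U2")
    n_snps, n_samples = tokens.shape
    lengths = np.char.str_len(tokens)
    if (lengths != 2).any():
        i, j = np.argwhere(lengths != 2)[0]
        raise ValueError(f"malformed genotype token {tokens[i, j]!r} (SNP row {i})")
    chars = tokens.view("U1").reshape(n_snps, n_samples, 2)
    a = allele_a.astype("U1")[:, None]
    b = allele_b.astype("U1")[:, None]
    is_missing = (chars == _MISSING_CHAR).any(axis=2)
    dosage = ((chars[:, :, 0] == b).astype(np.int8) + (chars[:, :, 1] == b).astype(np.int8))
    known = ((chars == a[:, :, None]) | (chars == b[:, :, None])).all(axis=2)
    bad = ~known & ~is_missing
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype token {tokens[i, j]!r} uses alleles outside "
            f"{{{allele_a[i]},{allele_b[i]}}} (SNP row {i})"
        )
    dosage[is_missing] = MISSING
    return dosage.T  # samples x SNPs


def read_panel(path, format: str = "hapmap_text") -> GenotypePanel:
    """Read a genotype panel from ``hapmap_text`` or ``matrix_tsv``."""
    path = Path(path)
    if format == "hapmap_text":
        return _read_hapmap_text(path)
    if format == "matrix_tsv":
        return _read_matrix_tsv(path)
    raise ValueError(f"unknown panel format {format!r}")


def _read_hapmap_text(path: Path) -> GenotypePanel:
    with open(path) as fh:
        header = fh.readline().split()
    if len(header) < 4 or header[1] != "alleles":
        raise ValueError(f"{path}: not a hapmap_text header: {header[:4]}")
    samples = header[4:]
    df = pd.read_csv(path, sep=r"\s+", skiprows=1, header=None, dtype=str)
    if df.shape[1] != 4 + len(samples):
        raise ValueError(
            f"{path}: rows have {df.shape[1] - 4} genotype columns but header "
            f"names {len(samples)} samples"
        )
    alleles = df.iloc[:, 1].str.split("/", expand=True)
    if alleles.shape[1] != 2 or alleles.isna().any().any():
        raise ValueError(f"{path}: alleles column must look like 'A/G'")
    snps = pd.DataFrame(
        {
            "snp_id": df.iloc[:, 0],
            "chrom": df.iloc[:, 2],
            "pos": df.iloc[:, 3].astype(int),
            "allele_a": alleles[0],
            "allele_b": alleles[1],
        }
    )
    tokens = df.iloc[:, 4:].to_numpy(dtype="U2")
    dosage = _tokens_to_dosage(
        tokens, snps["allele_a"].to_numpy(), snps["allele_b"].to_numpy()
    )
    return GenotypePanel(snps, samples, dosage)


def _read_matrix_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = ["snp_id", "chrom", "pos", "alleleA", "alleleB"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: matrix_tsv missing columns {missing}")
    samples = [c for c in df.columns if c not in meta]
    snps = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "chrom": df["chrom"],
            "pos": df["pos"].astype(int),
            "allele_a": df["alleleA"],
            "allele_b": df["alleleB"],
        }
    )
    tokens = df[samples].to_numpy(dtype="U2")
    dosage = _tokens_to_dosage(
        tokens, snps["allele_a"].to_numpy(), snps["allele_b"].to_numpy()
    )
    return GenotypePanel(snps, samples, dosage)


def write_panel(panel: GenotypePanel, path, format: str = "hapmap_text") -> None:
    path = Path(path)
    tokens = panel.call_strings().T  # SNPs x samples
    if format == "hapmap_text":
        with open(path, "w") as fh:
            fh.write("rs# alleles chrom pos " + " ".join(panel.samples) + "\n")
            for i in range(panel.n_snps):
                row = panel.snps.iloc[i]
                fh.write(
                    f"{row.snp_id} {row.allele_a}/{row.allele_b} "
                    f"{row.chrom} {row.pos} " + " ".join(tokens[i]) + "\n"
                )
    elif format == "matrix_tsv":
        out = pd.DataFrame(
            {
                "snp_id": panel.snps["snp_id"],
                "chrom": panel.snps["chrom"],
                "pos": panel.snps["pos"],
                "alleleA": panel.snps["allele_a"],
                "alleleB": panel.snps["allele_b"],
            }
        )
        for j, s in enumerate(panel.samples):
            out[s] = tokens[:, j]
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown panel format {format!r}")


# ---------------------------------------------------------------------------
# allele frequencies and filters
# ---------------------------------------------------------------------------

def compute_maf(panel: GenotypePanel, samples: Sequence[str] | None = None) -> GenotypePanel:
    """Set per-SNP minor-allele frequencies from a sample subset (in place).

    The MAF is the frequency of the less-frequent allele among non-missing
    calls of the chosen samples; an exact tie gives 0.5.  SNPs with zero
    usable calls get ``maf = NaN`` and a warning.  Returns the same panel for
    chaining.
    """
    if samples is None:
        samples = panel.samples
    if len(samples) == 0:
        raise ValueError("compute_maf requires a non-empty sample subset")
    g = panel.genotypes[panel.sample_indices(samples)]
    valid = g != MISSING
    n_alleles = 2 * valid.sum(axis=0)
    b_count = np.where(valid, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_alleles > 0, b_count / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    n_undefined = int(np.isnan(maf).sum())
    if n_undefined:
        warnings.warn(
            f"{n_undefined} SNP(s) have no non-missing calls in the chosen "
            "subset; their MAF is undefined",
            stacklevel=2,
        )
    panel.snps["maf"] = maf
    return panel


def filter_maf(panel: GenotypePanel, threshold: float) -> GenotypePanel:
    """Keep SNPs with computed ``maf >= threshold`` (undefined MAF drops)."""
    maf = panel.snps["maf"].to_numpy()
    if np.isnan(maf).all() and panel.n_snps > 0 and threshold > 0:
        raise ValueError("filter_maf called before compute_maf")
    keep = maf >= threshold  # NaN compares False
    if threshold == 0:
        keep = keep | np.isnan(maf)
    if not keep.any() and panel.n_snps > 0:
        warnings.warn("filter_maf removed every SNP", stacklevel=2)
    return panel.subset_snps(keep)


def subset_region(panel: GenotypePanel, region: RegionSpec) -> GenotypePanel:
    """Keep SNPs inside a region (both endpoints inclusive)."""
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    keep = (chrom == region.chromosome) & (pos >= region.start) & (pos <= region.end)
    return panel.subset_snps(keep)


def exclude_region(panel: GenotypePanel, region: RegionSpec) -> GenotypePanel:
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    drop = (chrom == region.chromosome) & (pos >= region.start) & (pos <= region.end)
    return panel.subset_snps(~drop)


def autosomal_only(panel: GenotypePanel) -> GenotypePanel:
    """Drop SNPs on X, Y, MT or any non-numeric chromosome label."""
    keep = panel.snps["chrom"].map(is_autosome).to_numpy()
    return panel.subset_snps(keep)
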