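"""Shared fixtures and oracle helpers for the matekin test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from matekin import CoupleSet, GenotypePanel, SimConfig, simulate_cohort
from matekin.relatedness import per_snp_identity

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


def build_panel(snp_meta, samples, dosages):
    """Construct a panel from per-SNP metadata and a samples x SNPs dosage list.

    ``snp_meta`` rows: (snp_id, chrom, pos, allele_a, allele_b); dosage -1 is
    missing.
    """
    snps = pd.DataFrame(snp_meta, columns=["snp_id", "chrom", "pos", "allele_a", "allele_b"])
    return GenotypePanel(snps, samples, np.array(dosages, dtype=np.int8))


def panel_from_tokens(alleles, samples, token_rows):
    """Panel from genotype tokens, e.g. alleles=[("A","G")], rows=[["AG","NN"]]."""
    meta = [
        (f"rs{i + 1}", "6", 1000 * (i + 1), a, b) for i, (a, b) in enumerate(alleles)
    ]
    dosages = []
    for j in range(len(samples)):
        row = []
        for i, (a, b) in enumerate(alleles):
            tok = token_rows[i][j]
            if "N" in tok:
                row.append(-1)
            else:
                row.append(sum(ch == b for ch in tok))
        dosages.append(row)
    return build_panel(meta, samples, dosages)


def dosage_call(dosage, allele_a, allele_b):
    """Dosage -> unordered allele-pair tuple (None for missing)."""
    if dosage < 0:
        return None
    return ((allele_a, allele_a), (allele_a, allele_b), (allele_b, allele_b))[dosage]


def brute_force_q(panel, sample_a, sample_b, scoring):
    """Allele-by-allele identity oracle, independent of the matrix path."""
    ia = panel.samples.index(sample_a)
    ib = panel.samples.index(sample_b)
    scores = []
    for j in range(panel.n_snps):
        row = panel.snps.iloc[j]
        ca = dosage_call(panel.genotypes[ia, j], row.allele_a, row.allele_b)
        cb = dosage_call(panel.genotypes[ib, j], row.allele_a, row.allele_b)
        s = per_snp_identity(ca, cb, scoring)
        if s is not None:
            scores.append(s)
    return float(np.mean(scores)) if scores else float("nan")


@pytest.fixture(scope="session")
def small_cohort():
    """A clean 5-couple cohort (no missing, no relatives) plus its couples."""
    panel, sheet, truth = simulate_cohort(
        SimConfig(n_couples=5, n_snps=300, missing_rate=0.0, seed=42)
    )
    return panel, sheet, truth, CoupleSet.from_sample_sheet(sheet)


@pytest.fixture(scope="session")
def null_cohort():
    """Default study conditions: 30 couples, 2000 SNPs, random mating."""
    panel, sheet, truth = simulate_cohort(SimConfig(seed=7))
    return panel, sheet, truth, CoupleSet.from_sample_sheet(sheet)
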