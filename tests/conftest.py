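"""Shared fixtures and dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ldecay import GenotypeDataset, SampleRecord, SnpRecord


def make_dataset(
    dosages,
    chromosomes=None,
    positions=None,
    snp_ids=None,
    alleles=None,
) -> GenotypeDataset:
    """Build a GenotypeDataset from a dosage matrix with default metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_snps = dosages.shape
    if chromosomes is None:
        chromosomes = ["1"] * n_snps
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_snps)]
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(n_snps)]
    if alleles is None:
        alleles = [("A", "B")] * n_snps
    snps = [
        SnpRecord(snp_ids[j], str(chromosomes[j]), int(positions[j]), *alleles[j])
        for j in range(n_snps)
    ]
    samples = [SampleRecord("F", f"i{i + 1}") for i in range(n_samples)]
    return GenotypeDataset(samples=samples, snps=snps, dosages=dosages)


def random_dosages(rng: np.random.Generator, n_samples: int, n_snps: int, missing_rate: float = 0.1) -> np.ndarray:
    d = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    d[rng.random(d.shape) < missing_rate] = -1
    return d


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240317)
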