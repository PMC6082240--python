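"""Minor-allele-frequency estimation and the five-bin MAF spectrum.

The spectrum uses the conventional chip-QC categories
[0.03, 0.1), [0.1, 0.2), [0.2, 0.3), [0.3, 0.4) and [0.4, 0.5]: every edge
belongs to the upper bin except 0.5, which closes the last bin.  SNPs with
MAF below 0.03 are tallied separately as "excluded" and do not enter the
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeDataset
from .qc import GenotypeCounts, genotype_count_matrix, _maf_from_count_matrix

__all__ = [
    "BIN_EDGES",
    "MafSpectrum",
    "minor_allele_freq",
    "maf_vector",
    "classify_maf_bin",
    "maf_spectrum",
    "maf_summary",
    "spectra_to_frame",
]

BIN_EDGES: tuple[float, ...] = (0.03, 0.1, 0.2, 0.3, 0.4, 0.5)

EXCLUDED = 0  #: bin code for MAF below the first edge


def minor_allele_freq(counts: GenotypeCounts) -> float:
    """MAF from genotype counts, missing genotypes excluded.

    p = (2*n_hom_a2 + n_het) / (2*n_called); returns min(p, 1-p).  Raises on
    an all-missing SNP, where the frequency is undefined.
    """
    n_called = counts.n_called
    if n_called == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    p = (2 * counts.n_hom_a2 + counts.n_het) / (2 * n_called)
    return min(p, 1.0 - p)


def maf_vector(dataset: GenotypeDataset) -> np.ndarray:
    """Per-SNP MAF for a dataset; NaN marks all-missing SNPs."""
    return _maf_from_count_matrix(genotype_count_matrix(dataset))


def classify_maf_bin(maf: float) -> int:
    """Bin index 1..5 for the five spectrum categories, or EXCLUDED (0).

    Edges belong to the upper bin; the last bin is closed at 0.5.
    """
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    if maf < BIN_EDGES[0]:
        return EXCLUDED
    for k in range(1, len(BIN_EDGES) - 1):
        if maf < BIN_EDGES[k]:
            return k
    return len(BIN_EDGES) - 1  # [0.4, 0.5], closed


@dataclass
class MafSpectrum:
    """Counts and proportions of SNPs in the five MAF categories."""

    grouping: str
    counts: list[int]
    n_excluded: int = 0
    bin_edges: tuple[float, ...] = BIN_EDGES

    @property
    def n_binned(self) -> int:
        return int(sum(self.counts))

    @property
    def proportions(self) -> list[float]:
        """Fractions over the five bins; NaN everywhere if the group is empty."""
        total = self.n_binned
        if total == 0:
            return [float("nan")] * len(self.counts)
        return [c / total for c in self.counts]

    def to_frame(self) -> pd.DataFrame:
        edges = self.bin_edges
        return pd.DataFrame(
            {
                "grouping": self.grouping,
                "bin_lo": edges[:-1],
                "bin_hi": edges[1:],
                "count": self.counts,
                "proportion": self.proportions,
            }
        )


def maf_spectrum(dataset: GenotypeDataset, grouping: str = "genome") -> list[MafSpectrum]:
    """Spectrum genome-wide (``grouping="genome"``) or one per chromosome.

    All-missing SNPs (undefined MAF) are not counted at all; MAF below the
    first edge counts toward ``n_excluded`` only.
    """
    mafs = maf_vector(dataset)
    if grouping == "genome":
        groups = [("genome", np.ones(dataset.n_snps, dtype=bool))]
    elif grouping == "chromosome":
        chroms = dataset.chromosomes
        seen: list[str] = []
        for c in chroms:
            if c not in seen:
                seen.append(c)
        groups = [(c, chroms == c) for c in seen]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    out: list[MafSpectrum] = []
    n_bins = len(BIN_EDGES) - 1
    for label, mask in groups:
        vals = mafs[mask]
        vals = vals[~np.isnan(vals)]
        counts = [0] * n_bins
        excluded = 0
        for v in vals:
            b = classify_maf_bin(float(v))
            if b == EXCLUDED:
                excluded += 1
            else:
                counts[b - 1] += 1
        out.append(MafSpectrum(grouping=str(label), counts=counts, n_excluded=excluded))
    return out


def maf_summary(dataset: GenotypeDataset) -> dict[str, float]:
    """Mean and sample SD of per-SNP MAF (all-missing SNPs skipped)."""
    mafs = maf_vector(dataset)
    mafs = mafs[~np.isnan(mafs)]
    if mafs.size == 0:
        return {"n_snps": 0, "mean_maf": float("nan"), "sd_maf": float("nan")}
    sd = float(np.std(mafs, ddof=1)) if mafs.size > 1 else float("nan")
    return {"n_snps": int(mafs.size), "mean_maf": float(np.mean(mafs)), "sd_maf": sd}


def spectra_to_frame(spectra: list[MafSpectrum]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in spectra], ignore_index=True)
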