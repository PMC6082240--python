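"""Pairwise linkage disequilibrium as genotype-dosage r².

The LD measure is the squared Pearson correlation between the 0/1/2 dosage
vectors of two SNPs, computed over samples called at both ("pairwise
complete").  It is symmetric, invariant to swapping either SNP's allele
labels (dosage d -> 2 - d), and needs no phase information.  A two-locus EM
haplotype-frequency estimator (D, D', haplotype r²) is provided as an
independent cross-check of the dosage statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset

__all__ = [
    "LdPair",
    "PairCounts",
    "HaplotypeEstimate",
    "genotype_r2",
    "em_haplotype_freqs",
    "pairwise_ld",
    "ld_pair_frame",
]


@dataclass(frozen=True)
class LdPair:
    """One same-chromosome SNP pair with its distance and dosage r²."""

    snp_i: str
    snp_j: str
    chromosome: str
    distance_bp: int
    r_squared: float
    n_complete: int


@dataclass
class PairCounts:
    """Bookkeeping for a pairwise-LD scan: what was emitted and what was not."""

    n_candidate: int = 0      # same-chromosome pairs within the distance cap
    n_emitted: int = 0
    n_undefined: int = 0      # zero variance or < 2 complete observations
    n_zero_distance: int = 0  # duplicate physical positions, excluded
    n_filtered: int = 0       # defined r2 below the r2_min prefilter

    def as_dict(self) -> dict[str, int]:
        return {
            "n_candidate": self.n_candidate,
            "n_emitted": self.n_emitted,
            "n_undefined": self.n_undefined,
            "n_zero_distance": self.n_zero_distance,
            "n_filtered": self.n_filtered,
        }


def genotype_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> tuple[float, int]:
    """Squared Pearson correlation of two dosage vectors.

    Only samples non-missing at both SNPs enter the correlation.  Returns
    ``(r2, n_complete)``; ``r2`` is NaN when fewer than 2 complete pairs
    remain or either SNP has zero variance among them.
    """
    a = np.asarray(dosage_a)
    b = np.asarray(dosage_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and of equal length")
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    if n < 2:
        return float("nan"), n
    x = a[ok].astype(np.float64)
    y = b[ok].astype(np.float64)
    x -= x.mean()
    y -= y.mean()
    sxx = float(x @ x)
    syy = float(y @ y)
    if sxx == 0.0 or syy == 0.0:
        return float("nan"), n
    sxy = float(x @ y)
    return min(1.0, sxy * sxy / (sxx * syy)), n


# ---------------------------------------------------------------------------
# two-locus EM (validation oracle for the dosage r²)
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeEstimate:
    """EM estimate of the four two-locus haplotype frequencies.

    Haplotypes are labelled by copies of each SNP's a2 allele: AB carries a2
    at both loci, ab at neither.  D = freq_AB - pA*pB with pA, pB the a2
    frequencies; D' normalizes D by its admissible extreme; r²_hap is
    D²/(pA qA pB qB).
    """

    freq_AB: float
    freq_Ab: float
    freq_aB: float
    freq_ab: float
    D: float
    D_prime: float
    r_squared_hap: float
    iterations: int
    converged: bool

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.freq_AB, self.freq_Ab, self.freq_aB, self.freq_ab])


def em_haplotype_freqs(
    dosage_a: np.ndarray,
    dosage_b: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HaplotypeEstimate:
    """Maximum-likelihood haplotype frequencies from unphased genotypes.

    Every genotype combination except the double heterozygote determines its
    two haplotypes; the double het is split between the coupling (AB/ab) and
    repulsion (Ab/aB) phases, starting from an equal split and iterating the
    standard EM update until the largest frequency change drops below
    ``tol``.
    """
    a = np.asarray(dosage_a)
    b = np.asarray(dosage_b)
    ok = (a != MISSING) & (b != MISSING)
    a = a[ok].astype(np.int64)
    b = b[ok].astype(np.int64)
    n = a.size
    if n == 0:
        raise ValueError("no complete genotype pairs")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("EM requires both SNPs polymorphic")

    # 3x3 table of genotype pair counts
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    n_dh = int(table[1, 1])  # double heterozygotes: phase unknown

    # haplotype counts contributed by unambiguous genotypes
    # index order: AB, Ab, aB, ab  (A/B = a2 allele at locus a / locus b)
    fixed = np.zeros(4)
    contrib = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    for (ga, gb), hap in contrib.items():
        c = table[ga, gb]
        if c:
            fixed += c * np.asarray(hap, dtype=float)

    total = 2.0 * n
    freqs = (fixed + n_dh * np.array([0.5, 0.5, 0.5, 0.5])) / total
    converged = n_dh == 0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if n_dh == 0:
            break
        coupling = freqs[0] * freqs[3]
        repulsion = freqs[1] * freqs[2]
        denom = coupling + repulsion
        w = 0.5 if denom == 0.0 else coupling / denom
        new = (fixed + n_dh * np.array([w, 1 - w, 1 - w, w])) / total
        delta = np.abs(new - freqs).max()
        freqs = new
        if delta < tol:
            converged = True
            break

    pA = freqs[0] + freqs[1]
    pB = freqs[0] + freqs[2]
    D = freqs[0] - pA * pB
    denom_r2 = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom_r2 if denom_r2 > 0 else float("nan")
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else float("nan")
    return HaplotypeEstimate(
        freq_AB=float(freqs[0]),
        freq_Ab=float(freqs[1]),
        freq_aB=float(freqs[2]),
        freq_ab=float(freqs[3]),
        D=float(D),
        D_prime=float(dprime),
        r_squared_hap=float(r2),
        iterations=iterations,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# all-pairs scan within a distance cap
# ---------------------------------------------------------------------------


def pairwise_ld(
    dataset: GenotypeDataset,
    max_distance_bp: int,
    r2_min: float = 0.0,
    counts: PairCounts | None = None,
) -> Iterator[LdPair]:
    """Yield every same-chromosome SNP pair within ``max_distance_bp``.

    The dataset must be sorted by (chromosome, position).  Pairs with
    undefined r² (monomorphic among complete samples, or < 2 complete
    samples) and pairs at zero distance (duplicate positions) are skipped
    and tallied in ``counts``; when ``r2_min > 0`` defined pairs below the
    prefilter are likewise skipped and tallied.

    The scan is windowed per chromosome but is exactly equivalent to the
    all-pairs double loop with the same distance cap.
    """
    if max_distance_bp <= 0:
        raise ValueError("max_distance_bp must be positive")
    if not dataset.is_sorted():
        raise ValueError(
            "dataset is not sorted by (chromosome, position); "
            "call dataset.sorted_by_position() first"
        )
    if counts is None:
        counts = PairCounts()

    chroms = dataset.chromosomes
    positions = dataset.positions_bp
    snp_ids = dataset.snp_ids
    dosages = dataset.dosages

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        for ii in range(idx.size - 1):
            hi = int(np.searchsorted(pos, pos[ii] + max_distance_bp, side="right"))
            for jj in range(ii + 1, hi):
                counts.n_candidate += 1
                dist = int(pos[jj] - pos[ii])
                if dist == 0:
                    counts.n_zero_distance += 1
                    continue
                r2, n_complete = genotype_r2(dosages[:, idx[ii]], dosages[:, idx[jj]])
                if np.isnan(r2):
                    counts.n_undefined += 1
                    continue
                if r2_min > 0.0 and r2 < r2_min:
                    counts.n_filtered += 1
                    continue
                counts.n_emitted += 1
                yield LdPair(
                    snp_i=str(snp_ids[idx[ii]]),
                    snp_j=str(snp_ids[idx[jj]]),
                    chromosome=str(chrom),
                    distance_bp=dist,
                    r_squared=r2,
                    n_complete=n_complete,
                )


def ld_pair_frame(
    dataset: GenotypeDataset,
    max_distance_bp: int,
    r2_min: float = 0.0,
) -> tuple[pd.DataFrame, PairCounts]:
    """Materialize :func:`pairwise_ld` as a DataFrame plus its tallies.

    Uses a vectorized per-anchor window so large panels stay fast; results
    are identical to the generator (and to the brute-force double loop).
    """
    if max_distance_bp <= 0:
        raise ValueError("max_distance_bp must be positive")
    if not dataset.is_sorted():
        raise ValueError(
            "dataset is not sorted by (chromosome, position); "
            "call dataset.sorted_by_position() first"
        )
    counts = PairCounts()
    chroms = dataset.chromosomes
    positions = dataset.positions_bp
    snp_ids = dataset.snp_ids
    dos = dataset.dosages.astype(np.float64)
    valid = dataset.dosages != MISSING
    dos[~valid] = 0.0

    cols: dict[str, list] = {k: [] for k in ("chromosome", "snp_i", "snp_j", "distance_bp", "r_squared", "n_complete")}

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        X = dos[:, idx]
        V = valid[:, idx]
        for ii in range(idx.size - 1):
            hi = int(np.searchsorted(pos, pos[ii] + max_distance_bp, side="right"))
            if hi <= ii + 1:
                continue
            js = np.arange(ii + 1, hi)
            counts.n_candidate += js.size
            dists = pos[js] - pos[ii]

            xa = X[:, ii][:, None]
            va = V[:, ii][:, None]
            xb = X[:, js]
            vb = V[:, js]
            both = va & vb
            n = both.sum(axis=0).astype(np.float64)
            sa = (xa * both).sum(axis=0)
            sb = (xb * both).sum(axis=0)
            saa = (xa * xa * both).sum(axis=0)
            sbb = (xb * xb * both).sum(axis=0)
            sab = (xa * xb * both).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sab - sa * sb / n
                var_a = saa - sa * sa / n
                var_b = sbb - sb * sb / n
                r2 = cov * cov / (var_a * var_b)
            r2 = np.minimum(r2, 1.0)
            undefined = (n < 2) | (var_a <= 0) | (var_b <= 0)
            r2[undefined] = np.nan

            zero_d = dists == 0
            counts.n_zero_distance += int(zero_d.sum())
            bad = np.isnan(r2) & ~zero_d
            counts.n_undefined += int(bad.sum())
            keep = ~zero_d & ~np.isnan(r2)
            if r2_min > 0.0:
                below = keep & (r2 < r2_min)
                counts.n_filtered += int(below.sum())
                keep &= ~below
            if not keep.any():
                continue
            kj = js[keep]
            counts.n_emitted += kj.size
            cols["chromosome"].extend([str(chrom)] * kj.size)
            cols["snp_i"].extend([str(snp_ids[idx[ii]])] * kj.size)
            cols["snp_j"].extend(str(snp_ids[idx[j]]) for j in kj)
            cols["distance_bp"].extend(int(d) for d in dists[keep])
            cols["r_squared"].extend(float(v) for v in r2[keep])
            cols["n_complete"].extend(int(v) for v in n[keep])

    frame = pd.DataFrame(cols)
    frame["distance_bp"] = frame["distance_bp"].astype(np.int64)
    return frame, counts
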