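"""Forward Wright-Fisher genotype simulation and LD-based Ne estimation.

The simulator produces SNP-chip-like panels with controlled
population-genetic structure.  Founder haplotypes are drawn in linkage
equilibrium (per-SNP allele frequencies from a configurable law), so all
terminal LD is generated by drift during the simulated generations — which
is exactly the regime Sved's approximation

    E[r²] ≈ 1 / (1 + 4 Ne c)            (+ 1/n with a sample-size correction)

describes for a neutral population of effective size Ne and recombination
fraction c.  ``fit_ne_from_decay`` inverts that relation by least squares on
a binned decay curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from .decay import DecayCurve
from .io import MISSING, GenotypeDataset, SampleRecord, SnpRecord

__all__ = [
    "SimConfig",
    "SvedFit",
    "simulate_wright_fisher",
    "simulate_block_ld",
    "expected_r2_sved",
    "fit_ne_from_decay",
]


@dataclass(frozen=True)
class SimConfig:
    """Wright-Fisher run parameters.

    ``recomb_rate_per_bp`` is in Morgans per bp per meiosis (1e-8 equals the
    usual 1 cM/Mb).  ``init_maf_law`` is ("uniform", lo, hi): each SNP's
    founder allele-1 frequency is an independent uniform draw, and founder
    haplotypes carry independent Bernoulli alleles, i.e. no initial LD.
    ``positions`` may be "equally_spaced" or an explicit list of 1-based bp
    positions per chromosome.  Chromosomes are simulated as independent
    replicates of the same population process (free recombination between
    chromosomes).
    """

    effective_size_ne: int = 100
    generations: int = 100
    n_sample: int = 50
    n_snps: int = 200
    chromosome_length_bp: int = 10_000_000
    recomb_rate_per_bp: float = 1e-8
    init_maf_law: tuple = ("uniform", 0.05, 0.5)
    positions: str | Sequence[int] = "equally_spaced"
    n_chromosomes: int = 1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effective_size_ne < 2:
            raise ValueError("effective_size_ne must be >= 2 diploids")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 1 <= self.n_sample <= self.effective_size_ne:
            raise ValueError("n_sample must be in [1, effective_size_ne]")
        if self.n_snps < 1 or self.chromosome_length_bp < 1 or self.n_chromosomes < 1:
            raise ValueError("sizes must be positive")
        if self.recomb_rate_per_bp < 0:
            raise ValueError("recomb_rate_per_bp must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "init_maf_law" in raw:
            raw["init_maf_law"] = tuple(raw["init_maf_law"])
        if "positions" in raw and not isinstance(raw["positions"], str):
            raw["positions"] = tuple(raw["positions"])
        return cls(**raw)

    def snp_positions(self) -> np.ndarray:
        """1-based bp positions of the markers on one chromosome."""
        if isinstance(self.positions, str):
            if self.positions != "equally_spaced":
                raise ValueError(f"unknown positions spec {self.positions!r}")
            spacing = self.chromosome_length_bp / self.n_snps
            return np.round(spacing * np.arange(1, self.n_snps + 1)).astype(np.int64)
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.size != self.n_snps or np.any(np.diff(pos) < 0) or pos[0] < 1:
            raise ValueError("explicit positions must be n_snps sorted 1-based values")
        return pos


def _draw_init_freqs(law: tuple, n_snps: int, rng: np.random.Generator) -> np.ndarray:
    name = law[0]
    if name == "uniform":
        lo, hi = float(law[1]), float(law[2])
        return rng.uniform(lo, hi, size=n_snps)
    if name == "beta":
        a, b = float(law[1]), float(law[2])
        return rng.beta(a, b, size=n_snps)
    raise ValueError(f"unknown init_maf_law {name!r}")


def _evolve_chromosome(
    haps: np.ndarray, pos_morgans: np.ndarray, generations: int, rng: np.random.Generator
) -> np.ndarray:
    """Evolve 2N haplotypes for ``generations`` of random-mating reproduction.

    Haplotypes 2k and 2k+1 form diploid k.  Each offspring gamete comes from
    a uniformly chosen parent diploid; crossovers per meiosis are Poisson
    with mean equal to the chromosome map length, at uniform map positions,
    without interference.
    """
    n_hap, _ = haps.shape
    n_dip = n_hap // 2
    lo, hi = float(pos_morgans[0]), float(pos_morgans[-1])
    map_len = hi - lo
    for _ in range(generations):
        parents = rng.integers(0, n_dip, size=n_hap)
        n_cross = rng.poisson(map_len, size=n_hap)
        start = rng.integers(0, 2, size=n_hap)
        new = np.empty_like(haps)
        for g in range(n_hap):
            h0 = haps[2 * parents[g]]
            h1 = haps[2 * parents[g] + 1]
            if n_cross[g] == 0:
                new[g] = h1 if start[g] else h0
            else:
                cuts = np.sort(rng.uniform(lo, hi, size=n_cross[g]))
                phase = (np.searchsorted(cuts, pos_morgans, side="right") + start[g]) % 2
                new[g] = np.where(phase == 0, h0, h1)
        haps = new
    return haps


def simulate_wright_fisher(
    config: SimConfig, return_haplotypes: bool = False
) -> GenotypeDataset | tuple[GenotypeDataset, np.ndarray]:
    """Simulate a diploid genotype panel under neutral Wright-Fisher drift.

    Returns a :class:`GenotypeDataset` of ``n_sample`` individuals at
    ``n_snps * n_chromosomes`` biallelic SNPs; dosage counts the allele
    labelled a2 ("B").  With ``return_haplotypes=True`` also returns the
    sampled haplotype matrix (2*n_sample, total SNPs) for validation.
    Output is a pure function of the config, including the seed.
    """
    rng = np.random.default_rng(config.seed)
    pos_bp = config.snp_positions()
    pos_m = pos_bp.astype(np.float64) * config.recomb_rate_per_bp

    sample_idx = rng.choice(config.effective_size_ne, size=config.n_sample, replace=False)
    hap_idx = np.empty(2 * config.n_sample, dtype=np.int64)
    hap_idx[0::2] = 2 * sample_idx
    hap_idx[1::2] = 2 * sample_idx + 1

    all_haps: list[np.ndarray] = []
    snps: list[SnpRecord] = []
    for chrom in range(1, config.n_chromosomes + 1):
        freqs = _draw_init_freqs(config.init_maf_law, config.n_snps, rng)
        haps = (
            rng.random((2 * config.effective_size_ne, config.n_snps)) < freqs
        ).astype(np.uint8)
        haps = _evolve_chromosome(haps, pos_m, config.generations, rng)
        all_haps.append(haps[hap_idx])
        snps.extend(
            SnpRecord(
                snp_id=f"snp_{chrom}_{k + 1}",
                chromosome=str(chrom),
                position_bp=int(pos_bp[k]),
                allele_a1="A",
                allele_a2="B",
            )
            for k in range(config.n_snps)
        )

    hap_matrix = np.concatenate(all_haps, axis=1)
    dosages = (hap_matrix[0::2] + hap_matrix[1::2]).astype(np.int8)
    if config.missing_rate > 0.0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    samples = [SampleRecord("SIM", f"ind_{i + 1}") for i in range(config.n_sample)]
    dataset = GenotypeDataset(samples=samples, snps=snps, dosages=dosages)
    if return_haplotypes:
        return dataset, hap_matrix
    return dataset


def simulate_block_ld(
    haplotype_freqs: Sequence[float],
    n_sample: int,
    seed: int,
    positions_bp: tuple[int, int] = (1_000, 11_000),
    chromosome: str = "1",
) -> GenotypeDataset:
    """Two-SNP panel drawn from exact haplotype frequencies (AB, Ab, aB, ab).

    2*n_sample haplotypes are drawn multinomially and paired at random into
    diploids, so the population LD of the returned pair is known in closed
    form: D = f_AB - pA pB, r² = D²/(pA qA pB qB).  Useful as an exact-LD
    fixture for validating dosage-r² estimators.
    """
    f = np.asarray(haplotype_freqs, dtype=np.float64)
    if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype_freqs must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(1, f, size=2 * n_sample).argmax(axis=1)
    # haplotype index -> (allele at SNP 1, allele at SNP 2); allele 1 == a2
    hap_alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
    alleles = hap_alleles[draws]
    rng.shuffle(alleles, axis=0)
    dosages = alleles[0::2] + alleles[1::2]

    pa = f[0] + f[1]
    pb = f[0] + f[2]
    monomorphic = pa in (0.0, 1.0) or pb in (0.0, 1.0)
    snps = [
        SnpRecord("block_1", chromosome, positions_bp[0], "A", "B"),
        SnpRecord("block_2", chromosome, positions_bp[1], "A", "B"),
    ]
    samples = [SampleRecord("BLK", f"ind_{i + 1}") for i in range(n_sample)]
    ds = GenotypeDataset(samples=samples, snps=snps, dosages=dosages.astype(np.int8))
    ds.monomorphic_warning = bool(monomorphic)  # advisory flag, not an error
    return ds


def expected_r2_sved(ne: float, c_morgans: float, sample_n: int | None = None) -> float:
    """Sved's drift expectation E[r²] = 1/(1 + 4 Ne c), capped at 1.

    With ``sample_n`` the finite-sample inflation 1/n is added — the squared
    correlation estimated from n diploids has that expectation even for
    unlinked loci.
    """
    if ne <= 0:
        raise ValueError("ne must be positive")
    if c_morgans < 0:
        raise ValueError("recombination fraction must be >= 0")
    val = 1.0 / (1.0 + 4.0 * ne * c_morgans)
    if sample_n is not None:
        val += 1.0 / sample_n
    return min(1.0, val)


@dataclass(frozen=True)
class SvedFit:
    """Least-squares fit of Sved's curve to a binned decay curve."""

    ne_hat: float
    residual_sse: float
    n_bins_used: int
    sample_size_correction: bool
    converged: bool


def fit_ne_from_decay(
    curve: DecayCurve,
    bp_per_morgan: float = 1e8,
    sample_n: int | None = None,
    allow_filtered: bool = False,
) -> SvedFit:
    """Estimate effective population size from an LD decay curve.

    Minimizes sum over non-empty bins of
    ``(mean_r2 - expected_r2_sved(Ne, midpoint/bp_per_morgan, sample_n))²``
    over log Ne (bounded, deterministic).  Curves built from pairs
    prefiltered at r² >= r2_min are refused unless ``allow_filtered`` — the
    floor inflates bin means and biases Ne downward.
    """
    if curve.r2_min_applied > 0.0 and not allow_filtered:
        raise ValueError(
            "decay curve was built with an r2 prefilter; refit from unfiltered "
            "pairs or pass allow_filtered=True"
        )
    occupied = [b for b in curve.bins if b.n_pairs > 0 and np.isfinite(b.mean_r2)]
    if len(occupied) < 3:
        raise ValueError("Ne fit needs at least 3 non-empty bins")
    c = np.array([b.midpoint_bp for b in occupied]) / bp_per_morgan
    y = np.array([b.mean_r2 for b in occupied])
    if np.ptp(y) < 1e-9:
        raise SvedFitError("decay curve is flat; Ne is not identifiable")

    offset = 1.0 / sample_n if sample_n else 0.0

    def residuals(log_ne: np.ndarray) -> np.ndarray:
        ne = np.exp(log_ne[0])
        return np.minimum(1.0 / (1.0 + 4.0 * ne * c) + offset, 1.0) - y

    # coarse deterministic grid start, then bounded least squares
    grid = np.linspace(np.log(1.0), np.log(1e7), 60)
    sses = [float(np.sum(residuals(np.array([g])) ** 2)) for g in grid]
    x0 = grid[int(np.argmin(sses))]
    sol = least_squares(
        residuals,
        x0=np.array([x0]),
        bounds=(np.log(1e-3), np.log(1e9)),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    ne_hat = float(np.exp(sol.x[0]))
    return SvedFit(
        ne_hat=ne_hat,
        residual_sse=float(np.sum(sol.fun**2)),
        n_bins_used=len(occupied),
        sample_size_correction=sample_n is not None,
        converged=bool(sol.success),
    )


class SvedFitError(RuntimeError):
    """Raised when the decay curve carries no information about Ne."""
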