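"""SNP quality-control cascade for chip genotype panels.

Filters, applied in a fixed order with each removed SNP attributed to the
first filter that rejects it:

1. call rate strictly below ``min_call_rate`` (default 0.90);
2. degenerate Hardy-Weinberg departure: both homozygote classes observed but
   zero heterozygotes;
3. exact conditional Hardy-Weinberg test p-value strictly below ``hwe_alpha``
   (default 1e-6);
4. unknown genomic position (position_bp == 0);
5. non-autosomal chromosome label;
6. minor allele frequency strictly below ``maf_floor`` (default 0.03; a SNP
   at exactly the floor is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeDataset, subset

__all__ = [
    "GenotypeCounts",
    "QcConfig",
    "QcReport",
    "FILTER_ORDER",
    "snp_genotype_counts",
    "genotype_count_matrix",
    "call_rate",
    "no_het_extreme_departure",
    "hwe_exact_pvalue",
    "apply_qc",
]

FILTER_ORDER: tuple[str, ...] = (
    "call_rate",
    "no_het",
    "hwe",
    "unknown_position",
    "sex_chromosome",
    "maf",
)

DEFAULT_AUTOSOMES: frozenset[str] = frozenset(str(c) for c in range(1, 30))


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-SNP genotype tally; the four classes partition the samples."""

    n_hom_a1: int
    n_het: int
    n_hom_a2: int
    n_missing: int

    def __post_init__(self) -> None:
        if min(self.n_hom_a1, self.n_het, self.n_hom_a2, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_hom_a1 + self.n_het + self.n_hom_a2 + self.n_missing

    @property
    def n_called(self) -> int:
        return self.n_hom_a1 + self.n_het + self.n_hom_a2


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the QC cascade.

    ``maf_drop_equal`` switches the MAF rule from "remove < floor" (default,
    so the lowest spectrum bin starting at the floor stays populated) to
    "remove <= floor".
    """

    min_call_rate: float = 0.90
    maf_floor: float = 0.03
    maf_drop_equal: bool = False
    hwe_alpha: float = 1e-6
    apply_no_het_rule: bool = True
    autosomes: frozenset[str] = DEFAULT_AUTOSOMES

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "maf_floor", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        object.__setattr__(self, "autosomes", frozenset(self.autosomes))


@dataclass
class QcReport:
    """Per-filter removal counts; input = sum(removed) + retained."""

    n_input_snps: int
    removed_call_rate: int
    removed_no_het: int
    removed_hwe: int
    removed_unknown_position: int
    removed_sex_chromosome: int
    removed_maf: int
    n_retained: int
    filter_order: tuple[str, ...] = FILTER_ORDER
    retained_snp_ids: list[str] = field(default_factory=list)

    @property
    def removed_total(self) -> int:
        return (
            self.removed_call_rate
            + self.removed_no_het
            + self.removed_hwe
            + self.removed_unknown_position
            + self.removed_sex_chromosome
            + self.removed_maf
        )

    def removed_by_filter(self) -> dict[str, int]:
        return {
            "call_rate": self.removed_call_rate,
            "no_het": self.removed_no_het,
            "hwe": self.removed_hwe,
            "unknown_position": self.removed_unknown_position,
            "sex_chromosome": self.removed_sex_chromosome,
            "maf": self.removed_maf,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input_snps)]
        rows += [(f"removed_{k}", v) for k, v in self.removed_by_filter().items()]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["stage", "n_snps"])

    def write_csv(self, path: str | Path, snp_list_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if snp_list_path is not None:
            Path(snp_list_path).write_text(
                "".join(f"{s}\n" for s in self.retained_snp_ids)
            )


# ---------------------------------------------------------------------------
# per-SNP statistics
# ---------------------------------------------------------------------------


def genotype_count_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """(n_snps, 4) array of [n_hom_a1, n_het, n_hom_a2, n_missing]."""
    d = dataset.dosages
    return np.stack(
        [(d == 0).sum(axis=0), (d == 1).sum(axis=0), (d == 2).sum(axis=0), (d == MISSING).sum(axis=0)],
        axis=1,
    ).astype(np.int64)


def snp_genotype_counts(dataset: GenotypeDataset) -> list[GenotypeCounts]:
    """Tally genotype classes for every SNP."""
    return [GenotypeCounts(*row) for row in genotype_count_matrix(dataset)]


def call_rate(counts: GenotypeCounts) -> float:
    """Fraction of samples with a non-missing genotype."""
    n = counts.n_samples
    if n == 0:
        raise ValueError("call rate undefined for zero samples")
    return counts.n_called / n


def no_het_extreme_departure(counts: GenotypeCounts) -> bool:
    """Both homozygote classes present, zero heterozygotes.

    The degenerate Hardy-Weinberg violation: any mixture of the two
    homozygotes without a single het is essentially impossible under random
    mating and flags assay artefacts.  Monomorphic SNPs do not trigger it.
    """
    return counts.n_hom_a1 > 0 and counts.n_hom_a2 > 0 and counts.n_het == 0


def hwe_exact_pvalue(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, by probability mass).

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity, 0..n_rare) whose conditional
    probability does not exceed that of the observed count.  Monomorphic
    SNPs return 1.0 by convention.
    """
    n = counts.n_called
    if n == 0:
        raise ValueError("HWE test undefined with no called genotypes")
    n_a1 = 2 * counts.n_hom_a1 + counts.n_het
    n_a2 = 2 * counts.n_hom_a2 + counts.n_het
    n_rare = min(n_a1, n_a2)
    if n_rare == 0:
        return 1.0

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(h | n, n_rare) up to a shared constant:
    #   P ~ 2^h * n! / (hom_r! h! hom_c!) / C(2n, n_rare)
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == counts.n_het][0]
    # 1e-12 relative slack guards against ties broken by rounding
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _maf_from_count_matrix(cm: np.ndarray) -> np.ndarray:
    """Minor allele frequency per SNP; NaN when all genotypes are missing."""
    called = cm[:, 0] + cm[:, 1] + cm[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * cm[:, 2] + cm[:, 1]) / (2 * called)
    maf = np.minimum(p, 1.0 - p)
    maf[called == 0] = np.nan
    return maf


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


def apply_qc(dataset: GenotypeDataset, config: QcConfig | None = None) -> tuple[GenotypeDataset, QcReport]:
    """Run the QC cascade and return (filtered dataset, removal report).

    Each SNP is attributed to the first filter in :data:`FILTER_ORDER` that
    rejects it, so the report's counts always reconcile with the retained
    total.  Applying the cascade twice with the same config removes nothing
    on the second pass.
    """
    if config is None:
        config = QcConfig()
    if dataset.n_snps == 0 or dataset.n_samples == 0:
        raise ValueError("apply_qc requires a non-empty dataset")

    cm = genotype_count_matrix(dataset)
    called = cm[:, :3].sum(axis=1)
    n = dataset.n_samples

    rates = called / n
    fail_call = rates < config.min_call_rate

    fail_nohet = np.zeros(dataset.n_snps, dtype=bool)
    if config.apply_no_het_rule:
        fail_nohet = (cm[:, 0] > 0) & (cm[:, 2] > 0) & (cm[:, 1] == 0)

    fail_hwe = np.zeros(dataset.n_snps, dtype=bool)
    if config.hwe_alpha > 0.0:
        pending = ~(fail_call | fail_nohet) & (called > 0)
        for j in np.flatnonzero(pending):
            p = hwe_exact_pvalue(GenotypeCounts(*cm[j]))
            fail_hwe[j] = p < config.hwe_alpha

    positions = dataset.positions_bp
    fail_pos = positions == 0
    chroms = dataset.chromosomes
    fail_sex = ~np.isin(chroms, sorted(config.autosomes))

    maf = _maf_from_count_matrix(cm)
    if config.maf_drop_equal:
        fail_maf = maf <= config.maf_floor
    else:
        fail_maf = maf < config.maf_floor
    # an all-missing SNP has undefined MAF: remove it here only if a floor is set
    fail_maf = np.where(np.isnan(maf), config.maf_floor > 0.0, fail_maf)

    fail_stack = np.stack([fail_call, fail_nohet, fail_hwe, fail_pos, fail_sex, fail_maf])
    any_fail = fail_stack.any(axis=0)
    first_fail = np.where(any_fail, fail_stack.argmax(axis=0), -1)

    removed = [int((first_fail == k).sum()) for k in range(len(FILTER_ORDER))]
    keep = first_fail == -1
    filtered = subset(dataset, snp_mask=keep)

    report = QcReport(
        n_input_snps=dataset.n_snps,
        removed_call_rate=removed[0],
        removed_no_het=removed[1],
        removed_hwe=removed[2],
        removed_unknown_position=removed[3],
        removed_sex_chromosome=removed[4],
        removed_maf=removed[5],
        n_retained=int(keep.sum()),
        retained_snp_ids=[s.snp_id for s in filtered.snps],
    )
    return filtered, report
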