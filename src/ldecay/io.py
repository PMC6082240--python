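"""PLINK 1 genotype I/O and the in-memory genotype container.

Supports the text PED/MAP and binary BED/BIM/FAM formats (SNP-major BED,
magic bytes ``6C 1B 01``).  Genotypes are held as an additively coded dosage
matrix: each entry counts copies of ``allele_a2`` ("allele B"), so the codes
are 0 (hom a1), 1 (het), 2 (hom a2) and :data:`MISSING`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpRecord",
    "SampleRecord",
    "GenotypeDataset",
    "GenotypeFormatError",
    "GenotypeDataError",
    "read_ped_map",
    "write_ped_map",
    "read_bed_bim_fam",
    "write_bed_bim_fam",
    "subset",
]

#: Sentinel dosage for a missing genotype.  Kept negative so it can never be
#: mistaken for an allele count; all arithmetic must mask it out explicitly.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit PLINK BED code -> dosage (copies of allele_a2)
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
# dosage (indexed as dosage, with MISSING mapped to index 3) -> 2-bit code
_BED_ENCODE = np.array([0b00, 0b10, 0b11, 0b01], dtype=np.uint8)


class GenotypeFormatError(ValueError):
    """A file does not conform to the PLINK 1 format it claims to be."""


class GenotypeDataError(ValueError):
    """The file parses but its genotype content is invalid (e.g. >2 alleles)."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP: identifier, map location and the two observed alleles.

    ``position_bp`` is the 1-based physical coordinate; 0 encodes an unknown
    genomic position (PLINK convention).  ``chromosome`` is a string label:
    autosomes "1".."29" for cattle, with sex/unplaced codes ("X", "Y", "0",
    ...) passed through verbatim.
    """

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a1: str = "0"
    allele_a2: str = "0"

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"negative position for SNP {self.snp_id}")


@dataclass(frozen=True)
class SampleRecord:
    """One individual as described by a PED/FAM row."""

    family_id: str
    individual_id: str
    sex: str = "0"
    phenotype: str = "-9"

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix plus the per-row/column metadata.

    ``dosages[i, j]`` counts copies of ``snps[j].allele_a2`` carried by
    ``samples[i]`` and is one of {0, 1, 2, MISSING}.
    """

    samples: list[SampleRecord]
    snps: list[SnpRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or MISSING")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id values must be unique")
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("(family_id, individual_id) pairs must be unique")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps], dtype=object)

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.snps], dtype=np.int64)

    @property
    def snp_ids(self) -> np.ndarray:
        return np.array([s.snp_id for s in self.snps], dtype=object)

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chromosome": [s.chromosome for s in self.snps],
                "position_bp": [s.position_bp for s in self.snps],
                "allele_a1": [s.allele_a1 for s in self.snps],
                "allele_a2": [s.allele_a2 for s in self.snps],
            }
        )

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family_id": [s.family_id for s in self.samples],
                "individual_id": [s.individual_id for s in self.samples],
                "sex": [s.sex for s in self.samples],
                "phenotype": [s.phenotype for s in self.samples],
            }
        )

    def is_sorted(self) -> bool:
        """True if SNPs are grouped by chromosome with nondecreasing positions."""
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for s in self.snps:
            if s.chromosome != prev_chrom:
                if s.chromosome in seen:
                    return False
                seen.add(s.chromosome)
                prev_chrom = s.chromosome
                prev_pos = -1
            if s.position_bp < prev_pos:
                return False
            prev_pos = s.position_bp
        return True

    def sorted_by_position(self) -> "GenotypeDataset":
        """Copy with SNPs sorted by (chromosome, position); samples untouched."""
        order = sorted(
            range(self.n_snps),
            key=lambda j: (_chrom_sort_key(self.snps[j].chromosome), self.snps[j].position_bp),
        )
        return GenotypeDataset(
            samples=list(self.samples),
            snps=[self.snps[j] for j in order],
            dosages=self.dosages[:, order].copy(),
        )

    def subset(
        self,
        snp_mask: Sequence[bool] | np.ndarray | None = None,
        sample_mask: Sequence[bool] | np.ndarray | None = None,
    ) -> "GenotypeDataset":
        return subset(self, snp_mask, sample_mask)


def _chrom_sort_key(label: str) -> tuple[int, int | str]:
    try:
        return (0, int(label))
    except ValueError:
        return (1, label)


def subset(
    dataset: GenotypeDataset,
    snp_mask: Sequence[bool] | np.ndarray | None = None,
    sample_mask: Sequence[bool] | np.ndarray | None = None,
) -> GenotypeDataset:
    """Keep the SNPs/samples flagged True, preserving order.

    Masks must match the corresponding dimension exactly; ``None`` keeps
    everything along that axis.
    """
    if snp_mask is None:
        snp_mask = np.ones(dataset.n_snps, dtype=bool)
    if sample_mask is None:
        sample_mask = np.ones(dataset.n_samples, dtype=bool)
    snp_mask = np.asarray(snp_mask, dtype=bool)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    if snp_mask.shape != (dataset.n_snps,):
        raise ValueError(f"snp mask length {snp_mask.size} != n_snps {dataset.n_snps}")
    if sample_mask.shape != (dataset.n_samples,):
        raise ValueError(
            f"sample mask length {sample_mask.size} != n_samples {dataset.n_samples}"
        )
    return GenotypeDataset(
        samples=[s for s, k in zip(dataset.samples, sample_mask) if k],
        snps=[s for s, k in zip(dataset.snps, snp_mask) if k],
        dosages=dataset.dosages[np.ix_(sample_mask, snp_mask)].copy(),
    )


# ---------------------------------------------------------------------------
# PED / MAP (text)
# ---------------------------------------------------------------------------


def _read_map(map_path: str | os.PathLike) -> list[SnpRecord]:
    records: list[SnpRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 4:
                raise GenotypeFormatError(
                    f"{map_path}:{lineno}: MAP line has {len(cols)} columns, expected 4"
                )
            chrom, snp_id, _cm, bp = cols
            records.append(SnpRecord(snp_id=snp_id, chromosome=chrom, position_bp=int(bp)))
    return records


def read_ped_map(ped_path: str | os.PathLike, map_path: str | os.PathLike) -> GenotypeDataset:
    """Read a PLINK text fileset into a :class:`GenotypeDataset`.

    Allele assignment is data-driven: per SNP, the less frequent observed
    allele becomes ``allele_a1`` (ties broken lexicographically, smaller
    string first), the other becomes ``allele_a2``; dosage counts a2.  A
    genotype containing the missing code "0" on either chromosome is MISSING.
    """
    snps = _read_map(map_path)
    n_snps = len(snps)
    samples: list[SampleRecord] = []
    allele_rows: list[np.ndarray] = []

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 6 + 2 * n_snps:
                raise GenotypeFormatError(
                    f"{ped_path}:{lineno}: PED line has {len(cols)} columns, "
                    f"expected {6 + 2 * n_snps} for {n_snps} SNPs"
                )
            fid, iid, _pat, _mat, sex, pheno = cols[:6]
            samples.append(SampleRecord(fid, iid, sex, pheno))
            allele_rows.append(np.array(cols[6:], dtype=object).reshape(n_snps, 2))

    n_samples = len(samples)
    dosages = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    alleles = (
        np.stack(allele_rows, axis=0)
        if allele_rows
        else np.empty((0, n_snps, 2), dtype=object)
    )

    out_snps: list[SnpRecord] = []
    for j, snp in enumerate(snps):
        col = alleles[:, j, :] if n_samples else np.empty((0, 2), dtype=object)
        called = ~np.any(col == "0", axis=1) if n_samples else np.zeros(0, dtype=bool)
        observed = col[called].ravel()
        uniq, counts = np.unique(observed, return_counts=True)
        if uniq.size > 2:
            raise GenotypeDataError(
                f"SNP {snp.snp_id} has {uniq.size} distinct alleles: {sorted(uniq)}"
            )
        if uniq.size == 0:
            a1, a2 = "0", "0"
        elif uniq.size == 1:
            a1, a2 = "0", str(uniq[0])
        else:
            # minor-count allele -> a1; lexicographic tie-break (smaller first)
            order = np.lexsort((uniq, counts))
            a1, a2 = str(uniq[order[0]]), str(uniq[order[1]])
        out_snps.append(replace(snp, allele_a1=a1, allele_a2=a2))
        if n_samples and a2 != "0":
            dosages[called, j] = (col[called] == a2).sum(axis=1)
        elif n_samples:
            dosages[:, j] = MISSING

    return GenotypeDataset(samples=samples, snps=out_snps, dosages=dosages)


def write_ped_map(dataset: GenotypeDataset, prefix: str | os.PathLike) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` / ``<prefix>.map``; inverse of :func:`read_ped_map`.

    SNPs whose alleles were never observed are written with placeholder
    alleles so the round trip preserves the MISSING mask.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(dataset.samples):
            fields = [
                sample.family_id,
                sample.individual_id,
                "0",
                "0",
                sample.sex,
                sample.phenotype,
            ]
            for j, snp in enumerate(dataset.snps):
                d = dataset.dosages[i, j]
                a1 = snp.allele_a1 if snp.allele_a1 != "0" else "A"
                a2 = snp.allele_a2 if snp.allele_a2 != "0" else "B"
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1, a1]
                elif d == 1:
                    fields += [a1, a2]
                else:
                    fields += [a2, a2]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# BED / BIM / FAM (binary)
# ---------------------------------------------------------------------------


def _decode_bed_block(block: bytes, n_samples: int, n_snps: int) -> np.ndarray:
    """Unpack a SNP-major genotype block into an (n_samples, n_snps) matrix."""
    bytes_per_snp = (n_samples + 3) // 4
    raw = np.frombuffer(block, dtype=np.uint8)
    if raw.size != bytes_per_snp * n_snps:
        raise GenotypeFormatError(
            f"BED genotype block is {raw.size} bytes, expected "
            f"{bytes_per_snp * n_snps} for {n_samples} samples x {n_snps} SNPs"
        )
    raw = raw.reshape(n_snps, bytes_per_snp)
    # little-endian within each byte: sample i -> bits (2*(i%4), 2*(i%4)+1)
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    return _BED_DECODE[codes[:, :n_samples]].T.copy()


def _encode_bed_block(dosages: np.ndarray) -> bytes:
    n_samples, n_snps = dosages.shape
    bytes_per_snp = (n_samples + 3) // 4
    idx = np.where(dosages == MISSING, 3, dosages).astype(np.intp)
    codes = _BED_ENCODE[idx].T  # (n_snps, n_samples)
    padded = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_samples] = codes  # pad positions carry code 0b00, as PLINK does
    out = np.zeros((n_snps, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    return out.tobytes()


def read_bed_bim_fam(prefix: str | os.PathLike) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset (``<prefix>.bed/.bim/.fam``)."""
    prefix = Path(prefix)
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    bed_path = prefix.with_suffix(".bed")

    snps: list[SnpRecord] = []
    with open(bim_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 6:
                raise GenotypeFormatError(
                    f"{bim_path}:{lineno}: BIM line has {len(cols)} columns, expected 6"
                )
            chrom, snp_id, _cm, bp, a1, a2 = cols
            snps.append(SnpRecord(snp_id, chrom, int(bp), a1, a2))

    samples: list[SampleRecord] = []
    with open(fam_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 6:
                raise GenotypeFormatError(
                    f"{fam_path}:{lineno}: FAM line has {len(cols)} columns, expected 6"
                )
            samples.append(SampleRecord(cols[0], cols[1], cols[4], cols[5]))

    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[:2] != _BED_MAGIC:
            raise GenotypeFormatError(f"{bed_path}: bad magic bytes {header[:2]!r}")
        if header[2] != _BED_SNP_MAJOR:
            raise GenotypeFormatError(
                f"{bed_path}: mode byte 0x{header[2]:02x}; only SNP-major (0x01) "
                "BED files are supported"
            )
        block = fh.read()

    dosages = _decode_bed_block(block, len(samples), len(snps))
    return GenotypeDataset(samples=samples, snps=snps, dosages=dosages)


def write_bed_bim_fam(dataset: GenotypeDataset, prefix: str | os.PathLike) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.bed/.bim/.fam``; inverse of :func:`read_bed_bim_fam`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    with open(bim_path, "w") as fh:
        for s in dataset.snps:
            a1 = s.allele_a1 if s.allele_a1 != "0" else "A"
            a2 = s.allele_a2 if s.allele_a2 != "0" else "B"
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t{a1}\t{a2}\n")
    with open(fam_path, "w") as fh:
        for s in dataset.samples:
            fh.write(f"{s.family_id}\t{s.individual_id}\t0\t0\t{s.sex}\t{s.phenotype}\n")
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(_encode_bed_block(dataset.dosages))
    return bed_path, bim_path, fam_path
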