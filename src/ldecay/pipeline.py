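"""End-to-end pipeline: QC -> MAF spectrum -> LD pairs -> decay -> Ne fit.

``run_pipeline`` reproduces the standard chip-panel workflow on any PLINK
fileset and writes a bundle of CSV outputs plus a JSON manifest (config,
input checksums, pair-count bookkeeping).  Reruns with identical inputs and
config produce byte-identical CSVs.

``make_fixture`` builds small deterministic panels with known ground truth
(planted QC violations, exact haplotype frequencies, or a Wright-Fisher
config echo) for validating each stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .decay import bin_decay, crossing_distance
from .io import (
    MISSING,
    GenotypeDataset,
    SampleRecord,
    SnpRecord,
    read_bed_bim_fam,
    read_ped_map,
    write_bed_bim_fam,
    write_ped_map,
)
from .ld import ld_pair_frame
from .maf import maf_spectrum, maf_summary, spectra_to_frame
from .qc import QcConfig, apply_qc
from .simulate import SimConfig, fit_ne_from_decay, simulate_block_ld, simulate_wright_fisher

log = logging.getLogger("ldecay")

__all__ = ["RunConfig", "run_pipeline", "make_fixture"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``bin_specs`` lists (bin_width_bp, max_distance_bp) pairs; the defaults
    are the two conventional views of chip-panel decay, 1 kb bins out to
    200 kb and 100 kb bins out to 1 Mb.  ``r2_min`` prefilters pairs before
    binning (set 0 to disable); the Ne fit always uses unfiltered pairs.
    """

    input_prefix: str
    input_format: str = "bed"  # "bed" or "ped"
    qc: QcConfig = field(default_factory=QcConfig)
    bin_specs: tuple[tuple[int, int], ...] = ((1_000, 200_000), (100_000, 1_000_000))
    r2_min: float = 0.1
    r2_threshold: float = 0.3
    per_chromosome: bool = False
    fit_ne: bool = False
    bp_per_morgan: float = 1e8
    make_plots: bool = False
    output_dir: str = "ldecay_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bin_specs:
            raise ValueError("at least one (bin_width, max_distance) spec is required")
        if self.input_format not in ("bed", "ped"):
            raise ValueError("input_format must be 'bed' or 'ped'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_paths(config: RunConfig) -> list[Path]:
    prefix = Path(config.input_prefix)
    exts = (".bed", ".bim", ".fam") if config.input_format == "bed" else (".ped", ".map")
    return [prefix.with_suffix(e) for e in exts]


def load_dataset(config: RunConfig) -> GenotypeDataset:
    prefix = Path(config.input_prefix)
    if config.input_format == "bed":
        return read_bed_bim_fam(prefix)
    return read_ped_map(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary.

    Writes into ``config.output_dir``: qc_report.csv, retained_snps.txt,
    maf_spectrum.csv (genome + per chromosome), maf_summary.csv,
    decay_<width>.csv per bin spec, crossing_distances.csv, optional
    ne_fit.csv and plots, and manifest.json.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    inputs = _input_paths(config)
    for p in inputs:
        if not p.exists():
            raise FileNotFoundError(f"input file missing: {p}")
    checksums = {p.name: _sha256(p) for p in inputs}

    dataset = load_dataset(config)
    log.info("loaded %d samples x %d SNPs", dataset.n_samples, dataset.n_snps)

    filtered, report = apply_qc(dataset, config.qc)
    report.write_csv(out / "qc_report.csv", out / "retained_snps.txt")
    log.info("QC retained %d of %d SNPs", report.n_retained, report.n_input_snps)

    filtered = filtered.sorted_by_position()

    spectra = maf_spectrum(filtered, "genome") + maf_spectrum(filtered, "chromosome")
    spectra_to_frame(spectra).to_csv(out / "maf_spectrum.csv", index=False)
    summary = maf_summary(filtered)
    with open(out / "maf_summary.csv", "w") as fh:
        fh.write("n_snps,mean_maf,sd_maf\n")
        fh.write(f"{summary['n_snps']},{summary['mean_maf']:.6f},{summary['sd_maf']:.6f}\n")

    max_needed = max(m for _, m in config.bin_specs)
    pairs, counts = ld_pair_frame(filtered, max_needed, r2_min=config.r2_min)
    log.info(
        "LD scan: %d pairs emitted (%d undefined, %d below r2_min)",
        counts.n_emitted,
        counts.n_undefined,
        counts.n_filtered,
    )

    per_chrom_counts = (
        pairs.groupby("chromosome").size().to_dict() if len(pairs) else {}
    )

    crossing_rows = []
    curves_for_plot = []
    for width, max_dist in config.bin_specs:
        in_range = pairs[pairs["distance_bp"] <= max_dist]
        curve = bin_decay(
            in_range,
            bin_width_bp=width,
            max_distance_bp=max_dist,
            threshold=config.r2_threshold,
            r2_min_applied=config.r2_min,
        )
        curve.to_frame().to_csv(out / f"decay_{width}.csv", index=False)
        curves_for_plot.append(curve)
        try:
            cross = crossing_distance(curve, config.r2_threshold)
            crossing_rows.append(
                (width, max_dist, config.r2_threshold, cross.status, cross.distance_bp)
            )
        except ValueError:
            crossing_rows.append((width, max_dist, config.r2_threshold, "undefined", None))

        if config.per_chromosome:
            per_rows = []
            for chrom, grp in in_range.groupby("chromosome", sort=False):
                c = bin_decay(
                    grp,
                    bin_width_bp=width,
                    max_distance_bp=max_dist,
                    threshold=config.r2_threshold,
                    r2_min_applied=config.r2_min,
                    grouping=str(chrom),
                )
                per_rows.append(c.to_frame())
            if per_rows:
                import pandas as pd

                pd.concat(per_rows, ignore_index=True).to_csv(
                    out / f"decay_{width}_by_chromosome.csv", index=False
                )

    with open(out / "crossing_distances.csv", "w") as fh:
        fh.write("bin_width_bp,max_distance_bp,r2_level,status,distance_bp\n")
        for width, max_dist, level, status, dist in crossing_rows:
            d = "" if dist is None else f"{dist:.1f}"
            fh.write(f"{width},{max_dist},{level},{status},{d}\n")

    ne_result = None
    if config.fit_ne:
        # refit from unfiltered pairs: the r2_min floor biases Ne downward
        pairs_nf, _ = ld_pair_frame(filtered, max_needed, r2_min=0.0)
        width, max_dist = config.bin_specs[-1]
        curve_nf = bin_decay(
            pairs_nf[pairs_nf["distance_bp"] <= max_dist],
            bin_width_bp=width,
            max_distance_bp=max_dist,
            threshold=config.r2_threshold,
            r2_min_applied=0.0,
        )
        fit = fit_ne_from_decay(
            curve_nf, bp_per_morgan=config.bp_per_morgan, sample_n=dataset.n_samples
        )
        ne_result = {
            "ne_hat": fit.ne_hat,
            "residual_sse": fit.residual_sse,
            "n_bins_used": fit.n_bins_used,
        }
        with open(out / "ne_fit.csv", "w") as fh:
            fh.write("ne_hat,residual_sse,n_bins_used,sample_size_correction\n")
            fh.write(
                f"{fit.ne_hat:.4f},{fit.residual_sse:.6e},{fit.n_bins_used},"
                f"{fit.sample_size_correction}\n"
            )

    if config.make_plots:
        from .plotting import plot_decay_curve, plot_maf_spectrum

        plot_decay_curve(curves_for_plot[0], out / "decay_curve.png", config.r2_threshold)
        plot_maf_spectrum(spectra[0], out / "maf_spectrum.png")

    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "input_checksums": checksums,
        "n_samples": dataset.n_samples,
        "n_input_snps": dataset.n_snps,
        "qc": report.removed_by_filter() | {"retained": report.n_retained},
        "maf_summary": summary,
        "pair_counts": counts.as_dict(),
        "pair_counts_per_chromosome": {str(k): int(v) for k, v in per_chrom_counts.items()},
        "ne_fit": ne_result,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["qc"]["autosomes"] = sorted(d["qc"]["autosomes"])
    d["bin_specs"] = [list(b) for b in d["bin_specs"]]
    return d


# ---------------------------------------------------------------------------
# deterministic fixtures with ground truth
# ---------------------------------------------------------------------------


def _hwe_column(n: int) -> np.ndarray:
    """Genotype column at exact Hardy-Weinberg proportions for p = 0.5."""
    reps = n // 4
    col = [0] * reps + [1] * (2 * reps) + [2] * (n - 3 * reps)
    return np.array(col, dtype=np.int8)


def _qc_violation_dataset(n_samples: int = 48) -> tuple[GenotypeDataset, dict]:
    """20-SNP panel with planted violations: 3 call-rate, 2 no-het, 1 unknown
    position, 2 sex-chromosome, 4 low-MAF; 8 clean SNPs survive."""
    if n_samples % 4 or n_samples < 40:
        raise ValueError("n_samples must be a multiple of 4, >= 40")
    cols: list[np.ndarray] = []
    snps: list[SnpRecord] = []

    def add(col: np.ndarray, chrom: str, pos: int) -> None:
        snps.append(
            SnpRecord(f"snp_{len(snps) + 1:02d}", chrom, pos, "A", "B")
        )
        cols.append(col.astype(np.int8))

    base = _hwe_column(n_samples)
    n_miss = int(np.ceil(n_samples * 0.11))  # call rate ~0.89 < 0.90

    # 3 low call rate
    for k in range(3):
        col = base.copy()
        col[:n_miss] = MISSING
        add(col, "1", 1_000_000 * (k + 1))
    # 2 no-het (both homozygote classes, zero heterozygotes)
    for k in range(2):
        col = np.array([0] * (n_samples // 2) + [2] * (n_samples - n_samples // 2))
        add(col, "2", 1_000_000 * (k + 1))
    # 1 unknown position
    add(base.copy(), "3", 0)
    # 2 sex chromosome
    for k in range(2):
        add(base.copy(), "X", 1_000_000 * (k + 1))
    # 4 low MAF (single het => MAF = 1/(2n) < 0.03)
    for k in range(4):
        col = np.zeros(n_samples, dtype=np.int8)
        col[k] = 1
        add(col, "4", 1_000_000 * (k + 1))
    # 8 clean
    for k in range(8):
        add(base.copy(), "5", 1_000_000 * (k + 1))

    dosages = np.stack(cols, axis=1)
    samples = [SampleRecord("FIX", f"ind_{i + 1}") for i in range(n_samples)]
    truth = {
        "n_input_snps": 20,
        "removed_call_rate": 3,
        "removed_no_het": 2,
        "removed_hwe": 0,
        "removed_unknown_position": 1,
        "removed_sex_chromosome": 2,
        "removed_maf": 4,
        "n_retained": 8,
        "retained_snp_ids": [s.snp_id for s in snps if s.chromosome == "5"],
    }
    return GenotypeDataset(samples=samples, snps=snps, dosages=dosages), truth


def make_fixture(kind: str, params: dict | None, seed: int, out_dir: str | Path) -> dict:
    """Write a deterministic test panel plus a JSON truth file.

    Kinds: "wright_fisher" (params forwarded to :class:`SimConfig`),
    "block_ld" (params: haplotype_freqs, n_sample), "qc_violations"
    (params: n_samples).  Returns the truth dictionary; files are
    ``fixture.{bed,bim,fam}`` + ``fixture.{ped,map}`` + ``truth.json``.
    """
    params = dict(params or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if kind == "wright_fisher":
        config = SimConfig(**{"seed": seed, **params})
        dataset = simulate_wright_fisher(config)
        truth = {"kind": kind, "sim_config": _jsonable(asdict(config))}
    elif kind == "block_ld":
        freqs = params.pop("haplotype_freqs", (0.35, 0.15, 0.15, 0.35))
        n_sample = params.pop("n_sample", 1000)
        dataset = simulate_block_ld(freqs, n_sample=n_sample, seed=seed, **params)
        f = np.asarray(freqs, dtype=float)
        pa, pb = f[0] + f[1], f[0] + f[2]
        d_coef = f[0] - pa * pb
        denom = pa * (1 - pa) * pb * (1 - pb)
        truth = {
            "kind": kind,
            "haplotype_freqs": list(map(float, f)),
            "n_sample": n_sample,
            "population_D": float(d_coef),
            "population_r2": float(d_coef**2 / denom) if denom > 0 else None,
        }
    elif kind == "qc_violations":
        dataset, planted = _qc_violation_dataset(**params)
        truth = {"kind": kind, **planted}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    write_bed_bim_fam(dataset, out / "fixture")
    write_ped_map(dataset, out / "fixture")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out
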