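"""Thin presentation layer: decay-curve and MAF-spectrum figures.

Plots are drawn from the same aggregated objects the CSV outputs serialize;
nothing here recomputes statistics.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .decay import DecayCurve
from .maf import MafSpectrum

__all__ = ["plot_decay_curve", "plot_maf_spectrum"]


def plot_decay_curve(
    curves: DecayCurve | list[DecayCurve],
    path: str | Path,
    r2_level: float | None = 0.3,
) -> Path:
    """Mean r² against distance (bin midpoints), one line per curve."""
    if isinstance(curves, DecayCurve):
        curves = [curves]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for curve in curves:
        xs = [b.midpoint_bp / 1e3 for b in curve.bins if b.n_pairs > 0]
        ys = [b.mean_r2 for b in curve.bins if b.n_pairs > 0]
        ax.plot(xs, ys, marker="o", markersize=3, linewidth=1, label=curve.grouping)
    if r2_level is not None:
        ax.axhline(r2_level, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    ax.set_ylim(0, 1)
    if len(curves) > 1:
        ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_maf_spectrum(spectra: MafSpectrum | list[MafSpectrum], path: str | Path) -> Path:
    """Bar chart of SNP proportions per MAF category."""
    if isinstance(spectra, MafSpectrum):
        spectra = [spectra]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    n_groups = len(spectra)
    width = 0.8 / n_groups
    for g, spec in enumerate(spectra):
        edges = spec.bin_edges
        labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
        labels[-1] = labels[-1].replace(")", "]")
        xs = [k + g * width for k in range(len(spec.counts))]
        ax.bar(xs, spec.proportions, width=width, label=spec.grouping)
        if g == 0:
            ax.set_xticks([k + 0.4 - width / 2 for k in range(len(spec.counts))])
            ax.set_xticklabels(labels, fontsize=8)
    ax.set_xlabel("MAF category")
    ax.set_ylabel("proportion of SNPs")
    if n_groups > 1:
        ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
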