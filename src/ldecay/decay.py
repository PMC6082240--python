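"""Distance-binned LD decay curves and their summaries.

Pairs are grouped into contiguous distance windows of fixed width; each
window reports its pair count, mean and sample SD of r², and the share of
pairs at or above a reference r² level (0.3 by default, the conventional
minimum for reliable association mapping).  A crossing distance locates
where the binned mean first falls through a given r² level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .ld import LdPair

__all__ = [
    "DecayBin",
    "DecayCurve",
    "CrossingResult",
    "bin_decay",
    "crossing_distance",
    "decay_summary_table",
]


@dataclass(frozen=True)
class DecayBin:
    """One distance window [lo_bp, hi_bp); the final window closes at the cap."""

    lo_bp: int
    hi_bp: int
    n_pairs: int
    mean_r2: float
    sd_r2: float
    prop_ge_threshold: float

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.lo_bp + self.hi_bp)


@dataclass
class DecayCurve:
    """Ordered, contiguous decay bins covering (0, max_distance_bp]."""

    bins: list[DecayBin]
    bin_width_bp: int
    max_distance_bp: int
    threshold: float
    r2_min_applied: float
    grouping: str = "genome"

    @property
    def n_pairs_total(self) -> int:
        return sum(b.n_pairs for b in self.bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grouping": self.grouping,
                "lo_bp": [b.lo_bp for b in self.bins],
                "hi_bp": [b.hi_bp for b in self.bins],
                "n_pairs": [b.n_pairs for b in self.bins],
                "mean_r2": [b.mean_r2 for b in self.bins],
                "sd_r2": [b.sd_r2 for b in self.bins],
                "prop_ge_threshold": [b.prop_ge_threshold for b in self.bins],
            }
        )


def _as_arrays(pairs: Iterable[LdPair] | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        return (
            pairs["distance_bp"].to_numpy(np.int64),
            pairs["r_squared"].to_numpy(np.float64),
        )
    pair_list = list(pairs)
    return (
        np.array([p.distance_bp for p in pair_list], dtype=np.int64),
        np.array([p.r_squared for p in pair_list], dtype=np.float64),
    )


def bin_decay(
    pairs: Iterable[LdPair] | pd.DataFrame,
    bin_width_bp: int,
    max_distance_bp: int,
    threshold: float = 0.3,
    r2_min_applied: float = 0.0,
    grouping: str = "genome",
) -> DecayCurve:
    """Aggregate LD pairs into fixed-width distance bins.

    Bins are half-open [lo, hi) on distance, except the last which also
    takes pairs at exactly ``max_distance_bp`` so the cap itself is covered.
    Bin means/SDs are NaN when empty (SD also for singleton bins).  Pairs
    beyond the cap raise.
    """
    if bin_width_bp <= 0:
        raise ValueError("bin_width_bp must be positive")
    if max_distance_bp < bin_width_bp:
        raise ValueError("max_distance_bp must be at least one bin wide")
    dist, r2 = _as_arrays(pairs)
    if np.any(dist <= 0):
        raise ValueError("pair distances must be positive")
    if np.any(dist > max_distance_bp):
        raise ValueError("pair distance exceeds max_distance_bp")

    n_bins = int(np.ceil(max_distance_bp / bin_width_bp))
    which = np.minimum(dist // bin_width_bp, n_bins - 1).astype(np.int64)

    n = np.bincount(which, minlength=n_bins)
    s1 = np.bincount(which, weights=r2, minlength=n_bins)
    s2 = np.bincount(which, weights=r2 * r2, minlength=n_bins)
    ge = np.bincount(which, weights=(r2 >= threshold).astype(np.float64), minlength=n_bins)

    bins: list[DecayBin] = []
    for k in range(n_bins):
        lo = k * bin_width_bp
        hi = min((k + 1) * bin_width_bp, max_distance_bp)
        nk = int(n[k])
        if nk == 0:
            mean = sd = prop = float("nan")
        else:
            mean = s1[k] / nk
            prop = ge[k] / nk
            if nk >= 2:
                ss = max(s2[k] - nk * mean * mean, 0.0)
                sd = float(np.sqrt(ss / (nk - 1)))
            else:
                sd = float("nan")
        bins.append(
            DecayBin(lo_bp=lo, hi_bp=hi, n_pairs=nk, mean_r2=float(mean), sd_r2=sd, prop_ge_threshold=float(prop))
        )
    return DecayCurve(
        bins=bins,
        bin_width_bp=bin_width_bp,
        max_distance_bp=max_distance_bp,
        threshold=threshold,
        r2_min_applied=r2_min_applied,
        grouping=grouping,
    )


@dataclass(frozen=True)
class CrossingResult:
    """Where the binned mean r² first falls through a level.

    ``status`` is "interpolated" (distance is the linear interpolation
    between the midpoints of the straddling bins), "below_from_start" (the
    first non-empty bin is already below the level; its midpoint is
    returned), or "not_reached" (the mean never drops below the level within
    the curve; distance is None).
    """

    level: float
    distance_bp: float | None
    status: str
    bin_above: DecayBin | None = None
    bin_below: DecayBin | None = None


def crossing_distance(curve: DecayCurve, r2_level: float) -> CrossingResult:
    """Locate the distance at which mean r² decays to ``r2_level``.

    Scans non-empty bins in ascending distance for the first adjacent pair
    with mean_i >= level > mean_{i+1} and interpolates linearly between
    their midpoints.
    """
    occupied = [b for b in curve.bins if b.n_pairs > 0]
    if not occupied:
        raise ValueError("crossing distance undefined: all bins empty")
    if len(occupied) < 2:
        raise ValueError("crossing distance needs at least 2 non-empty bins")

    if occupied[0].mean_r2 < r2_level:
        return CrossingResult(
            level=r2_level,
            distance_bp=occupied[0].midpoint_bp,
            status="below_from_start",
            bin_below=occupied[0],
        )
    for above, below in zip(occupied[:-1], occupied[1:]):
        if above.mean_r2 >= r2_level > below.mean_r2:
            x0, x1 = above.midpoint_bp, below.midpoint_bp
            y0, y1 = above.mean_r2, below.mean_r2
            dist = x0 + (y0 - r2_level) / (y0 - y1) * (x1 - x0)
            return CrossingResult(
                level=r2_level,
                distance_bp=float(dist),
                status="interpolated",
                bin_above=above,
                bin_below=below,
            )
    return CrossingResult(level=r2_level, distance_bp=None, status="not_reached")


def decay_summary_table(curves: DecayCurve | list[DecayCurve]) -> pd.DataFrame:
    """One row per bin (per grouping) with n, mean ± SD and prop >= threshold."""
    if isinstance(curves, DecayCurve):
        curves = [curves]
    return pd.concat([c.to_frame() for c in curves], ignore_index=True)
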