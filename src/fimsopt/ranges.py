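"""Scan-range determination for spectral-stitching flow-injection MS.

The central algorithm partitions an m/z interval [alpha, beta] into ``n``
contiguous quadrupole scan ranges holding equal numbers of reproducibly
detected features, so that dense spectral regions get narrow ranges (long
ion accumulation) and sparse regions get wide ones.  Given per-unit-bin
feature counts X_i and their cumulative sums C_i, the j-th interior
boundary is

    r_j = min{ i : C_i > j * C_beta / n },        1 <= j < n,

with r_0 = alpha and r_n = beta.  The strict inequality is kept verbatim,
including its asymmetric behaviour on ties; a balanced variant using >= is
available behind ``tie_rule="balanced"``.

Baselines provided for comparison: uniform-width ranges, a single range,
exhaustive narrow tiling, and equal-total-ion-count (TIC) ranges.  Since a
single injection accommodates at most eight scans per polarity,
:func:`plan_injections` chunks larger range sets into consecutive groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .features import FeatureCountHistogram

__all__ = [
    "ScanRangeSet",
    "optimize_equal_feature_ranges",
    "uniform_ranges",
    "single_range",
    "tiling_count",
    "tiling_ranges",
    "uniform_tic_ranges",
    "plan_injections",
    "MAX_SCANS_PER_INJECTION",
]

#: Scans per polarity that fit in one flow injection at the default flow
#: gradient; more would require a flow rate that degrades the TIC.
MAX_SCANS_PER_INJECTION = 8


@dataclass
class ScanRangeSet:
    """Ordered, contiguous, non-overlapping scan ranges covering [alpha, beta].

    ``boundaries`` holds r_0 < r_1 < ... < r_n; range j is
    [boundaries[j], boundaries[j+1]) with the final range closed at beta.
    ``counts``, when present, are the per-range feature (or TIC) totals.
    """

    boundaries: np.ndarray
    polarity: str = "negative"
    counts: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or len(b) < 2:
            raise ValueError("need at least two boundaries")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        self.boundaries = b
        if self.counts is not None:
            c = np.asarray(self.counts, dtype=float)
            if c.shape != (len(b) - 1,):
                raise ValueError("counts length must equal number of ranges")
            self.counts = c

    @property
    def n_ranges(self) -> int:
        return len(self.boundaries) - 1

    @property
    def alpha(self) -> float:
        return float(self.boundaries[0])

    @property
    def beta(self) -> float:
        return float(self.boundaries[-1])

    @property
    def ranges(self) -> List[Tuple[float, float]]:
        b = self.boundaries
        return [(float(b[i]), float(b[i + 1])) for i in range(self.n_ranges)]

    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def __iter__(self):
        return iter(self.ranges)

    def __len__(self) -> int:
        return self.n_ranges


class InfeasibleRangeCount(ValueError):
    """Requested more scan ranges than the histogram can support."""

    def __init__(self, requested: int, max_feasible: int):
        self.requested = requested
        self.max_feasible = max_feasible
        super().__init__(
            f"cannot split into {requested} ranges with strictly increasing "
            f"boundaries; maximum feasible is {max_feasible}"
        )


def _equal_cumulative_boundaries(
    hist: FeatureCountHistogram, n: int, tie_rule: str
) -> np.ndarray:
    c = hist.cumulative
    total = c[-1]
    grid = np.arange(hist.alpha, hist.beta + 1)
    bounds = [float(hist.alpha)]
    for j in range(1, n):
        target = j * total / n
        if tie_rule == "strict":
            hits = np.nonzero(c > target)[0]
        else:  # balanced
            hits = np.nonzero(c >= target)[0]
        if len(hits) == 0:
            return np.array([])  # signal infeasibility
        bounds.append(float(grid[hits[0]]))
    bounds.append(float(hist.beta))
    b = np.asarray(bounds)
    if not np.all(np.diff(b) > 0):
        return np.array([])
    return b


def _max_feasible_n(hist: FeatureCountHistogram, n: int, tie_rule: str) -> int:
    for m in range(min(n - 1, len(hist)), 0, -1):
        if len(_equal_cumulative_boundaries(hist, m, tie_rule)) > 0:
            return m
    return 0


def optimize_equal_feature_ranges(
    hist: FeatureCountHistogram,
    n: int,
    polarity: str = "negative",
    tie_rule: str = "strict",
) -> ScanRangeSet:
    """Partition [alpha, beta] into ``n`` ranges with equal feature counts.

    Boundaries lie on the integer m/z grid of the histogram.  With
    ``tie_rule="strict"`` the interior boundaries follow the formula
    ``r_j = min{i : C_i > j*C_beta/n}`` verbatim; ``"balanced"`` relaxes
    the inequality to >=, which rounds boundaries down on exact ties.

    Raises
    ------
    InfeasibleRangeCount
        When the requested ``n`` cannot produce strictly increasing
        boundaries (more ranges than occupied bins can support); the
        exception reports the maximum feasible ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if tie_rule not in ("strict", "balanced"):
        raise ValueError("tie_rule must be 'strict' or 'balanced'")
    if hist.total <= 0:
        raise ValueError("histogram holds no features")
    b = _equal_cumulative_boundaries(hist, n, tie_rule)
    if len(b) == 0:
        raise InfeasibleRangeCount(n, _max_feasible_n(hist, n, tie_rule))
    c = hist.cumulative
    idx = (b - hist.alpha).astype(int)
    counts = np.diff(c[idx])
    return ScanRangeSet(boundaries=b, polarity=polarity, counts=counts)


def uniform_ranges(
    alpha: float, beta: float, n: int, polarity: str = "negative"
) -> ScanRangeSet:
    """``n`` scan ranges of equal width (beta-alpha)/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if beta <= alpha:
        raise ValueError("beta must exceed alpha")
    return ScanRangeSet(boundaries=np.linspace(alpha, beta, n + 1), polarity=polarity)


def single_range(alpha: float, beta: float, polarity: str = "negative") -> ScanRangeSet:
    """The naive acquisition: one scan range spanning the whole interval."""
    return uniform_ranges(alpha, beta, 1, polarity)


def tiling_count(alpha: float, beta: float, width: float) -> int:
    """Number of consecutive fixed-width ranges needed to cover [alpha, beta]."""
    if width <= 0:
        raise ValueError("width must be positive")
    return math.ceil((beta - alpha) / width)


def tiling_ranges(
    alpha: float, beta: float, width: float, polarity: str = "negative"
) -> ScanRangeSet:
    """Exhaustive spectral-stitching tiling with fixed-width ranges.

    The final range is clipped at ``beta`` so the tiling covers exactly
    [alpha, beta]; e.g. 70-2500 at width 20 yields 122 ranges.
    """
    n = tiling_count(alpha, beta, width)
    b = alpha + width * np.arange(n + 1, dtype=float)
    b[-1] = beta
    return ScanRangeSet(boundaries=b, polarity=polarity)


def uniform_tic_ranges(
    tic_profile: FeatureCountHistogram,
    n: int,
    polarity: str = "negative",
    tie_rule: str = "strict",
) -> ScanRangeSet:
    """Ranges equalizing total ion count instead of feature count.

    Identical machinery to :func:`optimize_equal_feature_ranges` with the
    per-bin feature counts replaced by per-bin summed intensity.  Provided
    as a comparison method; equalizing TIC lets a few very intense ions
    dominate and yields fewer reproducible features.
    """
    return optimize_equal_feature_ranges(tic_profile, n, polarity, tie_rule)


def plan_injections(
    ranges: ScanRangeSet, max_per_injection: int = MAX_SCANS_PER_INJECTION
) -> List[List[int]]:
    """Split ranges into consecutive per-injection groups of <= 8 scans.

    Returns a list of injection groups, each a list of range indices in
    order; 122 ranges yield 16 injections (15 x 8 + 1 x 2).
    """
    if max_per_injection < 1:
        raise ValueError("max_per_injection must be >= 1")
    idx = list(range(ranges.n_ranges))
    return [idx[i: i + max_per_injection] for i in range(0, len(idx), max_per_injection)]
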