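"""Reproducible m/z feature detection from replicate flow injections.

Direct-infusion MS has no chromatographic dimension, so a "feature" is a
mass-to-charge value observed consistently across repeated injections of
the same sample.  Detection proceeds in two stages:

1. :func:`group_peaks` — centroid peaks from all injections (biological and
   blank) are grouped by m/z within a ppm tolerance.
2. :func:`apply_reproducibility_filter` — each group is kept as a
   reproducible feature only if it is (a) present in at least 90% of
   biological injections, (b) its median biological intensity exceeds
   1000 units, (c) its signal-to-noise ratio versus the blank injections
   exceeds 4, and (d) its relative standard deviation across biological
   injections is below 30%.

:func:`feature_distribution` bins the surviving features on the integer
m/z grid, producing the per-unit counts and cumulative counts consumed by
the scan-range optimizer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import ppm_diff

__all__ = [
    "FilterCriteria",
    "FeatureCountHistogram",
    "group_peaks",
    "apply_reproducibility_filter",
    "detect_features",
    "feature_distribution",
]

#: Columns a peak table must carry for feature detection.
REQUIRED_PEAK_COLUMNS = ("injection", "blank", "mz", "intensity")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds defining a reproducible m/z feature.

    Defaults: 5 ppm grouping tolerance, presence in >=90% of biological
    injections, median biological intensity > 1000, SNR (median biological
    intensity over maximal blank intensity) > 4, RSD < 30%.
    """

    tolerance_ppm: float = 5.0
    presence_fraction: float = 0.90
    min_median_intensity: float = 1000.0
    min_snr: float = 4.0
    max_rsd_pct: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.presence_fraction <= 1):
            raise ValueError("presence fraction must be in (0, 1]")
        for name in ("tolerance_ppm", "min_median_intensity", "min_snr", "max_rsd_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class FeatureCountHistogram:
    """Per-unit-m/z feature counts X_i with cumulative sums C_i over [alpha, beta].

    ``counts[k]`` is the number of features in ``[alpha+k, alpha+k+1)``;
    ``cumulative[k]`` is the number of features below ``alpha+k``, so
    ``cumulative[0] == 0`` and ``cumulative[-1] == counts.sum()``.
    ``counts`` may be float-valued (e.g. summed ion intensity per bin) —
    the scan-range machinery only needs monotone cumulative sums.
    """

    alpha: int
    beta: int
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.beta <= self.alpha:
            raise ValueError("beta must exceed alpha")
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.beta - self.alpha,):
            raise ValueError(
                f"expected {self.beta - self.alpha} bins, got {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("bin counts must be non-negative")
        self.counts = counts

    @property
    def cumulative(self) -> np.ndarray:
        c = np.empty(len(self.counts) + 1)
        c[0] = 0.0
        np.cumsum(self.counts, out=c[1:])
        return c

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


def group_peaks(peaks: pd.DataFrame, tolerance_ppm: float = 5.0) -> pd.DataFrame:
    """Group centroid peaks across injections by m/z proximity.

    Peaks are sorted by m/z and swept once: a peak opens a new group when
    it lies more than ``tolerance_ppm`` from the running median m/z of the
    current group.  This is deterministic and invariant to input row order.

    Returns a copy of ``peaks`` sorted by m/z with two added columns:
    ``group_id`` (0-based, ordered by reference m/z) and ``ref_mz`` (the
    median m/z of the group's members).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    missing = [c for c in ("mz", "intensity") if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table lacks columns {missing}")
    out = peaks.sort_values("mz", kind="mergesort").reset_index(drop=True)
    if len(out) == 0:
        out["group_id"] = pd.Series(dtype=int)
        out["ref_mz"] = pd.Series(dtype=float)
        return out

    mzs = out["mz"].to_numpy(dtype=float)
    group_ids = np.empty(len(mzs), dtype=int)
    current: List[float] = []
    gid = -1
    boundaries: List[int] = []
    for i, mz in enumerate(mzs):
        if current and ppm_diff(mz, median(current)) <= tolerance_ppm:
            current.append(mz)
        else:
            gid += 1
            current = [mz]
            boundaries.append(i)
        group_ids[i] = gid
    out["group_id"] = group_ids
    refs = np.empty(gid + 1)
    starts = boundaries + [len(mzs)]
    for g in range(gid + 1):
        refs[g] = median(mzs[starts[g]: starts[g + 1]])
    out["ref_mz"] = refs[group_ids]
    return out


def _rsd_pct(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    m = values.mean()
    if m == 0:
        return math.inf
    return float(values.std(ddof=1) / m * 100.0)


def apply_reproducibility_filter(
    grouped: pd.DataFrame,
    criteria: FilterCriteria,
    n_bio: int,
    n_blank: int,
) -> pd.DataFrame:
    """Reduce grouped peaks to the reproducible m/z features.

    ``grouped`` must carry ``group_id``/``ref_mz`` (from :func:`group_peaks`)
    plus ``injection`` and ``blank`` provenance columns.  When the same
    injection contributes several peaks to a group, the most intense one is
    used.  The RSD is computed over the biological injections in which the
    feature is present; absent injections affect the presence criterion
    only.  A group with no blank signal is assigned a blank level of 1
    intensity unit so the SNR criterion stays well defined.

    Returns one row per surviving feature with columns ``ref_mz``,
    ``median_intensity``, ``presence``, ``snr``, ``rsd_pct`` and
    ``max_blank`` (sorted by ``ref_mz``).
    """
    if n_bio <= 0:
        raise ValueError("n_bio must be >= 1")
    for col in ("group_id", "injection", "blank"):
        if col not in grouped.columns:
            raise ValueError(f"grouped peak table lacks column {col!r}")
    min_presence = math.ceil(criteria.presence_fraction * n_bio)

    records = []
    for (gid,), sub in grouped.groupby(["group_id"], sort=True):
        bio = sub[~sub["blank"].astype(bool)]
        blank = sub[sub["blank"].astype(bool)]
        # best (max) intensity per biological injection
        per_inj = bio.groupby("injection")["intensity"].max()
        presence = int(per_inj.size)
        if presence < min_presence:
            continue
        intensities = per_inj.to_numpy(dtype=float)
        med = float(np.median(intensities))
        if not med > criteria.min_median_intensity:
            continue
        max_blank = float(blank["intensity"].max()) if len(blank) else 0.0
        snr = med / max(max_blank, 1.0)
        if not snr > criteria.min_snr:
            continue
        rsd = _rsd_pct(intensities)
        if not rsd < criteria.max_rsd_pct:
            continue
        records.append(
            {
                "ref_mz": float(sub["ref_mz"].iloc[0]),
                "median_intensity": med,
                "presence": presence,
                "snr": snr,
                "rsd_pct": rsd,
                "max_blank": max_blank,
            }
        )
    out = pd.DataFrame.from_records(
        records,
        columns=["ref_mz", "median_intensity", "presence", "snr", "rsd_pct", "max_blank"],
    )
    return out.sort_values("ref_mz").reset_index(drop=True)


def detect_features(
    peaks: pd.DataFrame,
    criteria: Optional[FilterCriteria] = None,
    n_bio: Optional[int] = None,
    n_blank: Optional[int] = None,
) -> pd.DataFrame:
    """Convenience wrapper: group peaks then apply the reproducibility filter.

    ``n_bio``/``n_blank`` default to the number of distinct biological and
    blank injection ids present in the table.
    """
    criteria = criteria or FilterCriteria()
    blank_mask = peaks["blank"].astype(bool)
    if n_bio is None:
        n_bio = peaks.loc[~blank_mask, "injection"].nunique()
    if n_blank is None:
        n_blank = peaks.loc[blank_mask, "injection"].nunique()
    grouped = group_peaks(peaks, criteria.tolerance_ppm)
    return apply_reproducibility_filter(grouped, criteria, n_bio, n_blank)


def feature_distribution(
    feature_mzs: "Sequence[float] | pd.DataFrame",
    alpha: int,
    beta: int,
) -> FeatureCountHistogram:
    """Bin feature m/z values per unit m/z over the interval [alpha, beta).

    Accepts either a sequence of reference m/z values or a feature table
    with a ``ref_mz`` column.  Features outside the interval are counted
    nowhere; a warning reports how many were dropped.
    """
    if isinstance(feature_mzs, pd.DataFrame):
        mzs = feature_mzs["ref_mz"].to_numpy(dtype=float)
    else:
        mzs = np.asarray(list(feature_mzs), dtype=float)
    alpha, beta = int(alpha), int(beta)
    if beta <= alpha:
        raise ValueError("beta must exceed alpha")
    inside = (mzs >= alpha) & (mzs < beta)
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(
            f"{n_out} feature(s) outside [{alpha}, {beta}) excluded from histogram",
            stacklevel=2,
        )
    counts, _ = np.histogram(mzs[inside], bins=beta - alpha, range=(alpha, beta))
    return FeatureCountHistogram(alpha=alpha, beta=beta, counts=counts.astype(float))
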