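"""Greedy correlation clustering of m/z features into metabolite groups.

A reproducible m/z feature is not necessarily a distinct metabolite:
isotopologues, adducts and in-source fragments of one compound each
produce their own feature.  Without a chromatographic peak shape to
correlate, features are grouped by the correlation of their intensity
profiles across a series of distinct analyzed samples.

The clustering is greedy: features are visited in descending median
intensity (so monoisotopic ions tend to found clusters and their
satellites join them); a feature joins the first existing cluster — in
creation order — containing any member whose pairwise Pearson correlation
with it exceeds the threshold (default 0.95) over at least ``min_overlap``
co-detected samples, and otherwise founds a new cluster.

The within-cluster pairwise |delta m/z| histogram characterizes cluster
composition: with 13C isotopologues present its mode falls at 1.003 m/z,
while sodium adducts contribute ~21.98 and water losses 18.011.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "default_min_overlap",
    "greedy_correlation_clusters",
    "delta_mz_histogram",
    "modal_delta_mz",
]


def default_min_overlap(n_samples: int) -> int:
    """Minimum co-detected samples for a trustworthy correlation.

    max(10, half the samples): correlations over a handful of points are
    spuriously high far too often at a 0.95 threshold.
    """
    return max(10, math.ceil(0.5 * n_samples))


def _pairwise_pearson(x: np.ndarray, y: np.ndarray, min_overlap: int) -> float:
    """Pearson r over samples where both features are observed (else NaN)."""
    both = np.isfinite(x) & np.isfinite(y)
    if both.sum() < min_overlap:
        return np.nan
    xs, ys = x[both], y[both]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))


def greedy_correlation_clusters(
    intensity_matrix: pd.DataFrame,
    threshold: float = 0.95,
    min_overlap: Optional[int] = None,
) -> pd.Series:
    """Assign each feature (row) to a cluster by greedy single-link joining.

    Parameters
    ----------
    intensity_matrix
        Features x samples; NaN marks a feature not detected in a sample.
        The row index identifies features (reference m/z or feature id).
    threshold
        Minimal Pearson correlation for joining, strict (> threshold).
    min_overlap
        Minimum number of co-detected samples for a pair to be evaluated;
        defaults to :func:`default_min_overlap`.

    Returns
    -------
    Series
        Feature index -> integer cluster id (0-based, creation order).
        Deterministic: iteration order is descending median intensity with
        ties broken by row-index order.
    """
    if not (-1 < threshold < 1):
        raise ValueError("threshold must be in (-1, 1)")
    n_samples = intensity_matrix.shape[1]
    if min_overlap is None:
        min_overlap = default_min_overlap(n_samples)
    if n_samples < min_overlap:
        raise ValueError(
            f"matrix has {n_samples} samples but min_overlap={min_overlap}"
        )

    values = intensity_matrix.to_numpy(dtype=float)
    medians = np.nanmedian(values, axis=1)
    order = np.argsort(-medians, kind="mergesort")  # stable: ties keep row order

    clusters: list[list[int]] = []
    assignment = np.full(len(values), -1, dtype=int)
    for row in order:
        joined = False
        for cid, members in enumerate(clusters):
            for member in members:
                r = _pairwise_pearson(values[row], values[member], min_overlap)
                if np.isfinite(r) and r > threshold:
                    members.append(row)
                    assignment[row] = cid
                    joined = True
                    break
            if joined:
                break
        if not joined:
            assignment[row] = len(clusters)
            clusters.append([row])
    return pd.Series(assignment, index=intensity_matrix.index, name="cluster")


def delta_mz_histogram(
    clusters: pd.Series,
    mz_values: Optional[pd.Series] = None,
    precision: int = 3,
) -> pd.Series:
    """Frequency table of within-cluster pairwise |delta m/z|.

    ``mz_values`` maps feature -> m/z; when omitted the cluster index
    itself is taken as the m/z (the natural case when the intensity
    matrix is indexed by reference m/z).  Differences are rounded to
    ``precision`` decimals.  Singleton clusters contribute nothing.

    Returns a Series of counts indexed by rounded |delta m/z|, sorted by
    descending count then ascending delta.
    """
    if len(clusters) == 0:
        raise ValueError("no clusters given")
    mzs = mz_values if mz_values is not None else pd.Series(
        clusters.index.to_numpy(dtype=float), index=clusters.index
    )
    counter: Counter = Counter()
    for _, idx in clusters.groupby(clusters).groups.items():
        vals = np.sort(mzs.loc[idx].to_numpy(dtype=float))
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                counter[round(abs(vals[j] - vals[i]), precision)] += 1
    if not counter:
        return pd.Series(dtype=int, name="count")
    table = pd.Series(counter, name="count")
    return table.iloc[np.lexsort((table.index, -table.values))]


def modal_delta_mz(delta_table: pd.Series) -> float:
    """The most frequent within-cluster |delta m/z| (smallest on ties)."""
    if len(delta_table) == 0:
        raise ValueError("empty delta m/z table")
    return float(delta_table.index[0])
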