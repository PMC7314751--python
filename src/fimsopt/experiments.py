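"""End-to-end in-silico experiment pipelines on simulator output.

Three scripted experiments reproduce the phenomenology that motivates
scan-range optimization:

* :func:`competition_assay` — spike an increasingly abundant ion and
  compare feature retention between a scan range that *includes* the
  spike (ion competition + ESI suppression) and a nested narrower range
  that *excludes* it (ESI suppression only).
* :func:`width_sweep` — feature retention as a function of scan-range
  width around a dense versus a sparse spectral region.
* :func:`method_comparison` — reproducible-feature yield of optimized
  equal-feature ranges versus uniform ranges, a single range, and
  exhaustive narrow-tile spectral stitching.

Each pipeline is seed-deterministic given its acquisition config.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import FilterCriteria, detect_features, feature_distribution
from .ranges import (
    ScanRangeSet,
    optimize_equal_feature_ranges,
    single_range,
    tiling_ranges,
    uniform_ranges,
)
from .simulate import (
    AcquisitionConfig,
    IonSpecies,
    SyntheticMetabolome,
    simulate_injection_series,
)
from .msio import peak_table_from_events

__all__ = [
    "acquire_features",
    "competition_assay",
    "width_sweep",
    "method_comparison",
]


def acquire_features(
    metabolome: SyntheticMetabolome,
    ranges: "ScanRangeSet | Sequence[Tuple[float, float]]",
    config: AcquisitionConfig,
    criteria: Optional[FilterCriteria] = None,
    n_bio: int = 6,
    n_blank: int = 6,
    spike: Optional[Sequence[IonSpecies]] = None,
) -> pd.DataFrame:
    """Simulate an injection series and return its reproducible features."""
    events = simulate_injection_series(
        metabolome, ranges, config, n_bio=n_bio, n_blank=n_blank, spike=spike
    )
    peaks = peak_table_from_events(events)
    return detect_features(peaks, criteria or FilterCriteria(), n_bio, n_blank)


def _count_within(features: pd.DataFrame, low: float, high: float) -> int:
    mz = features["ref_mz"]
    return int(((mz >= low) & (mz < high)).sum())


def competition_assay(
    metabolome: SyntheticMetabolome,
    spike_mz: float,
    spike_fluxes: Sequence[float],
    include_range: Tuple[float, float],
    exclude_range: Tuple[float, float],
    config: AcquisitionConfig,
    criteria: Optional[FilterCriteria] = None,
    n_bio: int = 6,
    n_blank: int = 6,
) -> pd.DataFrame:
    """Dissect ion competition from ESI suppression with nested scan ranges.

    For each spike flux, the sample is acquired twice: once scanning only
    ``exclude_range`` (the spike never reaches the trap, so any feature
    loss is source suppression) and once scanning ``include_range`` (the
    spike consumes trap capacity as well).  Features are always counted
    inside ``exclude_range``; retention is relative to each
    configuration's own zero-spike count.

    Returns rows (spike_flux, configuration, n_features, retention_pct,
    mean_injection_time_ms).
    """
    ilo, ihi = include_range
    elo, ehi = exclude_range
    if not (ilo <= elo and ehi <= ihi and (elo, ehi) != (ilo, ihi)):
        raise ValueError("exclude_range must be strictly nested in include_range")
    if elo <= spike_mz < ehi:
        raise ValueError("spike m/z must lie outside the exclude range")
    if not (ilo <= spike_mz < ihi):
        raise ValueError("spike m/z must lie inside the include range")

    rows = []
    for configuration, scan_rg in (("exclude", exclude_range), ("include", include_range)):
        for flux in spike_fluxes:
            spike = (
                [IonSpecies(spike_mz, float(flux), metabolome.polarity, None, "spike")]
                if flux > 0
                else None
            )
            events = simulate_injection_series(
                metabolome, [scan_rg], config, n_bio=n_bio, n_blank=n_blank, spike=spike
            )
            feats = detect_features(
                peak_table_from_events(events),
                criteria or FilterCriteria(),
                n_bio,
                n_blank,
            )
            t_bio = float(
                np.mean([e.injection_time_ms for e in events if not e.blank])
            )
            rows.append((float(flux), configuration, _count_within(feats, elo, ehi), t_bio))
    out = pd.DataFrame(
        rows, columns=["spike_flux", "configuration", "n_features", "mean_injection_time_ms"]
    )
    base = out[out["spike_flux"] == 0].set_index("configuration")["n_features"]
    out["retention_pct"] = [
        100.0 * n / base[cfg] if base[cfg] else np.nan
        for cfg, n in zip(out["configuration"], out["n_features"])
    ]
    return out


def width_sweep(
    metabolome: SyntheticMetabolome,
    center: float,
    widths: Sequence[float],
    config: AcquisitionConfig,
    criteria: Optional[FilterCriteria] = None,
    n_bio: int = 6,
    n_blank: int = 6,
) -> pd.DataFrame:
    """Feature retention versus scan-range width around a center m/z.

    The narrowest width defines 100%; features are always counted within
    the narrowest window so widths are compared on common ground.
    """
    widths = sorted(float(w) for w in widths)
    if not widths or widths[0] <= 0:
        raise ValueError("widths must be positive")
    w0 = widths[0]
    count_lo, count_hi = center - w0 / 2, center + w0 / 2
    rows = []
    for w in widths:
        rg = (center - w / 2, center + w / 2)
        feats = acquire_features(
            metabolome, [rg], config, criteria, n_bio=n_bio, n_blank=n_blank
        )
        rows.append((w, _count_within(feats, count_lo, count_hi)))
    out = pd.DataFrame(rows, columns=["width", "n_features"])
    base = out["n_features"].iloc[0]
    out["pct_of_narrowest"] = 100.0 * out["n_features"] / base if base else np.nan
    return out


def method_comparison(
    metabolome: SyntheticMetabolome,
    n_values: Sequence[int],
    config: AcquisitionConfig,
    criteria: Optional[FilterCriteria] = None,
    alpha: int = 70,
    beta: int = 2500,
    tile_width: float = 20.0,
    n_bio: int = 6,
    n_blank: int = 6,
) -> pd.DataFrame:
    """Compare feature yields: optimized vs uniform vs single vs exhaustive.

    The exhaustive spectral-stitching acquisition (consecutive
    ``tile_width`` ranges over [alpha, beta]) defines both the feature-
    density histogram handed to the optimizer and the reference feature
    count.  For each requested number of ranges n, optimized and uniform
    acquisitions are simulated and their yields expressed as a fraction
    of the exhaustive count; the single-range baseline is reported as
    n = 1.

    Returns rows (method, n_ranges, n_features, fraction_of_exhaustive).
    """
    criteria = criteria or FilterCriteria()
    exhaustive = tiling_ranges(alpha, beta, tile_width, metabolome.polarity)
    feats_ex = acquire_features(
        metabolome, exhaustive, config, criteria, n_bio=n_bio, n_blank=n_blank
    )
    hist = feature_distribution(feats_ex, alpha, beta)
    n_ex = len(feats_ex)

    rows = [("exhaustive", exhaustive.n_ranges, n_ex)]
    feats_single = acquire_features(
        metabolome, single_range(alpha, beta, metabolome.polarity), config, criteria,
        n_bio=n_bio, n_blank=n_blank,
    )
    rows.append(("single", 1, len(feats_single)))
    for n in n_values:
        opt = optimize_equal_feature_ranges(hist, n, metabolome.polarity)
        uni = uniform_ranges(alpha, beta, n, metabolome.polarity)
        for method, rset in (("optimized", opt), ("uniform", uni)):
            feats = acquire_features(
                metabolome, rset, config, criteria, n_bio=n_bio, n_blank=n_blank
            )
            rows.append((method, n, len(feats)))
    out = pd.DataFrame(rows, columns=["method", "n_ranges", "n_features"])
    out["fraction_of_exhaustive"] = (
        out["n_features"] / n_ex if n_ex else np.nan
    )
    return out
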