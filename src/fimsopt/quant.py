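"""Quantification and analytical-performance statistics.

Standard addition with x-intercept extrapolation and confidence interval,
internal (stable-isotope) calibration, response linearity, matrix-effect
RSD across samples, and the inter-subject variability rule comparing
biological to QC (pooled-sample) technical variation.

Standard addition: known increments c_i of the analyte are spiked into
the sample and intensities fit by OLS, I = a + b c.  The endogenous
concentration is the magnitude of the negative x-intercept, c_hat = a/b.
Its confidence interval uses the classical analytical-chemistry
propagation

    s_x0 = (s / b) * sqrt(1/n + Ibar^2 / (b^2 * Sxx)),

with s the residual standard deviation and Sxx the centered sum of
squares of the added concentrations, giving c_hat +/- t_{n-2} * s_x0.
A Fieller-interval alternative is available via ``method="fieller"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardAdditionResult",
    "standard_addition_concentration",
    "internal_calibration",
    "linearity",
    "matrix_effect_rsd",
    "inter_subject_variable_features",
]


@dataclass(frozen=True)
class StandardAdditionResult:
    """Endogenous concentration estimate with its confidence interval."""

    concentration: float
    ci_low: float
    ci_high: float
    slope: float
    intercept: float
    r_squared: float
    confidence: float


def _ols(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    return res


def standard_addition_concentration(
    added: Sequence[float],
    intensity: Sequence[float],
    confidence: float = 0.95,
    method: str = "t",
) -> StandardAdditionResult:
    """Estimate an endogenous concentration by the standard-addition method.

    Parameters
    ----------
    added
        Spiked concentrations; must include 0 (the unspiked sample) and at
        least 3 points in total.
    intensity
        Measured intensities at each spike level (raw, untransformed).
    confidence
        Confidence level of the x-intercept interval (default 0.95).
    method
        ``"t"`` — t-quantile propagation of the x-intercept standard
        error (default); ``"fieller"`` — Fieller's exact ratio interval.

    Raises
    ------
    ValueError
        On fewer than 3 points, a missing zero-addition point, or a
        non-positive fitted slope (extrapolation undefined).
    """
    x = np.asarray(list(added), dtype=float)
    y = np.asarray(list(intensity), dtype=float)
    if len(x) != len(y):
        raise ValueError("added and intensity lengths differ")
    if len(x) < 3:
        raise ValueError("standard addition needs at least 3 points")
    if not np.any(x == 0):
        raise ValueError("added concentrations must include 0")
    fit = _ols(x, y)
    if fit.slope <= 0:
        raise ValueError("non-positive regression slope; extrapolation undefined")

    n = len(x)
    dof = n - 2
    c_hat = fit.intercept / fit.slope
    resid = y - (fit.intercept + fit.slope * x)
    s = math.sqrt(float(resid @ resid) / dof) if dof > 0 else 0.0
    sxx = float(((x - x.mean()) ** 2).sum())
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof)

    if method == "t":
        s_x0 = (s / fit.slope) * math.sqrt(
            1.0 / n + y.mean() ** 2 / (fit.slope**2 * sxx)
        )
        lo, hi = c_hat - tq * s_x0, c_hat + tq * s_x0
    elif method == "fieller":
        # interval for the ratio a/b of two correlated normal estimates
        va = s**2 * (1.0 / n + x.mean() ** 2 / sxx)
        vb = s**2 / sxx
        cab = -(s**2) * x.mean() / sxx
        a, b = fit.intercept, fit.slope
        g = tq**2 * vb / b**2
        if g >= 1:
            raise ValueError("slope too imprecise for a finite Fieller interval")
        center = (c_hat - g * cab / vb) / (1 - g)
        half = (
            tq
            / (abs(b) * (1 - g))
            * math.sqrt(va - 2 * c_hat * cab + c_hat**2 * vb - g * (va - cab**2 / vb))
        )
        lo, hi = center - half, center + half
    else:
        raise ValueError("method must be 't' or 'fieller'")

    return StandardAdditionResult(
        concentration=float(c_hat),
        ci_low=float(lo),
        ci_high=float(hi),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        confidence=confidence,
    )


def internal_calibration(
    analyte_intensity: float,
    standard_intensities: Sequence[float],
    standard_concentrations: Sequence[float],
) -> float:
    """Concentration of an analyte from an internal-standard calibration line.

    Fits intensity = a + b*concentration over the standard points by OLS
    and inverts it at the analyte's intensity.
    """
    y = np.asarray(list(standard_intensities), dtype=float)
    x = np.asarray(list(standard_concentrations), dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need at least two calibration points")
    if len(x) == 2:
        b = (y[1] - y[0]) / (x[1] - x[0])
        a = y[0] - b * x[0]
    else:
        fit = _ols(x, y)
        a, b = fit.intercept, fit.slope
    if b == 0:
        raise ValueError("flat calibration line")
    return float((analyte_intensity - a) / b)


def linearity(
    concentrations: Sequence[float], intensities: Sequence[float]
) -> Tuple[float, float]:
    """Response linearity: (R^2, two-sided slope p-value) from OLS."""
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(intensities), dtype=float)
    fit = _ols(x, y)
    return float(fit.rvalue**2), float(fit.pvalue)


def matrix_effect_rsd(intensities: Sequence[float]) -> float:
    """Relative standard deviation (%) of one compound across samples.

    Sample standard deviation (ddof=1) over the mean, times 100.
    """
    v = np.asarray(list(intensities), dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two measurements")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean intensity")
    return float(v.std(ddof=1) / mean * 100.0)


def _rowwise_rsd(matrix: pd.DataFrame) -> pd.Series:
    values = matrix.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1)
    sd = np.nanstd(values, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, sd / mean * 100.0, np.inf)
    return pd.Series(rsd, index=matrix.index, name="rsd_pct")


def inter_subject_variable_features(
    subject_matrix: pd.DataFrame,
    qc_matrix: pd.DataFrame,
    factor: float = 1.5,
) -> pd.Series:
    """Flag features whose biological variability exceeds technical noise.

    A feature is biologically variable when its RSD across subjects is
    more than ``factor`` times its RSD across repeated QC (pooled sample)
    injections — with the default 1.5, i.e. 50% higher.  The matrices are
    features x samples and features x QC injections, aligned on the
    feature index (only shared features are evaluated).

    Returns a boolean Series over the shared features.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    shared = subject_matrix.index.intersection(qc_matrix.index)
    rsd_subject = _rowwise_rsd(subject_matrix.loc[shared])
    rsd_qc = _rowwise_rsd(qc_matrix.loc[shared])
    return (rsd_subject > factor * rsd_qc).rename("variable")
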