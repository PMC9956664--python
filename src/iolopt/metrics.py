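"""Prediction-error summaries, trend regression and figure-ready data.

Quantiles use the Hazen plotting-position rule, (k − 0.5)/n with linear
interpolation (``numpy`` method ``"hazen"``), so snapshot values are
stable across environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_QUANTILE_METHOD = "hazen"


@dataclass(frozen=True)
class PEStats:
    """Summary of a prediction-error sample, all in dpt."""

    mean: float
    sd: float
    median: float
    q025: float
    q975: float
    iqr: float
    n: int


@dataclass(frozen=True)
class TrendFit:
    """OLS regression of PE on a corneal-radius covariate."""

    intercept: float  # dpt
    slope: float  # dpt/mm
    covariate: str  # "Rpow" or "Rmean"
    n: int


@dataclass(frozen=True)
class BoxStats:
    """Boxplot geometry for |PE|: quartiles, median and 95% whiskers."""

    q25: float
    median: float
    q75: float
    whisker_low: float
    whisker_high: float
    n: int


def _clean(pe) -> np.ndarray:
    arr = np.asarray(pe, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("PE vector contains non-finite values")
    return arr


def pe_stats(pe) -> PEStats:
    """Mean, SD (n−1), median, 2.5%/97.5% quantiles and IQR of PE."""
    arr = _clean(pe)
    if arr.size < 2:
        raise ValueError("need at least 2 observations")
    q025, q25, med, q75, q975 = np.quantile(
        arr, [0.025, 0.25, 0.5, 0.75, 0.975], method=_QUANTILE_METHOD
    )
    return PEStats(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        median=float(med),
        q025=float(q025),
        q975=float(q975),
        iqr=float(q75 - q25),
        n=arr.size,
    )


def trend_regression(pe, radius, covariate: str = "Rmean") -> TrendFit:
    """Least-squares line PE = intercept + slope·radius.

    The slope (dpt/mm) is the trend error: a systematic dependence of
    the refractive prediction error on corneal radius.
    """
    y = _clean(pe)
    x = np.asarray(radius, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("PE and radius vectors must have equal length")
    if x.size < 2 or np.ptp(x) == 0 or np.var(x) < 1e-300:
        raise ValueError("radius has zero variance; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return TrendFit(
        intercept=float(intercept), slope=float(slope),
        covariate=covariate, n=x.size,
    )


def cdf_curve(pe) -> pd.DataFrame:
    """Empirical CDF of PE: sorted values with fractions i/n.

    Right-continuous convention: the fraction at a value x is the share
    of observations ≤ x.  The share of eyes within ±0.5 dpt is the
    difference of the curve read at +0.5 and −0.5 dpt.
    """
    arr = np.sort(_clean(pe))
    frac = np.arange(1, arr.size + 1, dtype=float) / arr.size
    return pd.DataFrame({"PE": arr, "cum_fraction": frac})


def share_within(pe, limit: float = 0.5) -> float:
    """Fraction of eyes with |PE| ≤ limit (CDF at +limit minus at −limit⁻)."""
    arr = _clean(pe)
    return float(np.mean(np.abs(arr) <= limit))


def abs_pe_box(pe) -> BoxStats:
    """Boxplot data of the absolute prediction error |PE|.

    Box at the quartiles with the median line; whiskers at the 2.5% and
    97.5% quantiles of |PE| (the 95% interval, i.e. the outlier
    thresholds).
    """
    arr = np.abs(_clean(pe))
    if arr.size < 2:
        raise ValueError("need at least 2 observations")
    q025, q25, med, q75, q975 = np.quantile(
        arr, [0.025, 0.25, 0.5, 0.75, 0.975], method=_QUANTILE_METHOD
    )
    return BoxStats(
        q25=float(q25), median=float(med), q75=float(q75),
        whisker_low=float(q025), whisker_high=float(q975), n=arr.size,
    )
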