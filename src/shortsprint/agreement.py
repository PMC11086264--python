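"""Criterion-vs-practical agreement and sensitivity statistics.

Validity of a field instrument (timing gates) against a criterion
instrument (laser gun) is summarised per parameter and model by:

- %Diff   per observation: 100 * (practical - criterion) / criterion
- %Bias   mean of %Diff
- %MAD    mean absolute deviation of %Diff around its mean (a plain
          mean |%Diff| variant is exposed via ``mode="absolute_diff"``
          because the estimator's usual name suggests it)
- %RSE    percent residual standard error of the OLS regression of
          practical (outcome) on criterion (predictor):
          sqrt( sum_i (100 * (y_i - yhat_i) / yhat_i)^2 / (N - 2) ).
          Assuming an error-free criterion, this is the percent standard
          error of measurement (%SEM) of the practical instrument.
- %MDC95  minimum detectable change at 95% confidence:
          %RSE * sqrt(2) * 1.96 — the smallest observed change that can
          be read as a true change.

Interval estimates use the bias-corrected and accelerated (BCa)
nonparametric bootstrap, resampling athlete-trial rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedEstimates",
    "AgreementReport",
    "percent_diff",
    "percent_bias",
    "percent_mad",
    "percent_rse",
    "mdc95",
    "bca_bootstrap",
    "agreement_report",
]

MDC_FACTOR = np.sqrt(2.0) * 1.96


@dataclass(frozen=True)
class PairedEstimates:
    """Per athlete-trial criterion and practical values of one parameter."""

    criterion: np.ndarray
    practical: np.ndarray
    parameter: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.criterion, dtype=float)
        p = np.asarray(self.practical, dtype=float)
        object.__setattr__(self, "criterion", c)
        object.__setattr__(self, "practical", p)
        if c.shape != p.shape or c.ndim != 1:
            raise ValueError("criterion and practical must be 1-D, equal length")
        if len(c) < 3:
            raise ValueError("need at least 3 paired observations")
        if np.any(c == 0):
            raise ValueError("criterion values must be nonzero")

    def __len__(self) -> int:
        return len(self.criterion)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement and sensitivity summary for one model x parameter cell."""

    model: str
    parameter: str
    n: int
    pct_bias: float
    pct_bias_ci: tuple[float, float] | None
    pct_mad: float
    pct_mad_ci: tuple[float, float] | None
    pct_rse: float
    pct_mdc95: float
    pct_mdc95_ci: tuple[float, float] | None
    n_resamples: int | None = None
    conf: float | None = None
    seed: int | None = None

    def as_dict(self) -> dict:
        def lo(ci):
            return ci[0] if ci is not None else None

        def hi(ci):
            return ci[1] if ci is not None else None

        return {
            "model": self.model,
            "parameter": self.parameter,
            "n": self.n,
            "pct_bias": self.pct_bias,
            "pct_bias_lo": lo(self.pct_bias_ci),
            "pct_bias_hi": hi(self.pct_bias_ci),
            "pct_mad": self.pct_mad,
            "pct_mad_lo": lo(self.pct_mad_ci),
            "pct_mad_hi": hi(self.pct_mad_ci),
            "pct_rse": self.pct_rse,
            "pct_mdc95": self.pct_mdc95,
            "pct_mdc95_lo": lo(self.pct_mdc95_ci),
            "pct_mdc95_hi": hi(self.pct_mdc95_ci),
        }


def percent_diff(practical, criterion):
    """Elementwise 100 * (practical - criterion) / criterion."""
    p = np.asarray(practical, dtype=float)
    c = np.asarray(criterion, dtype=float)
    if np.any(c == 0):
        raise ValueError("criterion values must be nonzero")
    return 100.0 * (p - c) / c


def percent_bias(diffs) -> float:
    """Mean percent difference."""
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty input")
    return float(np.mean(d))


def percent_mad(diffs, mode: str = "deviation") -> float:
    """Mean absolute deviation of the percent differences.

    mode="deviation": (1/N) sum |%Diff_i - mean(%Diff)| — mean absolute
    deviation around the mean difference (the default).
    mode="absolute_diff": (1/N) sum |%Diff_i| — the reading the name
    "mean absolute difference" suggests.  The two coincide only when the
    mean difference is zero.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("empty input")
    if mode == "deviation":
        return float(np.mean(np.abs(d - np.mean(d))))
    if mode == "absolute_diff":
        return float(np.mean(np.abs(d)))
    raise ValueError(f"unknown mode {mode!r}")


def _pct_rse_from_fitted(y: np.ndarray, yhat: np.ndarray) -> float:
    resid_pct = 100.0 * (y - yhat) / yhat
    return float(np.sqrt(np.sum(resid_pct**2) / (len(y) - 2)))


def percent_rse(criterion, practical) -> float:
    """Percent residual standard error of practical ~ criterion OLS."""
    c = np.asarray(criterion, dtype=float)
    y = np.asarray(practical, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(c) == 0:
        raise ValueError("criterion has zero variance; regression degenerate")
    fit = stats.linregress(c, y)
    yhat = fit.intercept + fit.slope * c
    return _pct_rse_from_fitted(y, yhat)


def mdc95(pct_rse: float) -> float:
    """Minimum detectable change at 95% confidence: %RSE * sqrt(2) * 1.96."""
    if pct_rse < 0:
        raise ValueError("pct_rse must be >= 0")
    return pct_rse * MDC_FACTOR


def bca_bootstrap(
    data,
    statistic,
    n_resamples: int = 5000,
    conf: float = 0.95,
    seed: int | np.random.Generator | None = None,
    paired: bool = False,
    vectorized: bool = False,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for ``statistic(data)``.

    ``data`` is one sample (1-D) or, with ``paired=True``, a tuple of
    equal-length samples resampled jointly.  With ``vectorized`` the
    statistic must accept an ``axis`` keyword.  Deterministic under
    seed.  A degenerate resample distribution (all values equal)
    collapses to a point interval with a warning.
    """
    samples = tuple(np.asarray(s, dtype=float) for s in data) if paired else (
        np.asarray(data, dtype=float),
    )
    n = len(samples[0])
    if n < 3:
        raise ValueError("need at least 3 observations to bootstrap")
    point = statistic(*samples, axis=-1) if vectorized else statistic(*samples)
    if all(np.ptp(s) == 0 for s in samples):
        warnings.warn("degenerate (constant) data; returning point interval")
        return float(point), float(point)
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.bootstrap(
            samples,
            statistic,
            n_resamples=n_resamples,
            confidence_level=conf,
            method="BCa",
            paired=paired,
            vectorized=vectorized,
            rng=rng,
        )
    lo, hi = res.confidence_interval.low, res.confidence_interval.high
    if not (np.isfinite(lo) and np.isfinite(hi)):
        warnings.warn("degenerate resample distribution; returning point interval")
        return float(point), float(point)
    return float(lo), float(hi)


def _mean_axis(d, axis=-1):
    return np.mean(d, axis=axis)


def _mad_axis(d, axis=-1, mode="deviation"):
    d = np.asarray(d, dtype=float)
    if mode == "deviation":
        return np.mean(np.abs(d - np.mean(d, axis=axis, keepdims=True)), axis=axis)
    return np.mean(np.abs(d), axis=axis)


def _mdc_axis(c, y, axis=-1):
    """Axis-aware %MDC95 of the y ~ c OLS, for vectorized resampling."""
    c = np.asarray(c, dtype=float)
    y = np.asarray(y, dtype=float)
    n = c.shape[axis]
    cm = np.mean(c, axis=axis, keepdims=True)
    ym = np.mean(y, axis=axis, keepdims=True)
    var = np.sum((c - cm) ** 2, axis=axis, keepdims=True)
    var = np.where(var == 0, np.nan, var)
    slope = np.sum((c - cm) * (y - ym), axis=axis, keepdims=True) / var
    yhat = ym + slope * (c - cm)
    resid_pct = 100.0 * (y - yhat) / yhat
    rse = np.sqrt(np.sum(resid_pct**2, axis=axis) / (n - 2))
    return rse * MDC_FACTOR


def agreement_report(
    pairs: PairedEstimates,
    mad_mode: str = "deviation",
    ci: bool = True,
    n_resamples: int = 5000,
    conf: float = 0.95,
    seed: int | None = None,
) -> AgreementReport:
    """All agreement/sensitivity estimators for one model x parameter.

    CIs (when ``ci``) are BCa bootstrap over athlete-trial rows: %Bias
    and %MAD resample the %Diff values; %MDC95 resamples the
    (criterion, practical) pairs jointly and refits the regression.
    """
    diffs = percent_diff(pairs.practical, pairs.criterion)
    bias = percent_bias(diffs)
    mad = percent_mad(diffs, mode=mad_mode)
    rse = percent_rse(pairs.criterion, pairs.practical)
    mdc = mdc95(rse)
    bias_ci = mad_ci = mdc_ci = None
    if ci:
        ss = np.random.SeedSequence(seed).spawn(3)
        bias_ci = bca_bootstrap(
            diffs, _mean_axis, n_resamples, conf,
            np.random.default_rng(ss[0]), vectorized=True,
        )
        mad_ci = bca_bootstrap(
            diffs,
            lambda d, axis=-1: _mad_axis(d, axis=axis, mode=mad_mode),
            n_resamples,
            conf,
            np.random.default_rng(ss[1]),
            vectorized=True,
        )
        mdc_ci = bca_bootstrap(
            (pairs.criterion, pairs.practical),
            _mdc_axis,
            n_resamples,
            conf,
            np.random.default_rng(ss[2]),
            paired=True,
            vectorized=True,
        )
    return AgreementReport(
        model=pairs.model,
        parameter=pairs.parameter,
        n=len(pairs),
        pct_bias=bias,
        pct_bias_ci=bias_ci,
        pct_mad=mad,
        pct_mad_ci=mad_ci,
        pct_rse=rse,
        pct_mdc95=mdc,
        pct_mdc95_ci=mdc_ci,
        n_resamples=n_resamples if ci else None,
        conf=conf if ci else None,
        seed=seed,
    )
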