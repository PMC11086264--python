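"""Nonlinear least-squares estimation of sprint profiles.

Five timing-gate model variants share one estimation strategy: time is
the outcome and distance the predictor (reversing the axes biases the
estimates), and the residual sum of squares is minimised with a
trust-region-reflective damped least-squares solver under broad bounds.

    no_correction   t ~ t(d; MSS, TAU)
    fixed_tc        t + TC0 ~ t(d; MSS, TAU)           TC0 known
    estimated_tc    t ~ t(d; MSS, TAU) + TC            TC free, any sign
    fixed_fd        t ~ t(d+FD0) - t(FD0); MSS, TAU    FD0 known
    estimated_fd    t ~ t(d+FD) - t(FD); MSS, TAU, FD  FD free, >= 0

A sixth variant fits the time-shifted velocity model directly to a
laser-gun velocity-time trace (``laser_tc``), after discarding samples
before the smoothed velocity first crosses a threshold (default
0.5 m/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinematics import (
    CorrectionParams,
    SprintProfile,
    time_at_distance,
    time_at_distance_fd,
    time_at_distance_tc,
    velocity_at_time,
)

__all__ = [
    "SplitTimes",
    "VelocityTrace",
    "FitResult",
    "fit_no_correction",
    "fit_fixed_tc",
    "fit_estimated_tc",
    "fit_fixed_fd",
    "fit_estimated_fd",
    "fit_laser_trace",
    "predict_times",
    "predict_velocity",
    "MODEL_NAMES",
]

MODEL_NAMES = (
    "no_correction",
    "fixed_tc",
    "estimated_tc",
    "fixed_fd",
    "estimated_fd",
    "laser_tc",
)

# numerical safety rails; human short-sprint profiles sit well inside
_MSS_BOUNDS = (1e-6, 20.0)
_TAU_BOUNDS = (1e-6, 10.0)
_TC_BOUNDS = (-5.0, 5.0)
_FD_BOUNDS = (0.0, 10.0)
_FTOL = 1e-12
_MAX_NFEV = 1000


@dataclass(frozen=True)
class SplitTimes:
    """Cumulative timing-gate split times of one sprint trial.

    distances : gate positions, m, strictly increasing and > 0.
    times     : cumulative times at each gate, s, strictly increasing.
    provenance: "observed" or "simulated".
    rounding  : clock precision the times were rounded to, s, or None.
    """

    distances: np.ndarray
    times: np.ndarray
    provenance: str = "observed"
    rounding: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "times", t)
        if d.shape != t.shape or d.ndim != 1:
            raise ValueError("distances and times must be 1-D of equal length")
        if len(d) < 2:
            raise ValueError("need at least two gates")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("distances must be positive and strictly increasing")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if self.provenance not in ("observed", "simulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class VelocityTrace:
    """Sampled velocity-time series from a laser device.

    t        : sample times, s, strictly increasing.
    v_raw    : raw velocity channel, m/s.
    v_smooth : smoothed velocity channel, m/s (optional).
    """

    t: np.ndarray
    v_raw: np.ndarray
    v_smooth: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v_raw, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v_raw", v)
        if self.v_smooth is not None:
            object.__setattr__(
                self, "v_smooth", np.asarray(self.v_smooth, dtype=float)
            )
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t and v_raw must be 1-D of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("v_raw must be finite")
        if self.v_smooth is not None and self.v_smooth.shape != t.shape:
            raise ValueError("v_smooth must match t in length")

    @property
    def sample_rate(self) -> float:
        """Mean sampling rate, Hz."""
        return (len(self.t) - 1) / (self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class FitResult:
    """Estimated profile plus correction parameter and diagnostics."""

    model: str
    profile: SprintProfile
    correction: CorrectionParams
    residuals: np.ndarray = field(repr=False)
    rss: float
    converged: bool
    n_obs: int

    def as_dict(self) -> dict:
        """Flat row for serialisation (CSV/JSON)."""
        return {
            "model": self.model,
            "MSS": self.profile.mss,
            "TAU": self.profile.tau,
            "MAC": self.profile.mac,
            "PMAX": self.profile.pmax,
            "TC": self.correction.tc,
            "FD": self.correction.fd,
            "rss": self.rss,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def _initial_mss_tau(d: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    # 1.5x the mean velocity to the last gate is safely above MSS's
    # lower admissible value for a mono-exponential profile
    mss0 = min(d[-1] / t[-1] * 1.5, _MSS_BOUNDS[1] * 0.99)
    return mss0, 1.0


def _solve(residual_fn, x0, lower, upper) -> tuple[np.ndarray, np.ndarray, bool]:
    res = least_squares(
        residual_fn,
        x0,
        bounds=(lower, upper),
        method="trf",
        ftol=_FTOL,
        xtol=_FTOL,
        gtol=_FTOL,
        max_nfev=_MAX_NFEV,
    )
    return res.x, res.fun, bool(res.success)


def _require_gates(splits: SplitTimes, n_params: int) -> None:
    if len(splits) < n_params + 1:
        raise ValueError(
            f"{n_params}-parameter fit needs at least {n_params + 1} gates, "
            f"got {len(splits)}"
        )


def fit_no_correction(splits: SplitTimes) -> FitResult:
    """Fit MSS, TAU assuming timing starts exactly at first movement."""
    _require_gates(splits, 2)
    d, t = splits.distances, splits.times

    def resid(p):
        return time_at_distance(SprintProfile(p[0], p[1]), d) - t

    x, r, ok = _solve(
        resid,
        _initial_mss_tau(d, t),
        [_MSS_BOUNDS[0], _TAU_BOUNDS[0]],
        [_MSS_BOUNDS[1], _TAU_BOUNDS[1]],
    )
    return FitResult(
        model="no_correction",
        profile=SprintProfile(x[0], x[1]),
        correction=CorrectionParams(),
        residuals=r,
        rss=float(np.sum(r**2)),
        converged=ok,
        n_obs=len(splits),
    )


def fit_fixed_tc(splits: SplitTimes, tc_fixed: float) -> FitResult:
    """Fit MSS, TAU after adding a known time correction to every split."""
    _require_gates(splits, 2)
    d, t = splits.distances, splits.times + tc_fixed

    def resid(p):
        return time_at_distance(SprintProfile(p[0], p[1]), d) - t

    x, r, ok = _solve(
        resid,
        _initial_mss_tau(d, t),
        [_MSS_BOUNDS[0], _TAU_BOUNDS[0]],
        [_MSS_BOUNDS[1], _TAU_BOUNDS[1]],
    )
    return FitResult(
        model="fixed_tc",
        profile=SprintProfile(x[0], x[1]),
        correction=CorrectionParams(tc=tc_fixed),
        residuals=r,
        rss=float(np.sum(r**2)),
        converged=ok,
        n_obs=len(splits),
    )


def fit_estimated_tc(splits: SplitTimes) -> FitResult:
    """Fit MSS, TAU and a free time correction TC (any sign)."""
    _require_gates(splits, 3)
    d, t = splits.distances, splits.times

    def resid(p):
        return time_at_distance_tc(SprintProfile(p[0], p[1]), p[2], d) - t

    mss0, tau0 = _initial_mss_tau(d, t)
    x, r, ok = _solve(
        resid,
        [mss0, tau0, 0.0],
        [_MSS_BOUNDS[0], _TAU_BOUNDS[0], _TC_BOUNDS[0]],
        [_MSS_BOUNDS[1], _TAU_BOUNDS[1], _TC_BOUNDS[1]],
    )
    return FitResult(
        model="estimated_tc",
        profile=SprintProfile(x[0], x[1]),
        correction=CorrectionParams(tc=float(x[2])),
        residuals=r,
        rss=float(np.sum(r**2)),
        converged=ok,
        n_obs=len(splits),
    )


def fit_fixed_fd(splits: SplitTimes, fd_fixed: float) -> FitResult:
    """Fit MSS, TAU under a known flying-start distance."""
    if fd_fixed < 0:
        raise ValueError(f"FD must be >= 0, got {fd_fixed}")
    _require_gates(splits, 2)
    d, t = splits.distances, splits.times

    def resid(p):
        return time_at_distance_fd(SprintProfile(p[0], p[1]), fd_fixed, d) - t

    x, r, ok = _solve(
        resid,
        _initial_mss_tau(d, t),
        [_MSS_BOUNDS[0], _TAU_BOUNDS[0]],
        [_MSS_BOUNDS[1], _TAU_BOUNDS[1]],
    )
    return FitResult(
        model="fixed_fd",
        profile=SprintProfile(x[0], x[1]),
        correction=CorrectionParams(fd=fd_fixed),
        residuals=r,
        rss=float(np.sum(r**2)),
        converged=ok,
        n_obs=len(splits),
    )


def fit_estimated_fd(splits: SplitTimes) -> FitResult:
    """Fit MSS, TAU and a free flying-start distance FD >= 0.

    FD may land on the 0 bound.  Non-convergence is reported via the
    ``converged`` flag rather than raised: on some real trials this
    model cannot be fitted.
    """
    _require_gates(splits, 3)
    d, t = splits.distances, splits.times

    def resid(p):
        return time_at_distance_fd(SprintProfile(p[0], p[1]), p[2], d) - t

    mss0, tau0 = _initial_mss_tau(d, t)
    try:
        x, r, ok = _solve(
            resid,
            [mss0, tau0, 0.0],
            [_MSS_BOUNDS[0], _TAU_BOUNDS[0], _FD_BOUNDS[0]],
            [_MSS_BOUNDS[1], _TAU_BOUNDS[1], _FD_BOUNDS[1]],
        )
    except Exception:
        prof = SprintProfile(mss0, tau0)
        r = time_at_distance(prof, d) - t
        return FitResult(
            model="estimated_fd",
            profile=prof,
            correction=CorrectionParams(fd=0.0),
            residuals=r,
            rss=float(np.sum(r**2)),
            converged=False,
            n_obs=len(splits),
        )
    return FitResult(
        model="estimated_fd",
        profile=SprintProfile(x[0], x[1]),
        correction=CorrectionParams(fd=float(x[2])),
        residuals=r,
        rss=float(np.sum(r**2)),
        converged=ok,
        n_obs=len(splits),
    )


def fit_laser_trace(trace: VelocityTrace, v_threshold: float = 0.5) -> FitResult:
    """Fit MSS, TAU, TC to a laser velocity trace.

    Samples before the smoothed velocity (raw, if no smoothed channel)
    first crosses ``v_threshold`` are discarded; the time-shifted
    velocity model is then fitted to the *raw* velocity on the original
    time axis.
    """
    gate = trace.v_smooth if trace.v_smooth is not None else trace.v_raw
    above = np.nonzero(gate >= v_threshold)[0]
    if len(above) == 0:
        raise ValueError(
            f"trace never reaches the {v_threshold} m/s threshold"
        )
    i0 = above[0]
    t, v = trace.t[i0:], trace.v_raw[i0:]
    if len(t) < 4:
        raise ValueError("too few samples above threshold to fit 3 parameters")

    def resid(p):
        mss, tau, tc = p
        # unclamped: data below the start line were filtered out
        return mss * (1.0 - np.exp(-(t - tc) / tau)) - v

    mss0 = min(max(float(np.max(v)), 1.0), _MSS_BOUNDS[1] * 0.99)
    x, r, ok = _solve(
        resid,
        [mss0, 1.0, 0.0],
        [_MSS_BOUNDS[0], _TAU_BOUNDS[0], _TC_BOUNDS[0]],
        [_MSS_BOUNDS[1], _TAU_BOUNDS[1], _TC_BOUNDS[1]],
    )
    return FitResult(
        model="laser_tc",
        profile=SprintProfile(x[0], x[1]),
        correction=CorrectionParams(tc=float(x[2])),
        residuals=r,
        rss=float(np.sum(r**2)),
        converged=ok,
        n_obs=len(t),
    )


def predict_times(fit: FitResult, distances):
    """Predicted split times of a fitted model, on the data's own time axis.

    For ``fixed_tc`` the model was fitted to times + TC, so predictions
    on the original axis subtract the fixed correction back out.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    d = np.asarray(distances, dtype=float)
    if fit.model in ("no_correction",):
        return time_at_distance(fit.profile, d)
    if fit.model == "fixed_tc":
        return time_at_distance(fit.profile, d) - fit.correction.tc
    if fit.model in ("estimated_tc", "laser_tc"):
        return time_at_distance_tc(fit.profile, fit.correction.tc, d)
    if fit.model in ("fixed_fd", "estimated_fd"):
        return time_at_distance_fd(fit.profile, fit.correction.fd, d)
    raise ValueError(f"unknown model {fit.model!r}")


def predict_velocity(fit: FitResult, times):
    """Predicted velocity of a fitted model at the given times."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    t = np.asarray(times, dtype=float)
    tc = fit.correction.tc
    if fit.model in ("estimated_tc", "laser_tc") and tc is not None:
        v = fit.profile.mss * (1.0 - np.exp(-(t - tc) / fit.profile.tau))
        return np.maximum(v, 0.0)
    return velocity_at_time(fit.profile, t)
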