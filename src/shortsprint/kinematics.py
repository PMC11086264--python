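"""Closed-form mono-exponential short-sprint kinematics.

The model describes the velocity of an athlete accelerating from a
stationary start as

    v(t) = MSS * (1 - exp(-t / TAU))

where MSS is the maximal sprinting speed (m/s) and TAU the relative
acceleration (s), the time constant of the exponential: the time needed
to reach 63.2% of MSS.  Two derived parameters summarise the profile:
the maximal acceleration MAC = MSS / TAU (the acceleration at t = 0,
m/s^2) and the relative propulsive maximal power PMAX = MSS * MAC / 4
(W/kg, air resistance ignored).

Integrating v(t) gives distance as a function of time; inverting that
relation with the principal branch of the Lambert W function gives time
as a function of distance, which is the regression function used when
fitting timing-gate split times (time is the outcome, distance the
predictor).  Two distorted-start variants of the inversion are provided:
an additive time correction TC (constant time shift, e.g. reaction time)
and a flying-start distance FD (distance already covered when the first
gate fires, which shifts *and* bends the split-time curve).

All operations accept scalar or array time/distance and apply
elementwise.  Units are fixed: m, s, m/s, m/s^2, W/kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

__all__ = [
    "SprintProfile",
    "CorrectionParams",
    "velocity_at_time",
    "velocity_at_time_tc",
    "acceleration_at_time",
    "distance_at_time",
    "time_at_distance",
    "time_at_distance_tc",
    "time_at_distance_fd",
    "avp_line",
]


@dataclass(frozen=True)
class SprintProfile:
    """Parameter set {MSS, TAU} (with derived MAC, PMAX) of one athlete.

    Parameters
    ----------
    mss : float
        Maximal sprinting speed, m/s.  Must be > 0.
    tau : float
        Relative acceleration (model time constant), s.  Must be > 0.
    """

    mss: float
    tau: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mss) and self.mss > 0):
            raise ValueError(f"MSS must be finite and > 0, got {self.mss}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"TAU must be finite and > 0, got {self.tau}")

    @property
    def mac(self) -> float:
        """Maximal acceleration MSS / TAU, m/s^2."""
        return self.mss / self.tau

    @property
    def pmax(self) -> float:
        """Relative propulsive maximal power MSS * MAC / 4, W/kg."""
        return self.mss * self.mac / 4.0

    @classmethod
    def from_mss_mac(cls, mss: float, mac: float) -> "SprintProfile":
        """Build a profile from MSS and MAC (TAU = MSS / MAC)."""
        if mac <= 0:
            raise ValueError(f"MAC must be > 0, got {mac}")
        return cls(mss=mss, tau=mss / mac)


@dataclass(frozen=True)
class CorrectionParams:
    """Start-distortion parameters attached to a fitted model.

    tc : additive time correction, s (any sign; None when inactive).
    fd : flying-start distance, m (>= 0; None when inactive).
    """

    tc: float | None = None
    fd: float | None = None

    def __post_init__(self) -> None:
        if self.fd is not None and self.fd < 0:
            raise ValueError(f"FD must be >= 0, got {self.fd}")


def _check_finite(x, name: str):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")
    return x


def velocity_at_time(profile: SprintProfile, t):
    """Instantaneous velocity v(t) = MSS * (1 - exp(-t/TAU)), m/s."""
    t = _check_finite(t, "t")
    return profile.mss * (1.0 - np.exp(-t / profile.tau))


def velocity_at_time_tc(profile: SprintProfile, tc: float, t):
    """Time-shifted velocity MSS * (1 - exp(-(t - TC)/TAU)), m/s.

    Samples before the start of movement (t < TC) predict 0 rather than
    a negative extrapolation; model fitting uses the unclamped
    expression on threshold-filtered data only.
    """
    t = _check_finite(t, "t")
    v = profile.mss * (1.0 - np.exp(-(t - tc) / profile.tau))
    return np.maximum(v, 0.0)


def acceleration_at_time(profile: SprintProfile, t):
    """Instantaneous acceleration MAC * exp(-t/TAU), m/s^2."""
    t = _check_finite(t, "t")
    return profile.mac * np.exp(-t / profile.tau)


def distance_at_time(profile: SprintProfile, t):
    """Distance covered MSS * (t + TAU * exp(-t/TAU)) - MSS * TAU, m."""
    t = _check_finite(t, "t")
    mss, tau = profile.mss, profile.tau
    return mss * (t + tau * np.exp(-t / tau)) - mss * tau


def time_at_distance(profile: SprintProfile, d):
    """Split time at distance d, via the Lambert W inversion.

    t(d) = TAU * W0(-exp(-d/(MSS*TAU) - 1)) + d/MSS + TAU

    with W0 the principal branch.  The argument lies in [-1/e, 0); at
    d = 0 it sits exactly on the branch point W0(-1/e) = -1 and t = 0.
    A clamp guards against floating-point excursions below -1/e.
    """
    d = _check_finite(d, "d")
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    mss, tau = profile.mss, profile.tau
    z = -np.exp(-d / (mss * tau) - 1.0)
    z = np.maximum(z, -np.exp(-1.0))  # branch-point guard
    w = np.real(lambertw(z, k=0))
    t = tau * w + d / mss + tau
    # exact at the branch point: W(-1/e) = -1 -> t = 0
    return np.where(d == 0, 0.0, t) if np.ndim(d) else (0.0 if d == 0 else float(t))


def time_at_distance_tc(profile: SprintProfile, tc: float, d):
    """Split time with additive time correction: t(d) + TC."""
    return time_at_distance(profile, d) + tc


def time_at_distance_fd(profile: SprintProfile, fd: float, d):
    """Split time under a flying start of fd metres: t(d + FD) - t(FD).

    The athlete has already covered FD metres (and carries the
    corresponding velocity) when the first gate triggers, so every split
    is shortened — by more at short distances, which is why a flying
    start cannot be absorbed by a constant time shift.
    """
    if fd < 0:
        raise ValueError(f"FD must be >= 0, got {fd}")
    t0 = time_at_distance(profile, fd)
    return time_at_distance(profile, np.asarray(d, dtype=float) + fd) - t0


def avp_line(profile: SprintProfile) -> tuple[float, float]:
    """Acceleration-velocity profile line a(v) = MAC - (MAC/MSS) * v.

    Returns (intercept, slope) = (MAC, -MAC/MSS): acceleration is MAC at
    v = 0 and reaches 0 at v = MSS.  Power a*v peaks at v = MSS/2 with
    value PMAX.
    """
    return profile.mac, -profile.mac / profile.mss
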