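"""Generative models for timing-gate split times and laser traces.

The split-time data-generating process under known true parameters is

    t_i = round( [t(d_i + FD) - t(FD)] + RT, clock )

where t(.) is the Lambert-W split-time function, FD a flying-start
distance (the athlete begins FD metres behind the first gate and
carries velocity into it), RT an additive reaction time (e.g. a
gun-started clock), and ``clock`` the timing-system precision
(round-half-away-from-zero; 0.01 s for typical photocell systems).

``generate_triplets`` builds the canonical three-athlete demonstration:
identical true profiles (MSS 9.5 m/s, TAU 1.357 s), one clean start,
one 0.5 m flying start, one 0.2 s gun-started clock, all rounded to
0.01 s.

``generate_laser_trace`` and ``generate_cohort`` provide synthetic
stand-ins for a laser-gun criterion instrument and a multi-athlete,
multi-trial testing session; both are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import SprintProfile, time_at_distance, velocity_at_time_tc
from .fitting import SplitTimes, VelocityTrace

__all__ = [
    "GateSetup",
    "CohortSpec",
    "CohortTrial",
    "round_to_clock",
    "generate_splits",
    "generate_triplets",
    "generate_laser_trace",
    "generate_cohort",
    "cohort_to_frame",
    "TRIPLET_PROFILE",
]

#: True profile shared by the three demonstration athletes:
#: MSS 9.5 m/s, MAC exactly 7 m/s^2 (TAU = 19/14 ~ 1.357 s, PMAX 16.625).
TRIPLET_PROFILE = SprintProfile.from_mss_mac(mss=9.5, mac=7.0)

_DEFAULT_GATES = (5.0, 10.0, 20.0, 30.0, 40.0)


def round_to_clock(t, clock: float | None):
    """Round times to the clock precision, half away from zero.

    Timing systems report the nearest tick; for positive times
    half-away-from-zero is floor(t/clock + 0.5) * clock.
    """
    if clock is None:
        return np.asarray(t, dtype=float)
    if clock <= 0:
        raise ValueError(f"clock precision must be > 0, got {clock}")
    return np.floor(np.asarray(t, dtype=float) / clock + 0.5) * clock


@dataclass(frozen=True)
class GateSetup:
    """Gate layout and start-distortion of a simulated trial.

    gate_positions : gate distances from the first gate, m, increasing.
    flying_distance: m the athlete starts behind the first gate (>= 0).
    reaction_time  : s added to every split (gun-started clock; >= 0).
    rounding       : clock precision, s, or None for exact times.
    """

    gate_positions: tuple = _DEFAULT_GATES
    flying_distance: float = 0.0
    reaction_time: float = 0.0
    rounding: float | None = 0.01

    def __post_init__(self) -> None:
        pos = np.asarray(self.gate_positions, dtype=float)
        if np.any(pos <= 0) or np.any(np.diff(pos) <= 0):
            raise ValueError("gate positions must be positive and increasing")
        if self.flying_distance < 0:
            raise ValueError("flying_distance must be >= 0")
        if self.reaction_time < 0:
            raise ValueError("reaction_time must be >= 0")
        if self.rounding is not None and self.rounding <= 0:
            raise ValueError("rounding must be > 0 or None")


def generate_splits(profile: SprintProfile, setup: GateSetup) -> SplitTimes:
    """Exact-model split times under the gate setup's distortions."""
    d = np.asarray(setup.gate_positions, dtype=float)
    fd = setup.flying_distance
    t = time_at_distance(profile, d + fd) - time_at_distance(profile, fd)
    t = t + setup.reaction_time
    t = round_to_clock(t, setup.rounding)
    return SplitTimes(
        distances=d, times=t, provenance="simulated", rounding=setup.rounding
    )


def generate_triplets() -> dict[str, SplitTimes]:
    """The canonical clean / flying-start / gun-start demonstration.

    Three athletes with identical true profiles (MSS 9.5, TAU 1.357,
    hence MAC 7, PMAX 16.625) sprint 40 m with gates at 5/10/20/30/40 m
    and a 0.01 s clock:

    - Andrew triggers the first gate at first movement (clean start);
    - Ben starts 0.5 m behind the first gate (flying start);
    - Cole's clock starts at the gun, 0.2 s before first movement.
    """
    gates = _DEFAULT_GATES
    return {
        "Andrew": generate_splits(
            TRIPLET_PROFILE, GateSetup(gates, flying_distance=0.0)
        ),
        "Ben": generate_splits(
            TRIPLET_PROFILE, GateSetup(gates, flying_distance=0.5)
        ),
        "Cole": generate_splits(
            TRIPLET_PROFILE, GateSetup(gates, reaction_time=0.2)
        ),
    }


def generate_laser_trace(
    profile: SprintProfile,
    tc: float = 0.0,
    sample_rate: float = 1000.0,
    target_distance: float = 30.0,
    noise_sd: float = 0.05,
    smooth_window: int = 51,
    seed: int | np.random.Generator | None = None,
) -> VelocityTrace:
    """Synthetic laser-gun velocity trace with Gaussian sensor noise.

    The noiseless velocity follows the time-shifted model (clamped to 0
    before the start at t = TC); iid Gaussian noise of sd ``noise_sd``
    is added to the raw channel, and the smoothed channel is a centered
    moving average of the raw one over ``smooth_window`` samples.  The
    trace spans from t = 0 to the time the athlete reaches
    ``target_distance`` (plus the shift TC).
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    rng = np.random.default_rng(seed)
    t_end = float(time_at_distance(profile, target_distance)) + max(tc, 0.0)
    n = int(np.ceil(t_end * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    v = velocity_at_time_tc(profile, tc, t)
    v_raw = v + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else v.copy()
    if smooth_window and smooth_window > 1:
        k = int(smooth_window)
        kernel = np.ones(k) / k
        pad = k // 2
        vp = np.pad(v_raw, pad, mode="edge")
        v_smooth = np.convolve(vp, kernel, mode="valid")[: len(t)]
    else:
        v_smooth = v_raw.copy()
    return VelocityTrace(t=t, v_raw=v_raw, v_smooth=v_smooth)


@dataclass(frozen=True)
class CohortTrial:
    """One simulated athlete-trial: the truth and what was measured."""

    athlete: str
    trial: int
    true_profile: SprintProfile
    splits: SplitTimes


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic testing session.

    Defaults emulate a squad test: 31 athletes, 2 trials each, gates at
    5/10/20/30 m, a 0.5 m flying start, a 0.01 s clock, and a small
    additive trial-to-trial timing noise (0.01 s sd, the order of the
    clock precision).  Athlete profiles are drawn from
    MSS ~ N(mss_mean, mss_sd) and MAC ~ N(mac_mean, mac_sd), truncated
    positive; the defaults span the range typical of field-sport
    athletes.
    """

    n_athletes: int = 31
    n_trials: int = 2
    mss_mean: float = 8.0
    mss_sd: float = 0.7
    mac_mean: float = 7.0
    mac_sd: float = 1.0
    split_noise_sd: float = 0.01
    gate_positions: tuple = (5.0, 10.0, 20.0, 30.0)
    flying_distance: float = 0.5
    rounding: float | None = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_athletes < 1 or self.n_trials < 1:
            raise ValueError("need at least one athlete and one trial")
        for name in ("mss_sd", "mac_sd", "split_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _truncated_positive_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float = 0.1
):
    """One draw from N(mean, sd) redrawn until above ``floor``."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > floor:
            return float(x)
    raise RuntimeError("truncated normal draw failed; check mean/sd")


def generate_cohort(spec: CohortSpec) -> list[CohortTrial]:
    """Draw athlete profiles and simulate their gate trials.

    One true profile per athlete; each trial adds independent Gaussian
    noise (sd ``split_noise_sd``) to the exact distorted split times
    before clock rounding.  Fully reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    d = np.asarray(spec.gate_positions, dtype=float)
    trials: list[CohortTrial] = []
    for i in range(spec.n_athletes):
        mss = _truncated_positive_normal(rng, spec.mss_mean, spec.mss_sd, 2.0)
        mac = _truncated_positive_normal(rng, spec.mac_mean, spec.mac_sd, 1.0)
        profile = SprintProfile.from_mss_mac(mss, mac)
        fd = spec.flying_distance
        t_exact = time_at_distance(profile, d + fd) - time_at_distance(profile, fd)
        for j in range(spec.n_trials):
            t = t_exact.copy()
            if spec.split_noise_sd > 0:
                t = np.maximum(
                    t + rng.normal(0.0, spec.split_noise_sd, size=len(d)), 1e-3
                )
            t = round_to_clock(t, spec.rounding)
            # noise or rounding can tie adjacent gates; restore monotonicity
            tick = spec.rounding if spec.rounding else 1e-6
            for k in range(1, len(t)):
                if t[k] <= t[k - 1]:
                    t[k] = t[k - 1] + tick
            trials.append(
                CohortTrial(
                    athlete=f"athlete_{i + 1:02d}",
                    trial=j + 1,
                    true_profile=profile,
                    splits=SplitTimes(
                        distances=d,
                        times=t,
                        provenance="simulated",
                        rounding=spec.rounding,
                    ),
                )
            )
    return trials


def cohort_to_frame(trials: list[CohortTrial]) -> pd.DataFrame:
    """Tidy long table: athlete, trial, gate distance, split time, truth."""
    rows = []
    for tr in trials:
        for d, t in zip(tr.splits.distances, tr.splits.times):
            rows.append(
                {
                    "athlete": tr.athlete,
                    "trial": tr.trial,
                    "distance": d,
                    "time": t,
                    "true_MSS": tr.true_profile.mss,
                    "true_TAU": tr.true_profile.tau,
                }
            )
    return pd.DataFrame(rows)
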