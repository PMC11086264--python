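"""End-to-end workflows: trial screening, the triplet worked example,
and the criterion-vs-gates validation study.

``triplet_report`` regenerates the three-athlete demonstration (clean /
flying-start / gun-start) and fits all six timing-gate model variants to
each athlete, tabulating the estimates next to their absolute percent
difference from the shared true parameters.

``run_validation`` runs the full validity workflow over a cohort: per
trial it (a) fits the laser criterion, (b) fits each gate model to the
observed splits, (c) regenerates splits from the criterion parameters
under the assumed distortion (0.5 m flying start, 0.01 s clock) and fits
each model to those as the "simulated" comparison arm, then (d) emits an
agreement report per model x parameter x arm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .agreement import PairedEstimates, agreement_report
from .fitting import (
    FitResult,
    SplitTimes,
    VelocityTrace,
    fit_estimated_fd,
    fit_estimated_tc,
    fit_fixed_fd,
    fit_fixed_tc,
    fit_laser_trace,
    fit_no_correction,
)
from .kinematics import SprintProfile
from .simulate import (
    CohortSpec,
    CohortTrial,
    GateSetup,
    generate_cohort,
    generate_laser_trace,
    generate_splits,
    generate_triplets,
    TRIPLET_PROFILE,
)

__all__ = [
    "TrialRecord",
    "ValidationConfig",
    "segment_velocities",
    "exclude_decelerating_trials",
    "exclude_short_laser_trials",
    "triplet_report",
    "run_validation",
    "PARAMETERS",
    "GATE_MODELS",
]

PARAMETERS = ("MSS", "TAU", "MAC", "PMAX")

#: The five timing-gate models of the validation study, with their fitters.
GATE_MODELS = {
    "no_correction": lambda s: fit_no_correction(s),
    "fixed_tc_0.3": lambda s: fit_fixed_tc(s, 0.3),
    "estimated_tc": lambda s: fit_estimated_tc(s),
    "fixed_fd_0.5": lambda s: fit_fixed_fd(s, 0.5),
    "estimated_fd": lambda s: fit_estimated_fd(s),
}

REASON_DECELERATION = "deceleration"
REASON_SHORT_TRACE = "short_laser_trace"
REASON_MALFORMED = "malformed_splits"


@dataclass(frozen=True)
class TrialRecord:
    """One athlete-trial with inclusion flags."""

    athlete: str
    trial: int
    splits: SplitTimes | None = None
    trace: VelocityTrace | None = None
    trace_length: float | None = None  # m actually covered by the laser
    included: bool = True
    exclusion_reason: str | None = None


def segment_velocities(splits: SplitTimes) -> np.ndarray:
    """Mean velocity of each inter-gate segment, the start counting as
    a gate at (d, t) = (0, 0)."""
    d = np.concatenate([[0.0], splits.distances])
    t = np.concatenate([[0.0], splits.times])
    return np.diff(d) / np.diff(t)


def exclude_decelerating_trials(record: TrialRecord) -> TrialRecord:
    """Flag trials where any segment's mean velocity drops below the
    previous segment's (the athlete decelerated between gates)."""
    if record.splits is None or not record.included:
        return record
    try:
        v = segment_velocities(record.splits)
    except Exception:
        return replace(
            record, included=False, exclusion_reason=REASON_MALFORMED
        )
    if len(v) >= 2 and np.any(np.diff(v) < 0):
        return replace(
            record, included=False, exclusion_reason=REASON_DECELERATION
        )
    return record


def exclude_short_laser_trials(
    record: TrialRecord, min_length: float = 29.0
) -> TrialRecord:
    """Flag trials whose laser trace covers less than ``min_length`` m.

    The covered distance is ``trace_length`` when supplied, otherwise
    the time-integral of the raw velocity.  The boundary is a strict
    less-than: a trace of exactly ``min_length`` m is kept.
    """
    if not record.included:
        return record
    length = record.trace_length
    if length is None:
        if record.trace is None:
            return record
        length = float(np.trapezoid(record.trace.v_raw, record.trace.t))
    if length < min_length:
        return replace(
            record, included=False, exclusion_reason=REASON_SHORT_TRACE
        )
    return record


def _fit_row(name: str, athlete: str, fit: FitResult, truth: SprintProfile) -> dict:
    prof = fit.profile
    row = {
        "model": name,
        "athlete": athlete,
        "MSS": prof.mss,
        "TAU": prof.tau,
        "MAC": prof.mac,
        "PMAX": prof.pmax,
        "TC": fit.correction.tc,
        "FD": fit.correction.fd,
        "converged": fit.converged,
    }
    for p in PARAMETERS:
        row[f"pct_diff_{p}"] = 100.0 * abs(row[p] - getattr(truth, p.lower())) / getattr(
            truth, p.lower()
        )
    return row


#: Display names and fitters for the worked example (adds the +0.5 s model).
TRIPLET_MODELS = {
    "No Correction": lambda s: fit_no_correction(s),
    "Fixed +0.3 s TC": lambda s: fit_fixed_tc(s, 0.3),
    "Fixed +0.5 s TC": lambda s: fit_fixed_tc(s, 0.5),
    "Estimated TC": lambda s: fit_estimated_tc(s),
    "Fixed 0.5 m FD": lambda s: fit_fixed_fd(s, 0.5),
    "Estimated FD": lambda s: fit_estimated_fd(s),
}

TRIPLET_LABELS = {
    "Andrew": "Andrew (theoretical)",
    "Ben": "Ben (flying start)",
    "Cole": "Cole (gunfire)",
}


def triplet_report() -> pd.DataFrame:
    """The worked-example table: six models x three athletes.

    Columns: model, athlete, MSS, TAU, MAC, PMAX, TC, FD, converged and
    the absolute percent difference of each parameter from the shared
    truth (MSS 9.5, TAU 1.357, MAC 7, PMAX 16.625).  The first row
    carries the true values.  Deterministic (no randomness involved).
    """
    truth = TRIPLET_PROFILE
    rows = [
        {
            "model": "True",
            "athlete": "True",
            "MSS": truth.mss,
            "TAU": truth.tau,
            "MAC": truth.mac,
            "PMAX": truth.pmax,
            "TC": None,
            "FD": None,
            "converged": True,
            **{f"pct_diff_{p}": 0.0 for p in PARAMETERS},
        }
    ]
    splits = generate_triplets()
    for model_name, fitter in TRIPLET_MODELS.items():
        for athlete in ("Andrew", "Ben", "Cole"):
            fit = fitter(splits[athlete])
            rows.append(
                _fit_row(model_name, TRIPLET_LABELS[athlete], fit, truth)
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ValidationConfig:
    """Knobs of the validation workflow.

    criterion        : "refit" fits the criterion on a synthetic laser
                       trace per trial (closer to a real study);
                       "truth" uses the generating profile directly.
    sim_flying_distance / sim_rounding : distortion assumed when
                       regenerating the simulated comparison arm from
                       the criterion parameters.
    laser_noise_sd   : sensor noise of the synthetic criterion trace.
    ci               : compute BCa bootstrap intervals (slower).
    """

    models: tuple = tuple(GATE_MODELS)
    arms: tuple = ("observed", "simulated")
    criterion: str = "refit"
    sim_flying_distance: float = 0.5
    sim_rounding: float | None = 0.01
    laser_noise_sd: float = 0.05
    laser_sample_rate: float = 1000.0
    laser_target_distance: float = 30.0
    mad_mode: str = "deviation"
    ci: bool = True
    n_resamples: int = 5000
    conf: float = 0.95


def _params_of(fit: FitResult) -> dict[str, float]:
    p = fit.profile
    return {"MSS": p.mss, "TAU": p.tau, "MAC": p.mac, "PMAX": p.pmax}


def run_validation(
    cohort: list[CohortTrial] | None = None,
    spec: CohortSpec | None = None,
    config: ValidationConfig = ValidationConfig(),
    seed: int | None = None,
) -> pd.DataFrame:
    """Agreement reports for every model x parameter x arm cell.

    Returns a tidy frame with columns model, parameter, arm, n,
    pct_bias(+CI), pct_mad(+CI), pct_rse, pct_mdc95(+CI).  Fully
    reproducible under ``seed`` (which also seeds the cohort when one is
    generated here from ``spec``).
    """
    rng_seq = np.random.SeedSequence(seed)
    if cohort is None:
        spec = spec if spec is not None else CohortSpec(seed=seed)
        if spec.seed is None:
            spec = replace(spec, seed=int(rng_seq.generate_state(1)[0] % 2**31))
        cohort = generate_cohort(spec)

    laser_seeds = rng_seq.spawn(len(cohort))
    criterion_params: list[dict[str, float]] = []
    practical: dict[tuple[str, str], list[dict[str, float]]] = {
        (arm, m): [] for arm in config.arms for m in config.models
    }
    kept: list[CohortTrial] = []
    for trial, lseed in zip(cohort, laser_seeds):
        rec = exclude_decelerating_trials(
            TrialRecord(trial.athlete, trial.trial, splits=trial.splits)
        )
        if not rec.included:
            continue
        if config.criterion == "truth":
            crit_profile = trial.true_profile
        else:
            trace = generate_laser_trace(
                trial.true_profile,
                tc=0.0,
                sample_rate=config.laser_sample_rate,
                target_distance=config.laser_target_distance,
                noise_sd=config.laser_noise_sd,
                seed=np.random.default_rng(lseed),
            )
            crit_profile = fit_laser_trace(trace).profile
        row_crit = {
            "MSS": crit_profile.mss,
            "TAU": crit_profile.tau,
            "MAC": crit_profile.mac,
            "PMAX": crit_profile.pmax,
        }

        arm_splits: dict[str, SplitTimes] = {}
        if "observed" in config.arms:
            arm_splits["observed"] = trial.splits
        if "simulated" in config.arms:
            arm_splits["simulated"] = generate_splits(
                crit_profile,
                GateSetup(
                    gate_positions=tuple(trial.splits.distances),
                    flying_distance=config.sim_flying_distance,
                    rounding=config.sim_rounding,
                ),
            )

        fits = {}
        ok = True
        for arm, splits in arm_splits.items():
            for m in config.models:
                fit = GATE_MODELS[m](splits)
                if not fit.converged:
                    ok = False
                fits[(arm, m)] = fit
        if not ok:
            continue  # drop trials any model fails on, like failed real fits
        criterion_params.append(row_crit)
        for key, fit in fits.items():
            practical[key].append(_params_of(fit))
        kept.append(trial)

    if len(criterion_params) < 3:
        raise ValueError("fewer than 3 usable trials; cannot assess agreement")

    boot_seed = int(rng_seq.generate_state(2)[1] % 2**31)
    rows = []
    for arm in config.arms:
        for m in config.models:
            for p in PARAMETERS:
                pairs = PairedEstimates(
                    criterion=np.array([c[p] for c in criterion_params]),
                    practical=np.array([r[p] for r in practical[(arm, m)]]),
                    parameter=p,
                    model=m,
                )
                rep = agreement_report(
                    pairs,
                    mad_mode=config.mad_mode,
                    ci=config.ci,
                    n_resamples=config.n_resamples,
                    conf=config.conf,
                    seed=boot_seed,
                )
                row = rep.as_dict()
                row["arm"] = arm
                rows.append(row)
    out = pd.DataFrame(rows)
    cols = ["arm"] + [c for c in out.columns if c != "arm"]
    return out[cols]
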