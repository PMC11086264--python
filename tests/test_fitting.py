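"""Model fitting: printed-table reproduction, parameter recovery,
brute-force oracle equivalence, laser-trace fits."""

import numpy as np
import pytest
from scipy.optimize import minimize

from shortsprint import (
    GateSetup,
    SplitTimes,
    SprintProfile,
    VelocityTrace,
    fit_estimated_fd,
    fit_estimated_tc,
    fit_fixed_fd,
    fit_fixed_tc,
    fit_laser_trace,
    fit_no_correction,
    generate_laser_trace,
    generate_splits,
    predict_times,
    predict_velocity,
    time_at_distance,
    time_at_distance_fd,
)
from conftest import assert_printed

GATES = (5.0, 10.0, 20.0, 30.0, 40.0)


def exact_splits(profile, fd=0.0, rt=0.0):
    return generate_splits(
        profile,
        GateSetup(GATES, flying_distance=fd, reaction_time=rt, rounding=None),
    )


class TestSplitTimesValidation:
    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            SplitTimes([5, 10, 20], [1.0, 0.9, 2.0])
        with pytest.raises(ValueError):
            SplitTimes([5, 10, 5], [1.0, 2.0, 3.0])

    def test_too_few_gates_for_fit(self):
        s = SplitTimes([5, 10], [1.4, 2.1])
        with pytest.raises(ValueError):
            fit_no_correction(s)
        with pytest.raises(ValueError):
            fit_estimated_tc(SplitTimes([5, 10, 20], [1.4, 2.1, 3.3]))


class TestNoCorrection:
    def test_clean_start_table(self, table1_splits):
        fit = fit_no_correction(table1_splits)
        assert fit.converged
        assert_printed(fit.profile.mss, 9.54)
        assert_printed(fit.profile.tau, 1.37)
        assert_printed(fit.profile.mac, 6.96)

    def test_exact_recovery(self, triplet_profile):
        fit = fit_no_correction(exact_splits(triplet_profile))
        assert fit.profile.mss == pytest.approx(9.5, rel=1e-6)
        assert fit.profile.tau == pytest.approx(1.357, rel=1e-6)
        assert fit.rss < 1e-16

    def test_flying_start_bias(self, triplet_profile):
        # an uncorrected flying start inflates MAC enormously
        splits = generate_splits(
            triplet_profile, GateSetup(GATES, flying_distance=0.5)
        )
        fit = fit_no_correction(splits)
        assert_printed(fit.profile.mss, 8.90)
        assert_printed(fit.profile.tau, 0.73)
        assert_printed(fit.profile.mac, 12.15)
        assert_printed(fit.profile.pmax, 27.0, decimals=1)

    def test_derived_parameters_consistent(self, table1_splits):
        fit = fit_no_correction(table1_splits)
        assert fit.profile.mac == fit.profile.mss / fit.profile.tau
        assert fit.profile.pmax == fit.profile.mss * fit.profile.mac / 4


class TestFixedTc:
    def test_half_second_on_clean_start(self, table1_splits):
        fit = fit_fixed_tc(table1_splits, 0.5)
        assert_printed(fit.profile.mss, 12.92)
        assert_printed(fit.profile.tau, 3.55)
        assert fit.correction.tc == 0.5

    def test_plus_point_three_on_flying_start(self, triplet_profile):
        splits = generate_splits(
            triplet_profile, GateSetup(GATES, flying_distance=0.5)
        )
        fit = fit_fixed_tc(splits, 0.3)
        assert_printed(fit.profile.mss, 9.51)
        assert_printed(fit.profile.mac, 7.24)

    def test_zero_tc_equals_no_correction(self, table1_splits):
        a = fit_fixed_tc(table1_splits, 0.0)
        b = fit_no_correction(table1_splits)
        assert a.profile.mss == pytest.approx(b.profile.mss, rel=1e-9)
        assert a.profile.tau == pytest.approx(b.profile.tau, rel=1e-9)


class TestEstimatedTc:
    def test_recovers_reaction_time(self, triplet_profile):
        splits = generate_splits(
            triplet_profile, GateSetup(GATES, reaction_time=0.2)
        )
        fit = fit_estimated_tc(splits)
        assert_printed(fit.correction.tc, 0.19)
        assert_printed(fit.profile.mss, 9.56)

    def test_flying_start_absorbed_as_negative_shift(self, triplet_profile):
        splits = generate_splits(
            triplet_profile, GateSetup(GATES, flying_distance=0.5)
        )
        fit = fit_estimated_tc(splits)
        assert_printed(fit.correction.tc, -0.30)
        assert_printed(fit.profile.mss, 9.5)

    def test_exact_shift_recovery(self, triplet_profile):
        splits = exact_splits(triplet_profile, rt=0.2)
        fit = fit_estimated_tc(splits)
        assert fit.correction.tc == pytest.approx(0.2, abs=1e-6)
        assert fit.profile.mss == pytest.approx(9.5, rel=1e-6)
        assert fit.profile.tau == pytest.approx(1.357, rel=1e-6)


class TestFixedFd:
    def test_correctly_specified(self, triplet_profile):
        splits = generate_splits(
            triplet_profile, GateSetup(GATES, flying_distance=0.5)
        )
        fit = fit_fixed_fd(splits, 0.5)
        assert_printed(fit.profile.mss, 9.52)
        assert_printed(fit.profile.tau, 1.36)
        assert_printed(fit.profile.mac, 6.98)

    def test_misspecified_on_clean_start(self, table1_splits):
        fit = fit_fixed_fd(table1_splits, 0.5)
        assert_printed(fit.profile.mss, 11.75)

    def test_zero_fd_equals_no_correction(self, table1_splits):
        a = fit_fixed_fd(table1_splits, 0.0)
        b = fit_no_correction(table1_splits)
        assert a.profile.mss == pytest.approx(b.profile.mss, rel=1e-9)

    def test_negative_fd_rejected(self, table1_splits):
        with pytest.raises(ValueError):
            fit_fixed_fd(table1_splits, -0.5)


class TestEstimatedFd:
    def test_recovers_flying_distance(self, triplet_profile):
        splits = generate_splits(
            triplet_profile, GateSetup(GATES, flying_distance=0.5)
        )
        fit = fit_estimated_fd(splits)
        assert_printed(fit.correction.fd, 0.54)
        assert_printed(fit.profile.mss, 9.56)

    def test_clean_start_lands_on_zero_bound(self, table1_splits):
        fit = fit_estimated_fd(table1_splits)
        assert fit.correction.fd == pytest.approx(0.0, abs=1e-3)  # prints 0.00

    def test_exact_recovery(self, triplet_profile):
        splits = exact_splits(triplet_profile, fd=0.5)
        fit = fit_estimated_fd(splits)
        assert fit.correction.fd == pytest.approx(0.5, abs=1e-4)
        assert fit.profile.mss == pytest.approx(9.5, rel=1e-5)


class TestOracleEquivalence:
    """The solver must reach the same optimum as an independent
    grid + Nelder-Mead polish of the identical objective."""

    @pytest.mark.parametrize("seed", range(5))
    def test_no_correction_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        truth = SprintProfile(rng.uniform(6, 11), rng.uniform(0.7, 2.0))
        splits = generate_splits(
            truth, GateSetup(GATES, rounding=0.01)
        )
        d, t = splits.distances, splits.times

        def rss(params):
            mss, tau = params
            if mss <= 0 or tau <= 0:
                return 1e9
            r = time_at_distance(SprintProfile(mss, tau), d) - t
            return float(np.sum(r**2))

        # coarse grid then polish
        grid = [
            (m, ta)
            for m in np.linspace(4, 14, 21)
            for ta in np.linspace(0.3, 3.0, 28)
        ]
        x0 = min(grid, key=rss)
        best = minimize(rss, x0, method="Nelder-Mead",
                        options={"xatol": 1e-12, "fatol": 1e-14,
                                 "maxiter": 10000})
        fit = fit_no_correction(splits)
        assert fit.rss <= best.fun * (1 + 1e-10) + 1e-15

    @pytest.mark.parametrize("seed", range(3))
    def test_estimated_fd_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        truth = SprintProfile(rng.uniform(6, 11), rng.uniform(0.7, 2.0))
        fd_true = rng.uniform(0.0, 1.0)
        splits = generate_splits(
            truth, GateSetup(GATES, flying_distance=fd_true, rounding=0.01)
        )
        d, t = splits.distances, splits.times

        def rss(params):
            mss, tau, fd = params
            if mss <= 0 or tau <= 0 or fd < 0:
                return 1e9
            r = time_at_distance_fd(SprintProfile(mss, tau), fd, d) - t
            return float(np.sum(r**2))

        grid = [
            (m, ta, f)
            for m in np.linspace(5, 13, 9)
            for ta in np.linspace(0.4, 2.6, 12)
            for f in np.linspace(0, 2, 9)
        ]
        x0 = min(grid, key=rss)
        best = minimize(rss, x0, method="Nelder-Mead",
                        options={"xatol": 1e-12, "fatol": 1e-14,
                                 "maxiter": 20000})
        fit = fit_estimated_fd(splits)
        assert fit.rss <= best.fun * (1 + 1e-10) + 1e-15


class TestLaserTrace:
    def test_noiseless_recovery(self):
        truth = SprintProfile(9.0, 1.2)
        trace = generate_laser_trace(truth, tc=0.8, noise_sd=0.0)
        fit = fit_laser_trace(trace)
        assert fit.profile.mss == pytest.approx(9.0, rel=1e-6)
        assert fit.profile.tau == pytest.approx(1.2, rel=1e-6)
        assert fit.correction.tc == pytest.approx(0.8, abs=1e-6)

    def test_filter_drops_prestart_samples(self):
        truth = SprintProfile(9.0, 1.2)
        trace = generate_laser_trace(truth, tc=0.5, noise_sd=0.0)
        fit = fit_laser_trace(trace, v_threshold=0.5)
        # v = 0.5 m/s is reached only after the start at t = TC
        assert fit.n_obs < len(trace)
        kept_from = trace.t[len(trace) - fit.n_obs]
        assert kept_from > 0.5

    def test_zero_threshold_on_unshifted_trace(self):
        truth = SprintProfile(8.5, 1.0)
        trace = generate_laser_trace(truth, tc=0.0, noise_sd=0.0)
        fit = fit_laser_trace(trace, v_threshold=0.0)
        assert fit.profile.mss == pytest.approx(8.5, rel=1e-6)
        assert fit.correction.tc == pytest.approx(0.0, abs=1e-6)

    def test_never_crossing_threshold_raises(self):
        t = np.linspace(0, 2, 100)
        trace = VelocityTrace(t=t, v_raw=np.full(100, 0.1))
        with pytest.raises(ValueError):
            fit_laser_trace(trace)

    def test_noisy_recovery_monte_carlo(self):
        # mean recovery over seeds within +/-0.5% of truth
        truth = SprintProfile(9.0, 1.2)
        mss, tau, tc = [], [], []
        for seed in range(100):
            trace = generate_laser_trace(
                truth, tc=0.8, noise_sd=0.05, seed=seed
            )
            fit = fit_laser_trace(trace)
            mss.append(fit.profile.mss)
            tau.append(fit.profile.tau)
            tc.append(fit.correction.tc)
        assert np.mean(mss) == pytest.approx(9.0, rel=0.005)
        assert np.mean(tau) == pytest.approx(1.2, rel=0.005)
        assert np.mean(tc) == pytest.approx(0.8, rel=0.005)


class TestPredict:
    def test_self_consistency_on_clean_start(self, table1_splits):
        fit = fit_no_correction(table1_splits)
        t5 = predict_times(fit, [5.0])[0]
        assert round(float(t5), 2) == pytest.approx(1.40, abs=0.011)
        assert predict_times(fit, [0.0])[0] == 0.0

    def test_time_at_origin_is_tc_for_estimated_tc(self, triplet_profile):
        splits = generate_splits(
            triplet_profile, GateSetup(GATES, reaction_time=0.2)
        )
        fit = fit_estimated_tc(splits)
        assert predict_times(fit, [0.0])[0] == pytest.approx(
            fit.correction.tc, rel=1e-9
        )

    def test_velocity_approaches_mss(self, table1_splits):
        fit = fit_no_correction(table1_splits)
        v = predict_velocity(fit, [60.0])[0]
        assert v == pytest.approx(fit.profile.mss, rel=1e-9)

    def test_nonconverged_fit_refuses_to_predict(self, table1_splits):
        import dataclasses

        fit = dataclasses.replace(fit_no_correction(table1_splits),
                                  converged=False)
        with pytest.raises(ValueError):
            predict_times(fit, [5.0])
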