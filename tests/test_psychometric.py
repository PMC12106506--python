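"""Window estimation: rates, side fits, crossings, TBW derivation, groups."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit

import sjwindow as sj
from sjwindow.exceptions import InsufficientDataError, NoCrossingError
from tests.conftest import make_trials

LEVELS_AV = [-400, -334, -267, -200, -167, -100, -67]
LEVELS_VA = [67, 100, 167, 200, 267, 334, 400]


class TestComputeRates:
    def test_direct_count(self):
        trials = make_trials([-100], [8], [16])
        rates = sj.compute_rates(trials)
        assert rates.loc[-100, "rate"] == 0.5
        assert rates.loc[-100, "n_valid"] == 16

    def test_rejected_trials_excluded_from_both_sides_of_ratio(self):
        trials = make_trials([-100], [9], [16])
        # reject two synchronous trials: 7 of remaining 14 synchronous
        rej = trials.index[trials["response"] == 1][:2]
        trials.loc[rej, "rejected"] = True
        rates = sj.compute_rates(trials)
        assert rates.loc[-100, "n_valid"] == 14
        assert rates.loc[-100, "rate"] == 0.5

    def test_saturated_rates(self):
        trials = make_trials([-100, 100], [16, 16], [16, 16])
        assert (sj.compute_rates(trials)["rate"] == 1.0).all()

    def test_empty_input_errors(self):
        with pytest.raises(InsufficientDataError):
            sj.compute_rates(make_trials([], [], []))

    def test_fully_rejected_level_dropped_with_warning(self):
        trials = make_trials([-100, -200], [8, 8], [16, 16])
        trials.loc[trials.soa_ms == -200, "rejected"] = True
        with pytest.warns(UserWarning, match="-200"):
            rates = sj.compute_rates(trials)
        assert list(rates.index) == [-100]

    def test_order_invariance(self, simulated_session):
        trials, _ = simulated_session
        shuffled = trials.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(
            sj.compute_rates(trials), sj.compute_rates(shuffled)
        )


class TestFitSide:
    def test_recovers_generative_coefficients(self):
        """Large-sample ML fit lands within 3 SE of the true (b0, b1)."""
        b0, b1 = 4.8152, 0.02  # crossing at -240.76 ms
        rng = np.random.default_rng(17)
        n = 10_000
        succ = [int(rng.binomial(n, expit(b0 + b1 * s))) for s in LEVELS_AV]
        trials = make_trials(LEVELS_AV, succ, [n] * len(LEVELS_AV))
        fit = sj.fit_side(trials, "AV")
        # oracle SEs from the identical statsmodels trial-level fit
        rates = sj.compute_rates(trials)
        oracle = sm.GLM(
            np.column_stack([rates.n_synchronous, rates.n_valid - rates.n_synchronous]),
            sm.add_constant(rates.index.to_numpy(float)),
            family=sm.families.Binomial(),
        ).fit()
        se0, se1 = oracle.bse
        assert fit.b0 == pytest.approx(b0, abs=3 * se0)
        assert fit.b1 == pytest.approx(b1, abs=3 * se1)
        assert fit.converged and not fit.penalized

    def test_aggregated_equals_trial_level_fit(self, simulated_session):
        """Binomial likelihoods agree: per-SOA counts vs one row per trial."""
        trials, _ = simulated_session
        for side, mask in (("AV", trials.soa_ms < 0), ("VA", trials.soa_ms > 0)):
            fit = sj.fit_side(trials, side)
            sub = trials[mask]
            oracle = sm.GLM(
                sub["response"].astype(float),
                sm.add_constant(sub["soa_ms"].astype(float)),
                family=sm.families.Binomial(),
            ).fit(tol=1e-12, maxiter=300)
            coef = np.asarray(oracle.params)
            assert fit.b0 == pytest.approx(coef[0], abs=1e-8)
            assert fit.b1 == pytest.approx(coef[1], abs=1e-8)

    def test_flat_data_gives_near_zero_slope(self):
        trials = make_trials(LEVELS_AV, [8] * 7, [16] * 7)
        fit = sj.fit_side(trials, "AV")
        assert abs(fit.b1) < 1e-4
        with pytest.raises(NoCrossingError):
            sj.crossing_ms(fit)

    def test_separation_penalized_finite(self):
        trials = make_trials(LEVELS_AV, [16] * 7, [16] * 7)  # all synchronous
        fit = sj.fit_side(trials, "AV")
        assert fit.penalized
        assert np.isfinite(fit.b0) and np.isfinite(fit.b1)

    def test_expected_slope_signs(self, simulated_session):
        trials, _ = simulated_session
        assert sj.fit_side(trials, "AV").b1 > 0
        assert sj.fit_side(trials, "VA").b1 < 0

    def test_too_few_levels(self):
        trials = make_trials([-100], [8], [16])
        with pytest.raises(InsufficientDataError):
            sj.fit_side(trials, "AV")


class TestCrossing:
    def test_closed_forms(self):
        mk = lambda b0, b1, side: sj.SigmoidFit(side, b0, b1, 112, 7, True, False)
        assert sj.crossing_ms(mk(0.0, 0.01, "AV")) == 0.0
        assert sj.crossing_ms(mk(2.0, -0.01, "VA")) == pytest.approx(200.0)
        assert sj.crossing_ms(mk(4.8152, 0.02, "AV")) == pytest.approx(240.76)

    def test_agrees_with_bisection_root(self, simulated_session):
        trials, _ = simulated_session
        for side in ("AV", "VA"):
            fit = sj.fit_side(trials, side)
            root = brentq(lambda s: fit.predict(s) - 0.5, -2000, 2000, xtol=1e-9)
            assert sj.crossing_ms(fit) == pytest.approx(abs(root), abs=1e-6)


class TestEstimateTBW:
    def test_width_and_asymmetry_are_exact_sums(self, simulated_session):
        trials, _ = simulated_session
        res = sj.estimate_tbw(trials)
        assert res.width_ms == res.av_side_ms + res.va_side_ms
        assert res.asymmetry_ms == res.av_side_ms - res.va_side_ms

    def test_group_mean_sides_sum_to_group_width(self):
        # side means 240.76 and 119.53 give width 360.29 and asymmetry 121.23
        r = sj.TBWResults(
            av_fit=sj.SigmoidFit("AV", 4.8152, 0.02, 112, 7, True, False),
            va_fit=sj.SigmoidFit("VA", 2.3906, -0.02, 112, 7, True, False),
            av_side_ms=240.76,
            va_side_ms=119.53,
            peak_amplitude=0.98,
        )
        assert r.width_ms == pytest.approx(360.29)
        assert r.asymmetry_ms == pytest.approx(121.23)

    def test_symmetric_observer_small_asymmetry(self):
        params = sj.ObserverParams(200.0, 200.0, 0.02, 0.02)
        design = sj.build_design(
            sj.DesignSpec(conditions=("active",), blocks_per_condition=60)
        )
        trials = sj.simulate_session(design, params, 0, np.random.default_rng(3))
        res = sj.estimate_tbw(trials)
        assert res.asymmetry_ms == pytest.approx(0.0, abs=25.0)

    def test_peak_is_fitted_maximum_at_zero(self, simulated_session):
        trials, _ = simulated_session
        res = sj.estimate_tbw(trials)
        assert res.peak_amplitude == pytest.approx(
            max(res.av_fit.predict(0.0), res.va_fit.predict(0.0))
        )
        assert 0.0 <= res.peak_amplitude <= 1.0

    def test_observed_peak_definition(self, simulated_session):
        trials, _ = simulated_session
        res = sj.estimate_tbw(trials, peak_definition="observed")
        assert res.peak_amplitude == sj.compute_rates(trials)["rate"].max()

    def test_mirror_swaps_sides_exactly(self, simulated_session):
        """Negating all SOAs swaps AV and VA estimates and flips asymmetry."""
        trials, _ = simulated_session
        mirrored = trials.copy()
        mirrored["soa_ms"] = -mirrored["soa_ms"]
        mirrored[["audio_delay_ms", "video_delay_ms"]] = mirrored[
            ["video_delay_ms", "audio_delay_ms"]
        ].to_numpy()
        a = sj.estimate_tbw(trials)
        b = sj.estimate_tbw(mirrored)
        assert b.av_side_ms == pytest.approx(a.va_side_ms, abs=1e-9)
        assert b.va_side_ms == pytest.approx(a.av_side_ms, abs=1e-9)
        assert b.asymmetry_ms == pytest.approx(-a.asymmetry_ms, abs=1e-9)

    def test_added_far_synchrony_never_narrows_the_side(self):
        """Extra synchronous evidence beyond the crossing widens or keeps it."""
        base = make_trials(LEVELS_AV, [2, 3, 5, 8, 10, 13, 15], [16] * 7)
        res0 = sj.fit_side(base, "AV")
        c0 = sj.crossing_ms(res0)
        extra = make_trials([-400], [8], [8])
        extra["trial"] += 1000
        res1 = sj.fit_side(pd.concat([base, extra], ignore_index=True), "AV")
        assert sj.crossing_ms(res1) >= c0

    def test_flags_extrapolated_crossing(self):
        # rates stay above 50% across the grid: the crossing extrapolates
        trials = make_trials(LEVELS_AV, [9, 10, 10, 11, 11, 12, 12], [16] * 7)
        trials_va = make_trials(LEVELS_VA, [12, 12, 11, 11, 10, 10, 9], [16] * 7)
        both = pd.concat([trials, trials_va], ignore_index=True)
        res = sj.estimate_tbw(both)
        assert res.av_side_ms > 400
        assert "av_extrapolated" in res.flags


class TestModelInterface:
    def test_from_dataframe_selects_unit(self):
        pop = sj.PopulationSpec(n_participants=2, n_rejection_participants=0)
        trials, _ = sj.simulate_cohort(pop, seed=8)
        model = sj.SimultaneityJudgment.from_dataframe(trials, "p02", "passive")
        assert model.participant == "p02" and model.condition == "passive"
        res = model.fit()
        assert res.participant == "p02"
        assert "Temporal binding window" in res.summary()

    def test_mixed_units_rejected(self):
        pop = sj.PopulationSpec(n_participants=2, n_rejection_participants=0)
        trials, _ = sj.simulate_cohort(pop, seed=8)
        with pytest.raises(sj.ValidationError):
            sj.SimultaneityJudgment(trials)


class TestGroup:
    def test_two_point_mean_sd(self):
        est = pd.DataFrame(
            {
                "participant": ["a", "b"],
                "condition": "active",
                "av_ms": [200.0, 250.0],
                "va_ms": [100.0, 150.0],
                "width_ms": [300.0, 400.0],
                "asymmetry_ms": [100.0, 100.0],
                "peak": [0.9, 1.0],
                "flags": "",
            }
        )
        g = sj.group_tbw(est)
        assert g.loc[0, "width_ms_mean"] == 350.0
        assert g.loc[0, "width_ms_sd"] == pytest.approx(70.71, abs=0.01)

    def test_degenerate_sd_zero(self):
        est = pd.DataFrame(
            {
                "participant": ["a", "b", "c"],
                "condition": "x",
                "av_ms": 200.0,
                "va_ms": 100.0,
                "width_ms": 300.0,
                "asymmetry_ms": 100.0,
                "peak": 0.95,
                "flags": "",
            }
        )
        sds = sj.group_tbw(est).filter(like="_sd").to_numpy()
        np.testing.assert_allclose(sds, 0.0, atol=1e-12)

    def test_single_estimate_errors(self):
        est = pd.DataFrame(
            {
                "participant": ["a"],
                "condition": "x",
                "av_ms": 200.0,
                "va_ms": 100.0,
                "width_ms": 300.0,
                "asymmetry_ms": 100.0,
                "peak": 0.95,
                "flags": "",
            }
        )
        with pytest.raises(InsufficientDataError):
            sj.group_tbw(est)

    def test_fit_cohort_reports_failures(self):
        pop = sj.PopulationSpec(n_participants=2, n_rejection_participants=0)
        trials, _ = sj.simulate_cohort(pop, seed=8)
        # flatten one unit to exactly 50% at every SOA: slopes collapse to 0
        unit = (trials.participant == "p01") & (trials.condition == "active")
        flat = trials.loc[unit].groupby("soa_ms").cumcount() % 2
        trials.loc[unit, "response"] = pd.array(flat, dtype="Int64")
        est, failures = sj.fit_cohort(trials)
        assert len(est) == 3
        assert failures and failures[0]["participant"] == "p01"
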