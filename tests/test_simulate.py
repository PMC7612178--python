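"""Event-time draws, cohort generators, regimes, and censoring overlay."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import msmsim as ms


class TestEventTimeDraws:
    def test_constant_hazard_closed_form(self):
        assert ms.draw_event_time_constant(0.7, 1.0, 0.5) == pytest.approx(
            -math.log(0.5) / 0.7
        )
        # event occurs since 0.99 < 1
        assert ms.draw_event_time_constant(0.7, 1.0, 0.5) < 1.0

    def test_exact_half_interval(self):
        assert ms.draw_event_time_constant(0.7, 1.0, math.exp(-0.35)) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_negative_hazard_floored_to_no_event(self):
        assert ms.draw_event_time_constant(-0.05, 1.0, 0.42) == math.inf

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.3, 1.7])
    def test_uniform_draw_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            ms.draw_event_time_constant(0.5, 1.0, bad)
        with pytest.raises(ValueError):
            ms.draw_event_time_piecewise([0.0, 1.0], [0.5], bad)

    @given(st.floats(1e-6, 1 - 1e-6), st.floats(0.05, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_piecewise_single_step_reduces_to_constant(self, v, lam):
        const = ms.draw_event_time_constant(lam, 1.0, v)
        pw = ms.draw_event_time_piecewise([0.0, 1.0], [lam], v)
        if const >= 1.0:
            assert pw == math.inf or pw >= 1.0
        else:
            assert pw == pytest.approx(const)

    def test_piecewise_inverts_cumulative_hazard(self):
        # Lambda(0.5) = 0.25, remaining 0.25 at rate 1 -> t = 0.75
        t = ms.draw_event_time_piecewise([0.0, 0.5, 1.0], [0.5, 1.0], math.exp(-0.5))
        assert t == pytest.approx(0.75, abs=1e-12)

    def test_piecewise_survivor_function_matches_closed_form(self):
        bounds = np.array([0.0, 0.4, 1.0])
        rates = np.array([0.5, 1.5])
        rng = np.random.default_rng(5)
        n = 100_000
        draws = ms.simulate._draw_piecewise(bounds, np.tile(rates, (n, 1)), rng.random(n))
        for t in (0.2, 0.4, 0.7, 0.99):
            lam = 0.5 * min(t, 0.4) + 1.5 * max(t - 0.4, 0.0)
            p = math.exp(-lam)
            se = math.sqrt(p * (1 - p) / n)
            assert np.mean(draws > t) == pytest.approx(p, abs=3 * se)


class TestObservationalSimulator:
    def test_bit_reproducible_given_seed(self):
        a = ms.simulate_observational(500, seed=42)
        b = ms.simulate_observational(500, seed=42)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(
            np.nan_to_num(a.T, nan=-1), np.nan_to_num(b.T, nan=-1)
        )
        np.testing.assert_array_equal(a.L[a.atrisk], b.L[b.atrisk])

    def test_output_independent_of_frailty_when_decoupled(self):
        """With no U effect on hazard or L, swapping the U stream changes nothing else."""
        hazard = ms.ConditionalHazardSpec(frailty=0.0)
        cov = ms.CovariateProcessSpec(l0_u_coef=0.0, theta_u=0.0)
        a = ms.simulate_observational(2000, hazard=hazard, covariates=cov, seed=7,
                                      stream_seeds={"frailty": 1})
        b = ms.simulate_observational(2000, hazard=hazard, covariates=cov, seed=7,
                                      stream_seeds={"frailty": 2})
        assert not np.array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.atrisk, b.atrisk)
        np.testing.assert_array_equal(
            np.nan_to_num(a.T, nan=-1), np.nan_to_num(b.T, nan=-1)
        )

    def test_baseline_treatment_prevalence_matches_logistic_normal_integral(self):
        from scipy.integrate import quad
        from scipy.special import expit
        from scipy.stats import norm

        # E[expit(-2 + 0.5 L0)] with L0 ~ N(0, 1 + 0.1^2)
        target = quad(
            lambda x: expit(-2 + 0.5 * x) * norm.pdf(x, scale=np.sqrt(1.01)), -12, 12
        )[0]
        n = 200_000
        panel = ms.simulate_observational(n, seed=21)
        se = np.sqrt(target * (1 - target) / n)
        assert panel.A[:, 0].mean() == pytest.approx(target, abs=3 * se)

    def test_defaults_reproduce_printed_generator(self):
        h = ms.ConditionalHazardSpec()
        assert h.baseline(0.3) == 0.7
        assert h.treatment[0](0.3) == -0.2
        assert h.confounder[0](0.3) == 0.05
        assert h.frailty(0.3) == 0.05
        t = ms.TreatmentAssignmentSpec()
        assert (t.gamma0, t.gammaL, t.gammaA) == (-2.0, 0.5, 1.0)
        c = ms.CovariateProcessSpec()
        assert (c.rho, c.theta_a, c.theta_k, c.theta_u) == (0.8, -1.0, 0.1, 1.0)
        assert (c.u_sd, c.l0_sd, c.l_sd) == (0.1, 1.0, 1.0)

    def test_interval_survival_matches_conditional_hazard(self):
        """P(event in [0,1) | A0, L0, U) = 1 - exp(-hazard), per person."""
        panel = ms.simulate_observational(100_000, seed=22)
        lam = np.maximum(
            0.7 - 0.2 * panel.A[:, 0] + 0.05 * panel.L[:, 0] + 0.05 * panel.U, 0.0
        )
        p = 1.0 - np.exp(-lam)
        died = panel.event & (panel.T < 1.0)
        se = np.sqrt(np.mean(p * (1 - p)) / panel.n)
        assert died.mean() == pytest.approx(p.mean(), abs=3 * se)


class TestRegimes:
    def test_all_regimes_enumerates_32(self):
        regs = ms.all_regimes(4)
        assert len(regs) == 32
        assert len({r.label for r in regs}) == 32

    def test_never_treated_output_has_no_treatment(self):
        panel = ms.simulate_under_regimes([ms.never_treated(4)], 500, seed=3)
        assert panel.A[panel.atrisk].sum() == 0

    def test_duplicate_regimes_warn(self):
        with pytest.warns(UserWarning, match="duplicate"):
            ms.simulate_under_regimes([ms.never_treated(4)] * 2, 50, seed=3)

    def test_baseline_shared_across_regimes(self):
        panel = ms.simulate_under_regimes(
            [ms.never_treated(4), ms.always_treated(4)], 400, seed=4
        )
        never = panel.regime == "00000"
        np.testing.assert_array_equal(panel.U[never], panel.U[~never])
        np.testing.assert_allclose(panel.L[never, 0], panel.L[~never, 0])

    def test_never_treated_survival_proportion_at_one(self):
        m = 100_000
        panel = ms.simulate_under_regimes([ms.never_treated(4)], m, seed=5)
        surv = ~(panel.event & (panel.T <= 1.0))
        # exact lognormal value for the default generator is 0.4973
        assert surv.mean() == pytest.approx(0.497, abs=3 * np.sqrt(0.25 / m) + 5e-4)


class TestConditionalCoxSimulator:
    def test_no_confounding_limit_marginal_survival(self):
        hazard = ms.ConditionalHazardSpec(family="cox", baseline=0.7,
                                          treatment=(-0.3,), confounder=(0.0,),
                                          frailty=0.0)
        panel = ms.simulate_conditional_cox(50_000, hazard=hazard, seed=6)
        for a in (0, 1):
            sel = panel.A[:, 0] == a
            p = math.exp(-0.7 * math.exp(-0.3 * a))
            surv = ~(panel.event[sel] & (panel.T[sel] <= 1.0))
            se = math.sqrt(p * (1 - p) / sel.sum())
            assert surv.mean() == pytest.approx(p, abs=3 * se)

    def test_conditional_hazard_matches_exponential_rate(self):
        """Interval-0 event probability equals 1 - exp(-lam0 e^eta) path by path."""
        panel = ms.simulate_conditional_cox(100_000, seed=7)
        eta = -0.3 * panel.A[:, 0] + 0.1 * panel.L[:, 0] + 0.1 * panel.U
        p = 1.0 - np.exp(-0.7 * np.exp(eta))
        died = panel.event & (panel.T < 1.0)
        se = np.sqrt(np.mean(p * (1 - p)) / panel.n)
        assert died.mean() == pytest.approx(p.mean(), abs=3 * se)

    def test_family_mismatch_rejected(self):
        with pytest.raises(ms.ConfigurationError):
            ms.simulate_conditional_cox(10, hazard=ms.ConditionalHazardSpec(), seed=1)
        with pytest.raises(ms.ConfigurationError):
            ms.simulate_observational(
                10, hazard=ms.ConditionalHazardSpec.cox_illustration(), seed=1
            )


class TestRandomCensoring:
    def test_zero_hazard_leaves_panel_unchanged(self):
        panel = ms.simulate_observational(500, seed=8)
        out = ms.apply_random_censoring(panel, 0.0, seed=9)
        np.testing.assert_array_equal(out.C, panel.C)
        np.testing.assert_array_equal(out.event, panel.event)

    def test_constant_hazard_gives_exponential_censoring(self):
        # with no events, censoring times are Exp(c) truncated at K+1
        hazard = ms.ConditionalHazardSpec(baseline=0.0, treatment=(0.0,),
                                          confounder=(0.0,), frailty=0.0)
        panel = ms.simulate_observational(50_000, hazard=hazard, seed=10)
        c = 0.3
        out = ms.apply_random_censoring(panel, c, seed=11)
        for t in (0.5, 1.5, 3.0):
            p = math.exp(-c * t)
            se = math.sqrt(p * (1 - p) / panel.n)
            assert np.mean(out.C > t) == pytest.approx(p, abs=3 * se)

    def test_censoring_times_strictly_positive(self):
        panel = ms.simulate_observational(2000, seed=12)
        out = ms.apply_random_censoring(panel, 5.0, seed=13)
        assert np.all(out.C > 0)


def test_config_round_trip(tmp_path):
    cfg = tmp_path / "c.yaml"
    cfg.write_text(
        "n: 123\nK: 4\nhazard:\n  alpha0: 0.7\n  alphaA: [-0.2]\n"
        "covariates:\n  rho: 0.8\ntreatment:\n  gammaL: 0.5\n"
    )
    s = ms.specs_from_config(ms.load_config(cfg))
    assert s["n"] == 123
    assert s["hazard"].baseline(0.5) == 0.7
    assert s["covariates"].rho == 0.8
    assert s["treatment"].gammaL == 0.5
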