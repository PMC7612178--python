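"""Weighted Aalen least-squares fitting and the survival transform."""

import numpy as np
import pytest

import msmsim as ms
from msmsim.trajectories import CountingProcessData


def _toy_counting_process(design_rows, stops, events, weights, form="current", K=4):
    design = ms.MSMDesign(form, K=K)
    X = np.asarray(design_rows, dtype=float)
    return CountingProcessData(
        ids=np.arange(len(stops)),
        tstart=np.zeros(len(stops)),
        tstop=np.asarray(stops, dtype=float),
        event=np.asarray(events, dtype=bool),
        design=X,
        weight=np.asarray(weights, dtype=float),
        msm_design=design,
        K=K,
    )


def _brute_force_aalen(X, stops, events, weights):
    """Dense per-event-time evaluation of (X'WX)^-1 X'W dN, cumulated."""
    times = np.unique(stops[events])
    out = np.zeros((len(times), X.shape[1]))
    cum = np.zeros(X.shape[1])
    for i, t in enumerate(times):
        at_risk = stops >= t
        Xr = X[at_risk]
        W = np.diag(weights[at_risk])
        dN = (events & (stops == t))[at_risk].astype(float)
        cum = cum + np.linalg.solve(Xr.T @ W @ Xr, Xr.T @ W @ dN)
        out[i] = cum
    return times, out


class TestMSMDesign:
    def test_cox_form_fails_loudly(self):
        with pytest.raises(NotImplementedError):
            ms.MSMDesign("cox", K=4)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            ms.MSMDesign("splines", K=4)

    def test_history_dimension_grows_with_interval(self):
        d = ms.MSMDesign("history", K=4)
        assert d.ncols == 6
        assert list(d.active_columns(0)) == [0, 1]
        assert list(d.active_columns(3)) == [0, 1, 2, 3, 4]

    def test_regime_rows_apply_lag_mapping(self):
        d = ms.MSMDesign("history", K=4)
        rows = d.regime_rows(ms.TreatmentRegime((1, 0, 1, 0, 0)))
        # interval 2: (1, a2, a1, a0, 0, 0) = (1, 1, 0, 1, 0, 0)
        np.testing.assert_allclose(rows[2], [1, 1, 0, 1, 0, 0])

    def test_duration_design(self):
        d = ms.MSMDesign("duration", K=4)
        A = np.array([[1, 1, 0, 1, 0]])
        assert d.matrix_at(A, 3)[0, 1] == 3


class TestAalenFit:
    def test_intercept_only_reduces_to_nelson_aalen(self):
        """Unit-weight intercept fit equals the Nelson-Aalen estimator (lifelines)."""
        from lifelines import NelsonAalenFitter

        panel = ms.simulate_observational(2000, seed=41)
        cpd = ms.expand_to_counting_process(panel, ms.MSMDesign("intercept", K=4))
        cc = ms.fit_weighted_aalen(cpd)
        fu = panel.followup()
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(fu, event_observed=panel.event)
        ours = cc.at(cc.times)[:, 0]
        theirs = naf.cumulative_hazard_at_times(cc.times).to_numpy()
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)

    def test_two_group_fit_equals_groupwise_nelson_aalen(self):
        rng = np.random.default_rng(42)
        n = 400
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.5 + 0.4 * x))
        stops = np.minimum(t, 1.0 - 1e-9)
        events = t < 1.0
        X = np.column_stack([np.ones(n), x])
        cpd = _toy_counting_process(X, stops, events, np.ones(n), form="current", K=0)
        cc = ms.fit_weighted_aalen(cpd)

        def na(group):
            ts = np.sort(stops[events & (x == group)])
            return ts, np.cumsum(
                [1.0 / np.sum(stops[x == group] >= s) for s in ts]
            )

        t0, na0 = na(0)
        np.testing.assert_allclose(cc.at(t0)[:, 0], na0, rtol=1e-8)
        t1, na1 = na(1)
        np.testing.assert_allclose(cc.at(t1)[:, 0] + cc.at(t1)[:, 1], na1, rtol=1e-8)

    def test_weighted_toy_matches_brute_force_matrix_oracle(self):
        X = np.array([[1, 0], [1, 1], [1, 1], [1, 0], [1, 1]], dtype=float)
        stops = np.array([0.2, 0.35, 0.5, 0.95, 0.9])
        events = np.array([True, True, False, False, True])
        weights = np.array([0.5, 2.0, 1.5, 0.8, 1.2])
        cpd = _toy_counting_process(X, stops, events, weights, form="current", K=0)
        cc = ms.fit_weighted_aalen(cpd)
        times, expected = _brute_force_aalen(X, stops, events, weights)
        np.testing.assert_allclose(cc.times, times)
        np.testing.assert_allclose(cc.values, expected, rtol=1e-10)

    def test_weighted_cohort_fit_matches_brute_force(self, default_cohort, default_weights):
        sub = 400  # brute force is O(events * n); keep it small
        panel = ms.CohortPanel(
            ids=default_cohort.ids[:sub], A=default_cohort.A[:sub],
            L=default_cohort.L[:sub], atrisk=default_cohort.atrisk[:sub],
            U=None, T=default_cohort.T[:sub], event=default_cohort.event[:sub],
            C=default_cohort.C[:sub],
        )
        cpd = ms.expand_to_counting_process(
            panel, ms.MSMDesign("current", K=4), weights=default_weights.sw[:sub]
        )
        cc = ms.fit_weighted_aalen(cpd)
        # brute force within each interval, pooled: risk set tstart < t <= tstop
        times = np.sort(cpd.tstop[cpd.event])
        cum = np.zeros(2)
        for t in times:
            at = (cpd.tstart < t) & (t <= cpd.tstop)
            Xr = cpd.design[at]
            W = np.diag(cpd.weight[at])
            dN = (cpd.event & (cpd.tstop == t))[at].astype(float)
            cum = cum + np.linalg.solve(Xr.T @ W @ Xr, Xr.T @ W @ dN)
        np.testing.assert_allclose(cc.values[-1], cum, rtol=1e-8)

    def test_singular_design_strict_mode_raises(self):
        X = np.array([[1, 1], [1, 1], [1, 1]], dtype=float)  # no variation in x
        stops = np.array([0.3, 0.6, 0.9])
        events = np.array([True, True, False])
        cpd = _toy_counting_process(X, stops, events, np.ones(3), form="current", K=0)
        with pytest.raises(ms.SingularDesignError):
            ms.fit_weighted_aalen(cpd, strict_singular=True)
        cc = ms.fit_weighted_aalen(cpd)  # default: pseudo-inverse, no error
        assert np.all(np.isfinite(cc.values))


class TestCumulativeCoefficients:
    @pytest.fixture()
    def fitted(self, default_cohort):
        cpd = ms.expand_to_counting_process(default_cohort, ms.MSMDesign("history", K=4))
        return ms.fit_weighted_aalen(cpd)

    def test_zero_at_time_zero(self, fitted):
        assert np.all(fitted.at([0.0]) == 0.0)

    def test_step_function_is_right_continuous(self, fitted):
        t = fitted.times[10]
        mid = 0.5 * (t + fitted.times[11])
        np.testing.assert_allclose(fitted.at([mid])[0], fitted.values[10])

    def test_lag_columns_zero_before_activation(self, fitted):
        vals = fitted.at([1.0, 2.0, 3.0, 4.0, 5.0])
        for j in range(1, 5):
            col = 1 + j
            assert np.all(vals[:j, col] == 0.0)
            assert vals[j, col] != 0.0

    def test_out_of_range_time_rejected(self, fitted):
        with pytest.raises(ValueError):
            fitted.at([5.5])
        with pytest.raises(ValueError):
            ms.survival_from_cumcoef(fitted, ms.never_treated(4), [6.0])

    def test_grid_equals_resummed_increments(self, fitted):
        resum = np.cumsum(fitted.increments(), axis=0)
        np.testing.assert_allclose(resum, fitted.values, rtol=1e-9, atol=1e-12)


class TestSurvivalTransform:
    def _table_like_cc(self):
        """Cumulative coefficients at integer times matching published-style values."""
        design = ms.MSMDesign("history", K=4)
        values = np.zeros((5, 6))
        values[:, 0] = [0.700, 1.408, 2.128, 2.863, 3.623]
        values[:, 1] = [-0.198, -0.396, -0.594, -0.790, -0.987]
        values[1:, 2] = [-0.098, -0.195, -0.291, -0.386]
        values[2:, 3] = [-0.077, -0.153, -0.228]
        values[3:, 4] = [-0.060, -0.121]
        values[4:, 5] = [-0.047]
        return ms.CumulativeCoefficients(
            times=np.arange(1.0, 6.0), values=values, design=design, K=4
        )

    def test_all_zero_coefficients_give_unit_survival(self):
        cc = ms.CumulativeCoefficients(
            times=np.arange(1.0, 6.0), values=np.zeros((5, 6)),
            design=ms.MSMDesign("history", K=4), K=4,
        )
        np.testing.assert_allclose(
            ms.survival_from_cumcoef(cc, ms.always_treated(4), [1, 3, 5]), 1.0
        )

    def test_always_treated_survival_from_cumulative_values(self):
        cc = self._table_like_cc()
        s5 = ms.survival_from_cumcoef(cc, ms.always_treated(4), [5.0])[0]
        expected = np.exp(-(3.623 - (0.987 + 0.386 + 0.228 + 0.121 + 0.047)))
        assert s5 == pytest.approx(expected, abs=1e-12)
        assert s5 == pytest.approx(0.157, abs=5e-4)

    def test_never_treated_survival_from_cumulative_values(self):
        cc = self._table_like_cc()
        s5 = ms.survival_from_cumcoef(cc, ms.never_treated(4), [5.0])[0]
        assert s5 == pytest.approx(np.exp(-3.623), abs=1e-12)
        assert s5 == pytest.approx(0.027, abs=5e-4)

    def test_survival_can_exceed_one_unless_clamped(self):
        design = ms.MSMDesign("history", K=4)
        values = np.zeros((1, 6))
        values[0, 0] = -0.1  # negative cumulative hazard from an additive fit
        cc = ms.CumulativeCoefficients(times=np.array([1.0]), values=values,
                                       design=design, K=4)
        assert ms.survival_from_cumcoef(cc, ms.never_treated(4), [1.0])[0] > 1.0
        assert ms.survival_from_cumcoef(cc, ms.never_treated(4), [1.0], clamp=True)[0] == 1.0


class TestUnconfoundedRecovery:
    def test_unweighted_fit_recovers_conditional_coefficients(self, unconfounded_specs):
        """Without confounding the lag-0 cumulative slope is alpha_A and lags vanish."""
        hazard, treatment = unconfounded_specs
        panel = ms.simulate_observational(30_000, hazard=hazard, treatment=treatment,
                                          seed=43)
        cpd = ms.expand_to_counting_process(panel, ms.MSMDesign("history", K=4))
        cc = ms.fit_weighted_aalen(cpd)
        vals = cc.at([1.0, 2.0])
        assert vals[0, 1] == pytest.approx(-0.2, abs=0.04)
        assert vals[1, 1] == pytest.approx(-0.4, abs=0.06)
        assert vals[1, 2] == pytest.approx(0.0, abs=0.06)

    def test_fit_survival_agrees_with_kaplan_meier_subgroup(self, unconfounded_specs):
        hazard, treatment = unconfounded_specs
        panel = ms.simulate_observational(30_000, hazard=hazard, treatment=treatment,
                                          seed=44)
        cpd = ms.expand_to_counting_process(panel, ms.MSMDesign("history", K=4))
        cc = ms.fit_weighted_aalen(cpd)
        s1 = ms.survival_from_cumcoef(cc, ms.never_treated(4), [1.0])[0]
        never0 = panel.A[:, 0] == 0
        km = np.mean(~(panel.event[never0] & (panel.T[never0] <= 1.0)))
        se = np.sqrt(km * (1 - km) / never0.sum())
        assert s1 == pytest.approx(km, abs=4 * se)
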