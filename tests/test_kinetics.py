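"""Piecewise kinetic model: closed forms, fitting, MAP refit, population
summaries.  Closed-form curves are checked against direct numerical
integration of the phase ODEs; the MAP refit against a brute-force grid."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from lumiquant import (
    DynamicParams,
    FitResult,
    PriorSpec,
    RadianceSeries,
    apply_refits,
    bayesian_refit,
    classify_growth_speed,
    compare_growth_relapse,
    compute_priors,
    decay_curve,
    fit_trajectory,
    growth_curve,
    killing_rate,
    piecewise_predict,
    relapse_curve,
    residual_summary,
    segment_phases,
)
from lumiquant.kinetics import cohort_killing_rates, needs_refit


def _ode_piecewise(params: DynamicParams, label: str, t_eval):
    """Independent oracle: integrate the phase ODEs segment by segment.

    Growth/relapse: dT/dt = k T (1 - T/T_inf); decay: dT/dt = -kD (T - TB).
    """
    t_eval = np.asarray(t_eval, dtype=float)
    spans = []
    if label in ("G", "GD", "GDR"):
        t0, y0 = 0.0, params.T0
        t_end = params.t_decay if label != "G" else t_eval[-1]
        spans.append(("logistic", params.k_growth, t0, t_end, y0))
    else:
        t_end = params.t_decay
    if label in ("GD", "GDR", "D", "DR"):
        t0 = params.t_decay
        t_stop = params.t_relapse if label in ("GDR", "DR") else t_eval[-1]
        spans.append(("decay", params.k_decay, t0, t_stop, None))
    if label in ("GDR", "DR"):
        spans.append(("logistic", params.k_relapse, params.t_relapse,
                      t_eval[-1], None))

    out = np.empty_like(t_eval)
    y0 = params.T0
    for kind, k, t0, t1, y_start in spans:
        if y_start is not None:
            y0 = y_start
        if kind == "logistic":
            rhs = lambda t, y: k * y[0] * (1 - y[0] / params.T_inf)  # noqa: E731
        else:
            rhs = lambda t, y: -k * (y[0] - params.T_B)  # noqa: E731
        pts = t_eval[(t_eval >= t0 - 1e-12) & (t_eval <= t1 + 1e-12)]
        sol = solve_ivp(
            rhs, (t0, max(t1, t0 + 1e-9)), [y0],
            t_eval=np.unique(np.concatenate([pts, [t1]])),
            rtol=1e-11, atol=1e-4, dense_output=True, method="LSODA",
        )
        for t in pts:
            out[np.argmin(np.abs(t_eval - t))] = sol.sol(t)[0]
        y0 = sol.sol(t1)[0]
    return out


def _random_gdr_params(rng) -> DynamicParams:
    T0 = 10 ** rng.uniform(4, 6)
    T_inf = 10 ** rng.uniform(8.5, 10)
    return DynamicParams(
        T0=T0,
        k_growth=rng.uniform(0.1, 2.0),
        t_decay=rng.uniform(3, 12),
        k_decay=rng.uniform(0.1, 2.0),
        T_B=10 ** rng.uniform(3.2, 4.5),
        t_relapse=rng.uniform(13, 25),
        k_relapse=rng.uniform(0.1, 2.0),
        T_inf=T_inf,
    )


class TestPhaseCurves:
    def test_growth_starts_at_t0(self):
        assert growth_curve(0.0, 1e5, 0.5, 1e9) == pytest.approx(1e5)

    def test_growth_reduces_to_exponential_for_large_capacity(self):
        got = growth_curve(5.0, 1e5, 0.5, 1e15)
        assert got == pytest.approx(1e5 * np.exp(2.5), rel=1e-6)

    def test_growth_monotone_and_bounded(self):
        t = np.linspace(0, 40, 200)
        y = growth_curve(t, 1e5, 0.8, 1e9)
        assert np.all(np.diff(y) >= 0)
        assert y.max() <= 1e9 * (1 + 1e-12)

    def test_growth_against_ode_oracle(self):
        p = DynamicParams(T0=1e5, k_growth=0.5, T_inf=1e9)
        rhs = lambda t, y: 0.5 * y[0] * (1 - y[0] / 1e9)  # noqa: E731
        sol = solve_ivp(rhs, (0, 5), [1e5], rtol=1e-11, atol=1e-6,
                        dense_output=True)
        assert growth_curve(5.0, p.T0, p.k_growth, p.T_inf) == pytest.approx(
            sol.sol(5.0)[0], rel=1e-6
        )

    def test_decay_continuous_with_growth_at_junction(self):
        p = DynamicParams(T0=1e5, k_growth=0.7, t_decay=7.0, k_decay=0.4,
                          T_B=5e3, T_inf=1e9)
        g = growth_curve(7.0, p.T0, p.k_growth, p.T_inf)
        assert decay_curve(7.0, p) == pytest.approx(g, rel=1e-12)

    def test_decay_with_zero_rate_is_constant(self):
        p = DynamicParams(T0=1e5, k_growth=0.7, t_decay=7.0, k_decay=0.0,
                          T_B=5e3, T_inf=1e9)
        g = growth_curve(7.0, p.T0, p.k_growth, p.T_inf)
        assert decay_curve(30.0, p) == pytest.approx(g)

    def test_decay_asymptote_is_baseline(self):
        p = DynamicParams(T0=1e5, k_growth=0.7, t_decay=7.0, k_decay=0.6,
                          T_B=5e3, T_inf=1e9)
        assert decay_curve(1e4, p) == pytest.approx(5e3, rel=1e-9)

    def test_relapse_continuous_with_decay_at_junction(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = _random_gdr_params(rng)
            assert relapse_curve(p.t_relapse, p) == pytest.approx(
                decay_curve(p.t_relapse, p), rel=1e-12
            )

    def test_relapse_reduces_to_exponential_for_large_capacity(self):
        p = DynamicParams(T0=1e5, k_growth=0.7, t_decay=7.0, k_decay=0.6,
                          T_B=5e3, t_relapse=14.0, k_relapse=0.5, T_inf=1e15)
        t1r = p.T1_relapse
        got = relapse_curve(20.0, p)
        assert got == pytest.approx(t1r * np.exp(0.5 * 6.0), rel=1e-6)

    def test_closed_forms_match_ode_on_random_parameters(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            p = _random_gdr_params(rng)
            t = np.linspace(0, 30, 13)
            closed = piecewise_predict(t, p, "GDR")
            ode = _ode_piecewise(p, "GDR", t)
            assert np.max(np.abs(closed - ode) / ode) < 1e-6

    def test_dr_composite_against_ode(self):
        p = DynamicParams(T0=8e5, t_decay=0.0, k_decay=0.5, T_B=4e3,
                          t_relapse=14.0, k_relapse=0.6, T_inf=2e9)
        t = np.linspace(0, 30, 11)
        closed = piecewise_predict(t, p, "DR")
        ode = _ode_piecewise(p, "DR", t)
        assert np.max(np.abs(closed - ode) / ode) < 1e-6


class TestPiecewisePredict:
    def test_label_params_mismatch_rejected(self):
        p = DynamicParams(T0=1e5, k_growth=0.5, T_inf=1e9)
        with pytest.raises(ValueError, match="requires"):
            piecewise_predict([0, 1], p, "GDR")
        with pytest.raises(ValueError, match="unknown"):
            piecewise_predict([0, 1], p, "X")

    def test_junction_continuity_to_1e12(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            p = _random_gdr_params(rng)
            eps = 1e-9
            for tj in (p.t_decay, p.t_relapse):
                lo = piecewise_predict(tj - eps, p, "GDR")
                hi = piecewise_predict(tj + eps, p, "GDR")
                assert abs(hi - lo) / lo < 1e-6  # continuity across the step
                assert piecewise_predict(tj, p, "GDR") == pytest.approx(
                    decay_curve(tj, p) if tj == p.t_relapse
                    else growth_curve(tj, p.T0, p.k_growth, p.T_inf),
                    rel=1e-12,
                )


def _gdr_series(n=10, step=3.5, **over):
    p = DynamicParams(
        T0=over.get("T0", 2e5), k_growth=over.get("k_growth", 0.8),
        t_decay=2 * step, k_decay=over.get("k_decay", 0.5),
        T_B=over.get("T_B", 5e3), t_relapse=5 * step,
        k_relapse=over.get("k_relapse", 0.6), T_inf=over.get("T_inf", 2e9),
    )
    days = np.arange(n) * step
    vals = np.maximum(piecewise_predict(days, p, "GDR"), 1e3)
    return RadianceSeries("m0", days, vals), p


class TestFitTrajectory:
    def test_noise_free_gdr_rates_recovered_within_one_percent(self):
        series, p = _gdr_series()
        seg = segment_phases(series, floor=1e3)
        assert (seg.D_index, seg.R_index) == (2, 6)
        fit = fit_trajectory(series, seg, floor=1e3)
        for name in ("k_growth", "k_decay", "k_relapse"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(p, name), rel=0.01
            )

    def test_two_point_exponential_recovers_log_slope(self):
        days = np.array([0.0, 3.5])
        k_true = 0.6
        vals = 1e5 * np.exp(k_true * days)
        series = RadianceSeries("m0", days, vals)
        fit = fit_trajectory(series, floor=1e3)
        assert fit.label == "G"
        assert fit.params.k_growth == pytest.approx(k_true, rel=0.01)

    def test_fit_is_scale_invariant(self):
        series, _ = _gdr_series()
        f1 = fit_trajectory(series, floor=1e3)
        scaled = RadianceSeries("m0", series.days, series.values * 37.0)
        f2 = fit_trajectory(scaled, floor=1e3 * 37.0)
        for name in ("k_growth", "k_decay", "k_relapse"):
            assert getattr(f2.params, name) == pytest.approx(
                getattr(f1.params, name), rel=1e-5
            )
        for name in ("T0", "T_B", "T_inf"):
            assert getattr(f2.params, name) == pytest.approx(
                getattr(f1.params, name) * 37.0, rel=1e-4
            )

    def test_residual_count_matches_timepoints(self):
        series, _ = _gdr_series()
        fit = fit_trajectory(series, floor=1e3)
        assert len(fit.residuals) == len(series)
        assert np.all(np.abs(fit.residuals) < 0.05)  # noise-free


class TestResidualSummary:
    def test_perfect_fits_are_all_within_a_decade(self):
        series, _ = _gdr_series()
        fit = fit_trajectory(series, floor=1e3)
        out = residual_summary([fit])
        for frac in out["fraction_within_decade"].values():
            assert frac == 1.0

    def test_one_large_residual_among_ten(self):
        series, _ = _gdr_series()
        fit = fit_trajectory(series, floor=1e3)
        res = np.zeros(10)
        res[3] = 1.5
        doctored = dataclasses.replace(
            fit, residuals=res, phase_of_point=np.array(["growth"] * 10)
        )
        out = residual_summary([doctored])
        assert out["fraction_within_decade"]["growth"] == pytest.approx(0.9)


class TestComputePriors:
    def test_constant_after_outlier_removal(self):
        prior = compute_priors([0.5, 0.5, 0.5, 5.0], cutoff=3.0)
        assert prior.mean == pytest.approx(0.5)
        assert prior.sd == pytest.approx(0.0)

    def test_mean_and_sample_sd(self):
        rates = [0.2, 0.4, 0.6, 0.8]
        prior = compute_priors(rates, cutoff=3.0)
        assert prior.mean == pytest.approx(np.mean(rates))
        assert prior.sd == pytest.approx(np.std(rates, ddof=1))

    def test_too_few_survivors_rejected(self):
        with pytest.raises(ValueError):
            compute_priors([0.5, 4.0, 5.0], cutoff=3.0)


def _two_point_growth_fit(k=6.0, dt=1.0):
    days = np.array([0.0, dt, dt + 3.5, dt + 7.0, dt + 10.5])
    vals = np.empty(5)
    vals[:2] = 1e5 * np.exp(k * days[:2])
    # decay afterwards so the growth phase is exactly the first two points
    vals[2:] = vals[1] * np.exp(-0.8 * (days[2:] - days[1]))
    series = RadianceSeries("m0", days, np.maximum(vals, 1e3))
    seg = segment_phases(series, floor=1e3)
    assert seg.D_index == 1
    return fit_trajectory(series, seg, floor=1e3, joint_polish=False)


class TestBayesianRefit:
    PRIOR = PriorSpec(0.84, 0.43, 3.0)

    def test_flat_prior_recovers_unpenalized_rate(self):
        fit = _two_point_growth_fit()
        wide = PriorSpec(0.84, 1e9, 3.0)
        refit = bayesian_refit(fit, wide, which="k_growth")
        assert refit.params.k_growth == pytest.approx(
            fit.params.k_growth, rel=1e-4
        )

    def test_map_lies_between_prior_mean_and_mle(self):
        fit = _two_point_growth_fit(k=6.0)
        k_mle = fit.params.k_growth
        refit = bayesian_refit(fit, self.PRIOR, which="k_growth")
        assert self.PRIOR.mean < refit.params.k_growth < k_mle
        assert refit.refit_flags["k_growth"]

    def test_matches_brute_force_grid(self):
        fit = _two_point_growth_fit(k=2.4)
        noise_sd = 0.15
        t = fit.series.days[:2]
        y = np.log10(fit.series.values[:2])
        p = fit.params
        grid = np.arange(0.0, 6.0, 1e-4)
        obj = [
            np.sum(((np.log10(growth_curve(t, p.T0, k, p.T_inf)) - y)
                    / noise_sd) ** 2)
            + ((k - self.PRIOR.mean) / self.PRIOR.sd) ** 2
            for k in grid
        ]
        k_grid = grid[int(np.argmin(obj))]
        refit = bayesian_refit(fit, self.PRIOR, which="k_growth",
                               noise_sd=noise_sd)
        assert abs(refit.params.k_growth - k_grid) < 1e-3

    def test_shrinkage_monotone_in_prior_sd(self):
        fit = _two_point_growth_fit(k=3.5)
        k_mle = fit.params.k_growth
        rates = [
            bayesian_refit(fit, PriorSpec(0.84, sd, 3.0),
                           which="k_growth").params.k_growth
            for sd in (2.0, 1.0, 0.5, 0.25, 0.1)
        ]
        assert all(np.diff(rates) < 1e-9)  # toward the prior mean
        assert all(self.PRIOR.mean - 1e-9 < r < k_mle for r in rates)

    def test_trigger_rule(self):
        fit = _two_point_growth_fit(k=0.5)  # 2-point phase triggers
        assert needs_refit(fit, "k_growth", self.PRIOR)
        series, _ = _gdr_series()  # 3-point growth, moderate rate: no trigger
        fit2 = fit_trajectory(series, floor=1e3)
        assert not needs_refit(fit2, "k_growth", self.PRIOR)
        with pytest.raises(ValueError):
            needs_refit(fit2, "k_decay", self.PRIOR)

    def test_zero_sd_prior_rejected_at_refit(self):
        fit = _two_point_growth_fit()
        with pytest.raises(ValueError, match="sd > 0"):
            bayesian_refit(fit, PriorSpec(0.5, 0.0, 3.0), which="k_growth")

    def test_apply_refits_only_touches_triggered_rates(self):
        series, _ = _gdr_series()
        fit = fit_trajectory(series, floor=1e3)
        out = apply_refits(fit, {"k_growth": self.PRIOR,
                                 "k_relapse": PriorSpec(0.6, 0.32, 3.0)})
        assert not any(out.refit_flags.values())
        assert out.params.k_growth == fit.params.k_growth


class TestPopulationSummaries:
    def test_killing_rate(self):
        assert killing_rate(1.0, 1.0) == 0.0
        assert killing_rate(0.3, 1.0) == pytest.approx(0.7)
        with pytest.raises(ValueError):
            killing_rate(-0.1, 1.0)

    def test_cohort_killing_rates_require_controls(self):
        df = pd.DataFrame({"k_growth": [0.5, 0.9], "is_control": [False, False]})
        with pytest.raises(ValueError, match="control"):
            cohort_killing_rates(df)
        df2 = pd.DataFrame(
            {"k_growth": [0.5, 0.9, 1.1], "is_control": [False, True, True]}
        )
        out = cohort_killing_rates(df2)
        assert out["killing_rate"].iloc[0] == pytest.approx(1.0 - 0.5)

    @pytest.mark.parametrize(
        "k,expected", [(0.85, "slow"), (0.86, "fast"), (0.0, "slow")]
    )
    def test_growth_speed_boundary(self, k, expected):
        assert classify_growth_speed(k) == expected

    def test_compare_growth_relapse_all_slower(self):
        fits = []
        # relapse rates kept above ln(3)/3.5 so the 3-fold rule fires
        for kg, kr in [(0.9, 0.5), (1.2, 0.7), (0.8, 0.4)]:
            series, _ = _gdr_series(k_growth=kg, k_relapse=kr)
            fits.append(fit_trajectory(series, floor=1e3))
        frac, pairs = compare_growth_relapse(fits)
        assert frac == 1.0 and len(pairs) == 3

    def test_compare_growth_relapse_known_fraction(self):
        # 8 of 10 mice constructed with a slower relapse; noise-free fits
        # preserve the ordering exactly
        fits = []
        rng = np.random.default_rng(2)
        for i in range(10):
            kg = rng.uniform(0.6, 1.2)
            kr = kg * (0.6 if i < 8 else 1.5)
            series, _ = _gdr_series(k_growth=kg, k_relapse=kr)
            fits.append(fit_trajectory(series, floor=1e3))
        frac, _ = compare_growth_relapse(fits)
        assert frac == pytest.approx(0.8)

    def test_compare_growth_relapse_requires_both_rates(self):
        series, _ = _gdr_series()
        fit = fit_trajectory(series, floor=1e3)
        bad = dataclasses.replace(
            fit, params=dataclasses.replace(fit.params, k_relapse=None)
        )
        with pytest.raises(ValueError):
            compare_growth_relapse([bad])
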