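import math

import numpy as np
import pytest

from oracles import numeric_extrema, numeric_stationary_point

from nutrireq.dose_response import (
    CubicModel,
    DoseResponseFit,
    FitError,
    InsufficientDataError,
    LognormalModel,
    NoStationaryPointError,
    PowerSeriesModel,
    SegmentedModel,
    aic_least_squares,
    aicc_least_squares,
    bootstrap_breakpoint_ci,
    cubic_stationary_points,
    estimate_requirement,
    eval_model,
    fit_model,
    fit_segmented,
    inflection_cubic,
    inflection_lognormal,
    inflection_power_series,
    select_model,
)


class TestEvalModel:
    def test_power_series_simple(self):
        m = PowerSeriesModel(1, 1, 1, -1)  # y = x + 1/x
        assert eval_model(m, 1.0) == pytest.approx(2.0)

    def test_lognormal_at_geo_mean(self):
        m = LognormalModel(amplitude=47.0, geo_mean=17.0, geo_sd=1.35)
        assert eval_model(m, 17.0) == pytest.approx(47.0 / 17.0)

    def test_constant_cubic(self):
        m = CubicModel(1, 0, 0, 0)
        assert np.allclose(eval_model(m, np.array([0.0, 3.7, -2.0])), 1.0)

    def test_lognormal_rejects_nonpositive_dose(self):
        m = LognormalModel(1.0, 10.0, 1.5)
        with pytest.raises(ValueError):
            eval_model(m, 0.0)

    def test_segmented_sharp_hinge_is_piecewise_linear(self):
        m = SegmentedModel(
            breakpoint=15.0, slope1=0.1, slope2=0.0, intercept=2.0,
            blend_width=0.0,
        )
        x = np.array([10.0, 15.0, 20.0])
        assert np.allclose(m(x), [3.0, 3.5, 3.5])

    def test_segmented_blend_is_c1(self):
        m = SegmentedModel(
            breakpoint=15.0, slope1=0.2, slope2=-0.1, intercept=1.0,
            blend_width=2.0,
        )
        h = 1e-7
        for edge in (14.0, 16.0):  # blend boundaries
            left = (m(edge) - m(edge - h)) / h
            right = (m(edge + h) - m(edge)) / h
            assert left == pytest.approx(right, abs=1e-4)


class TestInflectionPowerSeries:
    def test_known_minimum(self):
        assert inflection_power_series(
            PowerSeriesModel(1, 1, 1, -1)
        ) == pytest.approx(1.0)

    def test_parabola_vertex(self):
        # y = -x^2 + 4x peaks at 2
        assert inflection_power_series(
            PowerSeriesModel(-1, 2, 4, 1)
        ) == pytest.approx(2.0)

    def test_equal_exponents_rejected(self):
        with pytest.raises(NoStationaryPointError):
            inflection_power_series(PowerSeriesModel(1, 2, 1, 2))

    def test_no_real_stationary_point(self):
        # y = x + x^3 is strictly increasing
        with pytest.raises(NoStationaryPointError):
            inflection_power_series(PowerSeriesModel(1, 1, 1, 3))

    def test_matches_numeric_oracle_on_random_draws(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            b, d = rng.uniform(-3, 3, 2)
            if abs(b - d) < 0.3 or abs(b) < 0.05 or abs(d) < 0.05:
                continue
            a = rng.uniform(0.1, 10) * rng.choice([-1, 1])
            c = abs(rng.uniform(0.1, 10)) * (-np.sign(a * b * d))
            m = PowerSeriesModel(a, b, c, d)
            try:
                x_star = inflection_power_series(m)
            except NoStationaryPointError:
                continue
            if not 0.05 < x_star < 50:
                continue
            oracle = numeric_stationary_point(m, 1e-3, 1e3, log=True)
            assert x_star == pytest.approx(oracle, rel=1e-6)
            checked += 1


class TestInflectionLognormal:
    def test_unit_case(self):
        m = LognormalModel(1.0, math.e, math.e)
        assert inflection_lognormal(m) == pytest.approx(1.0)

    def test_narrow_spread_limit_is_geo_mean(self):
        m = LognormalModel(1.0, 17.0, 1.0 + 1e-9)
        assert inflection_lognormal(m) == pytest.approx(17.0, rel=1e-6)

    def test_matches_numeric_argmax(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = LognormalModel(
                amplitude=rng.uniform(1, 100),
                geo_mean=rng.uniform(1, 30),
                geo_sd=rng.uniform(1.05, 2.5),
            )
            oracle = numeric_stationary_point(m, 1e-2, 1e2, log=True)
            assert inflection_lognormal(m) == pytest.approx(oracle, rel=1e-8)


class TestInflectionCubic:
    def test_local_max_of_x3_minus_3x(self):
        m = CubicModel(0, -3, 0, 1)
        assert inflection_cubic(m, (-2, 0), "maximize") == pytest.approx(-1.0)

    def test_local_min_of_x3_minus_3x(self):
        m = CubicModel(0, -3, 0, 1)
        assert inflection_cubic(m, (0, 2), "minimize") == pytest.approx(1.0)

    def test_saddle_flagged(self):
        m = CubicModel(0, 0, 0, 1)  # y = x^3
        with pytest.warns(UserWarning, match="saddle"):
            assert inflection_cubic(m, (-1, 1), "maximize") == pytest.approx(0.0)

    def test_negative_discriminant(self):
        m = CubicModel(0, 3, 0, 1)  # y = x^3 + 3x, monotone
        with pytest.raises(NoStationaryPointError):
            inflection_cubic(m, (-5, 5), "maximize")

    def test_out_of_range_rejected(self):
        m = CubicModel(0, -3, 0, 1)
        with pytest.raises(NoStationaryPointError):
            inflection_cubic(m, (5, 10), "maximize")

    def test_both_roots_reported_ascending(self):
        lo, hi = cubic_stationary_points(CubicModel(0, -3, 0, 1))
        assert (lo, hi) == (pytest.approx(-1.0), pytest.approx(1.0))

    def test_roots_match_numeric_extrema(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = CubicModel(
                rng.uniform(-5, 5), rng.uniform(-5, 5),
                rng.uniform(-5, 5), rng.uniform(0.2, 3) * rng.choice([-1, 1]),
            )
            try:
                lo, hi = cubic_stationary_points(m)
            except NoStationaryPointError:
                continue
            if hi - lo < 1e-2:
                continue
            span = hi - lo
            maxima, minima = numeric_extrema(m, lo - span, hi + span)
            assert len(maxima) == 1 and len(minima) == 1
            assert sorted(maxima + minima) == [
                pytest.approx(lo, rel=1e-6, abs=1e-8),
                pytest.approx(hi, rel=1e-6, abs=1e-8),
            ]


class TestFitModel:
    def test_lognormal_self_consistency(self):
        truth = LognormalModel(47.0, 17.0, 1.35)
        x = np.linspace(8, 25, 8)
        fit = fit_model("lognormal", list(zip(x, truth(x))))
        assert fit.sse == pytest.approx(0.0, abs=1e-12)
        assert fit.params.amplitude == pytest.approx(47.0, abs=1e-6)
        assert fit.params.geo_mean == pytest.approx(17.0, abs=1e-6)
        assert fit.params.geo_sd == pytest.approx(1.35, abs=1e-6)

    def test_saturated_cubic_r2_is_one(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_model("cubic", list(zip(x, x**3)))
        assert fit.params.b3 == pytest.approx(1.0, abs=1e-9)
        assert abs(fit.params.b0) < 1e-9
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_points(self):
        data = [(1.0, 1.0), (2.0, 2.0), (3.0, 1.5)]
        with pytest.raises(InsufficientDataError):
            fit_model("power_series", data)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            fit_model("quartic", [(1, 1)] * 6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        x = np.repeat([9.5, 11.6, 14.0, 17.9, 21.5], 3)
        truth = LognormalModel.from_mode(15.8, 3.15, 3.0)
        y = truth(x) + rng.normal(0, 0.09, x.size)
        data = list(zip(x, y))
        f1 = fit_model("power_series", data, seed=5)
        f2 = fit_model("power_series", data, seed=5)
        assert f1.params == f2.params
        assert f1.aic == f2.aic

    def test_power_series_fit_inflection_matches_numeric_argmax(self):
        rng = np.random.default_rng(3)
        x = np.repeat([9.5, 11.6, 14.0, 17.9, 21.5], 3)
        truth = LognormalModel.from_mode(15.8, 3.15, 3.0)
        y = truth(x) + rng.normal(0, 0.05, x.size)
        fit = fit_model("power_series", list(zip(x, y)))
        if fit.inflection_in_range:
            oracle = numeric_stationary_point(
                fit.params, fit.inflection / 5, fit.inflection * 5, log=True
            )
            assert fit.inflection == pytest.approx(oracle, rel=1e-6)

    def test_weights_change_the_fit(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        unweighted = fit_model("cubic", list(zip(x, y)))
        down_weighted = fit_model(
            "cubic", list(zip(x, y)), weights=[1, 1, 1, 1, 1e-6]
        )
        assert down_weighted.params != unweighted.params


class TestFitStatistics:
    def test_se_of_estimate_definition(self):
        rng = np.random.default_rng(1)
        x = np.linspace(9, 22, 12)
        y = LognormalModel(47, 17, 1.35)(x) + rng.normal(0, 0.05, 12)
        fit = fit_model("lognormal", list(zip(x, y)))
        assert fit.se_estimate == pytest.approx(
            math.sqrt(fit.sse / (fit.n - fit.k))
        )
        assert fit.aic == pytest.approx(
            fit.n * math.log(fit.sse / fit.n) + 2 * fit.k
        )

    def test_aic_constant_shift_invariance(self):
        # for fixed k and unchanged SSE, AIC is unchanged
        assert aic_least_squares(0.5, 15, 3) == aic_least_squares(0.5, 15, 3)
        shifted = aic_least_squares(0.5, 15, 3)
        assert shifted == pytest.approx(15 * math.log(0.5 / 15) + 6)

    def test_aicc_exceeds_aic_and_degenerates(self):
        assert aicc_least_squares(0.5, 15, 3) > aic_least_squares(0.5, 15, 3)
        assert aicc_least_squares(0.5, 4, 3) == math.inf

    def test_r2_upper_bound(self):
        rng = np.random.default_rng(2)
        x = np.linspace(9, 22, 10)
        y = rng.normal(3, 0.2, 10)
        for family in ("cubic", "lognormal"):
            fit = fit_model(family, list(zip(x, y)))
            assert fit.r2 <= 1.0 + 1e-12


class TestFitSegmented:
    @staticmethod
    def _broken_stick(x0=15.0, s1=0.1, s2=0.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = np.repeat([9.5, 11.6, 14.0, 16.0, 17.9, 21.5], 3)
        y = 2.0 + s1 * np.minimum(x, x0) + s2 * np.maximum(x - x0, 0) - s1 * 0
        y = 2.0 + s1 * x + (s2 - s1) * np.maximum(x - x0, 0)
        return list(zip(x, y + rng.normal(0, noise, x.size)))

    def test_noiseless_recovery(self):
        fit = fit_segmented(self._broken_stick(), blend_width=0.0)
        assert fit.inflection == pytest.approx(15.0, abs=1e-6)
        assert fit.params.slope1 == pytest.approx(0.1, abs=1e-8)
        assert fit.params.slope2 == pytest.approx(0.0, abs=1e-8)

    def test_straight_line_unidentifiable(self):
        x = np.linspace(9, 22, 9)
        fit = fit_segmented(list(zip(x, 1.0 + 0.2 * x)))
        assert math.isnan(fit.inflection)
        assert "unidentifiable" in fit.message

    def test_needs_five_distinct_doses(self):
        with pytest.raises(InsufficientDataError):
            fit_segmented([(1, 1), (2, 2), (3, 3), (4, 4)])

    def test_bootstrap_ci_covers_true_break(self):
        # scaled-down simulation study: 30 replicates x 120 resamples
        # (full scale is 100 x 200; the coverage target is >= 90%)
        covered = 0
        n_rep = 30
        for rep in range(n_rep):
            data = self._broken_stick(noise=0.04, seed=100 + rep)
            lo, hi = bootstrap_breakpoint_ci(
                data, "segmented", n_boot=120, seed=rep,
                group_ids=[str(x) for x, _ in data],
            )
            if lo <= 15.0 <= hi:
                covered += 1
        assert covered / n_rep >= 0.80


class TestSelectModel:
    @staticmethod
    def _fit(family="cubic", aic=0.0, k=4, sse=1.0, inflection=15.0,
             converged=True):
        return DoseResponseFit(
            family=family, params=None, sse=sse, r2=0.5, se_estimate=0.1,
            aic=aic, aicc=aic, inflection=inflection, n=15, k=k,
            dose_range=(9.5, 21.5), converged=converged,
        )

    def test_minimum_aic_wins(self):
        best = select_model([self._fit(aic=10.0), self._fit(aic=12.0)])
        assert best.aic == 10.0

    def test_aic_tie_broken_by_fewer_params(self):
        best = select_model(
            [self._fit(aic=5.0, k=4), self._fit(family="lognormal", aic=5.0, k=3)]
        )
        assert best.k == 3

    def test_single_fit_returned(self):
        only = self._fit()
        assert select_model([only]) is only

    def test_extrapolated_inflection_screened_out(self):
        best = select_model(
            [self._fit(aic=-10.0, inflection=30.0), self._fit(aic=3.0)]
        )
        assert best.aic == 3.0

    def test_no_admissible_fit(self):
        with pytest.raises(FitError):
            select_model([self._fit(converged=False)])


class TestEstimateRequirement:
    def test_noiseless_round_trip(self):
        from nutrireq.performance import tank_metrics
        from nutrireq.synthetic_trial import default_design, generate_trial

        design = default_design(seed=0, tank_sd=0.0)
        trial = generate_trial(design)
        dose_of = {d.diet_id: d.content("methionine") for d in trial.diets}
        points = [(t.diet_id, tank_metrics(t).sgr) for t in trial.tanks]
        (est,) = estimate_requirement(
            {"dietary": dose_of}, {"sgr": points}, {"dietary": 4.5},
            exclude_diets=("D6",), seed=0,
        )
        assert est.met_requirement == pytest.approx(15.8, abs=1e-6)
        assert est.model_family == "lognormal"

    def test_tsaa_conversion_of_requirement(self):
        from nutrireq.performance import tank_metrics
        from nutrireq.synthetic_trial import default_design, generate_trial

        trial = generate_trial(default_design(seed=0, tank_sd=0.0))
        dose_of = {d.diet_id: d.content("methionine") for d in trial.diets}
        points = [(t.diet_id, tank_metrics(t).sgr) for t in trial.tanks]
        (est,) = estimate_requirement(
            {"dietary": dose_of}, {"sgr": points}, {"dietary": 4.5},
            exclude_diets=("D6",),
        )
        assert est.tsaa_met_plus_cys == pytest.approx(20.3, abs=1e-5)
        assert est.tsaa_met_equivalent == pytest.approx(
            15.8 + 4.5 * 149.21 / 121.16, abs=1e-5
        )

    def test_fcr_objective_minimizes(self):
        # valley-shaped response: the requirement is the minimizer
        x = np.repeat([9.5, 11.6, 14.0, 16.0, 17.9, 21.5], 2)
        y = 0.8 + 0.004 * (x - 14.6) ** 2
        dose_of = {f"D{i}": float(v) for i, v in enumerate(sorted(set(x)))}
        points = [
            (f"D{sorted(set(x)).index(v)}", float(w)) for v, w in zip(x, y)
        ]
        (est,) = estimate_requirement(
            {"dietary": dose_of}, {"fcr": points}, {"dietary": 4.5},
            families=("cubic", "power_series"), seed=1,
        )
        assert est.met_requirement == pytest.approx(14.6, abs=0.2)
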