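import math
import warnings

import numpy as np
import pytest

from nanoprune.core_data import Material, ResponseSeries
from nanoprune.dose_response import (
    NoConcentrationEffectError,
    fit_dose_response,
    fit_log_endpoint,
    steepness_profile,
)


def series(c, y, sd=None, material="NM", day=49):
    c = np.asarray(c, dtype=float)
    sd = np.full(len(c), np.nan) if sd is None else np.asarray(sd, dtype=float)
    n = np.where(np.isnan(sd), 1, 3)
    return ResponseSeries(material, day, "reproduction", c, np.asarray(y, float), sd, n)


def ols_on_log(c, y, w=None):
    """Independent normal-equations oracle for y = a ln c + b0."""
    x = np.log(np.asarray(c, float))
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    W = np.diag(w)
    A = np.column_stack([x, np.ones_like(x)])
    coef = np.linalg.solve(A.T @ W @ A, A.T @ W @ np.asarray(y, float))
    return -coef[0], coef[1]  # (b, b0)


class TestFitLogEndpoint:
    def test_exact_line(self, log_series):
        f = fit_log_endpoint(log_series)
        assert f.b == pytest.approx(2.0, abs=1e-12)
        assert f.b0 == pytest.approx(5.0, abs=1e-12)
        assert f.r_squared == pytest.approx(1.0)

    def test_flat_series_gives_zero_slope(self):
        f = fit_log_endpoint(series([1, 10, 100], [10, 10, 10]))
        assert f.b == 0
        assert f.b0 == 10
        assert f.r_squared == 0

    def test_controls_excluded(self):
        c = [0.0, 1.0, math.e, math.e**2]
        f = fit_log_endpoint(series(c, [999.0, 5.0, 3.0, 1.0]))
        assert f.b == pytest.approx(2.0, abs=1e-12)
        assert f.n_points == 3

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match=">=3"):
            fit_log_endpoint(series([1, 10], [5, 3]))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            c = np.sort(rng.uniform(10, 3000, size=5))
            y = rng.normal(200, 40, size=5)
            f = fit_log_endpoint(series(c, y))
            b, b0 = ols_on_log(c, y)
            # absolute for O(1) parameters, relative for large magnitudes
            assert abs(f.b - b) < 1e-10 * max(1.0, abs(b))
            assert abs(f.b0 - b0) < 1e-10 * max(1.0, abs(b0))

    def test_weighted_fit_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(5)
        c = np.array([100.0, 320.0, 640.0, 1000.0, 3200.0])
        y = rng.normal(150, 30, size=5)
        sd = rng.uniform(5, 20, size=5)
        f = fit_log_endpoint(series(c, y, sd=sd))
        b, b0 = ols_on_log(c, y, w=1 / sd**2)
        assert f.b == pytest.approx(b, abs=1e-10)
        assert f.b0 == pytest.approx(b0, abs=1e-10)


class TestFitDoseResponse:
    def test_logistic2_parameter_recovery(self, logistic_series):
        fit = fit_dose_response(logistic_series, "logistic2")
        assert fit.ec50 == pytest.approx(650.0, rel=1e-3)
        assert fit.slope == pytest.approx(3.0, rel=1e-3)
        assert fit.y0 == 500.0

    def test_ec10_matches_closed_form(self, logistic_series):
        fit = fit_dose_response(logistic_series, "logistic2")
        closed = fit.ec50 * math.exp(math.log(1.0 / 9.0) / fit.slope)
        assert fit.ecx(10.0) == pytest.approx(closed, abs=1e-8)

    def test_half_response_at_ec50(self, logistic_series):
        fit = fit_dose_response(logistic_series, "logistic2")
        assert fit.predict([fit.ec50])[0] == pytest.approx(fit.y0 / 2.0, rel=1e-9)

    def test_ecx_monotone_in_x(self, logistic_series):
        fit = fit_dose_response(logistic_series, "logistic2")
        xs = [5, 10, 20, 50, 80, 95]
        ecs = [fit.ecx(x) for x in xs]
        assert all(a < b for a, b in zip(ecs, ecs[1:]))
        assert fit.ecx(50.0) == pytest.approx(fit.ec50)

    def test_flat_series_has_no_ec50(self):
        s = series([0, 100, 320, 640, 1000], [400] * 5, day=21)
        with pytest.raises(NoConcentrationEffectError, match="no concentration effect"):
            fit_dose_response(s, "logistic2")

    def test_increasing_response_warns_but_fits(self):
        s = series([0, 100, 320, 640, 1000], [100, 120, 150, 180, 220], day=21)
        with pytest.warns(UserWarning, match="increases with concentration"):
            fit_dose_response(s, "logistic2")

    def test_threshold_model_flat_then_decay(self):
        c = np.array([0.0, 100.0, 320.0, 640.0, 1000.0, 3200.0])
        y = np.where(c <= 320, 400.0, 2 * 400.0 / (1 + (c / 320.0) ** 2.5))
        y[0] = 400.0
        fit = fit_dose_response(series(c, y, day=21), "threshold_sigmoid2")
        assert fit.r_squared > 0.999
        assert fit.ec50 == pytest.approx(fit.ecx(50.0))
        # below the threshold the model is exactly flat at y0
        assert fit.predict([fit.threshold * 0.5])[0] == fit.y0

    def test_noiseless_recovery_over_many_seeds(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(50):
            ec50 = rng.uniform(200, 2000)
            slope = rng.uniform(1.5, 5)
            y0 = rng.uniform(200, 600)
            c = np.array([0.0, 100.0, 320.0, 640.0, 1000.0, 3200.0])
            y = np.empty_like(c)
            y[0] = y0
            y[1:] = y0 / (1 + np.exp(slope * (np.log(c[1:]) - math.log(ec50))))
            fit = fit_dose_response(series(c, y, day=21), "logistic2")
            worst = max(worst, abs(fit.ec50 - ec50) / ec50)
        assert worst < 1e-3


class TestSteepnessProfile:
    def test_planted_monotone_trend(self):
        from scipy.stats import spearmanr
        from nanoprune.dose_response import LogEndpointFit

        fits = {}
        for i, fe in enumerate([0, 2, 4, 6, 8, 10]):
            mat = Material(f"{fe}%Fe-CuO" if fe else "CuO", fe_fraction=fe)
            fits[mat] = LogEndpointFit(b=40.0 - 3.0 * fe, b0=300.0, r_squared=0.95, n_points=5)
        table = steepness_profile(fits)
        assert list(table.fe_fraction) == sorted(table.fe_fraction)
        rho, _ = spearmanr(table.fe_fraction, table.b)
        assert rho == -1.0

    def test_single_material(self):
        from nanoprune.dose_response import LogEndpointFit

        table = steepness_profile(
            {Material("CuO"): LogEndpointFit(b=30.0, b0=250.0, r_squared=0.9, n_points=5)}
        )
        assert len(table) == 1

    def test_per_day_fits_expand(self):
        from nanoprune.dose_response import LogEndpointFit

        f21 = LogEndpointFit(b=20.0, b0=300.0, r_squared=0.9, n_points=5)
        f49 = LogEndpointFit(b=35.0, b0=280.0, r_squared=0.9, n_points=5)
        table = steepness_profile({Material("CuO"): {21: f21, 49: f49}})
        assert set(table.day) == {21, 49}
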