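"""AR(1)-GLS exchange-model fitting, prediction, screening, conversions."""

import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm

from innerbark.errors import AnchorError, CollinearityError, DomainError
from innerbark.exchange_model import (
    ExchangeDesign,
    ExchangeModelFit,
    accept_fit,
    build_design,
    fit_gls_ar1,
    predict_thickness,
    radial_conductance_si,
    turgor_pressure_amplitude,
    turgor_signal,
)
from innerbark.timeseries_io import Flag, GriddedSeries, SAMPLES_PER_DAY

from conftest import make_series


def simulate_design(alpha, beta, gamma, phi, sigma, rng, n=SAMPLES_PER_DAY):
    """Day generated by the model recursion with AR(1) process noise."""
    h = np.arange(n) / 6.0
    psi = -0.6 * np.clip(np.sin(np.pi * (h - 6) / 12), 0, None)
    psi = psi + 0.05 * np.cumsum(rng.normal(0, 0.1, n)) / np.sqrt(n)
    dpsi = psi - psi[0]
    e = np.zeros(n)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + rng.normal(0, sigma)
    dth = np.zeros(n)
    for t in range(n - 1):
        dth[t + 1] = dth[t] + alpha * (beta * dpsi[t] - dth[t]) + gamma + e[t + 1]
    return ExchangeDesign(
        d_thickness=np.diff(dth),
        delta_psi=dpsi[:-1],
        delta_th=dth[:-1],
        n_steps=n,
        delta_psi_full=dpsi,
        delta_th_full=dth,
    )


class TestBuildDesign:
    def _day(self, th_vals, psi_vals):
        n = len(th_vals)
        ts = pd.date_range("2019-08-01", periods=n, freq="600s")
        flags = np.full(n, Flag.OK, np.int8)
        return (
            GriddedSeries(ts, th_vals, flags, "µm"),
            GriddedSeries(ts, psi_vals, flags.copy(), "MPa"),
        )

    def test_constant_inputs_give_zero_arrays(self):
        th, psi = self._day(np.full(144, 5.0), np.full(144, -0.2))
        d = build_design(th, psi)
        assert not d.d_thickness.any()
        assert not d.delta_psi.any()
        assert not d.delta_th.any()
        assert d.delta_psi[0] == 0.0 and d.delta_th[0] == 0.0

    def test_ramp_thickness_arithmetic(self):
        th, psi = self._day(np.arange(144, dtype=float), np.linspace(0, -1, 144))
        d = build_design(th, psi)
        np.testing.assert_array_equal(d.d_thickness, np.ones(143))
        np.testing.assert_array_equal(d.delta_th, np.arange(143, dtype=float))

    def test_missing_midnight_anchor_rejected(self):
        ts = pd.date_range("2019-08-01 00:10", periods=143, freq="600s")
        flags = np.full(143, Flag.OK, np.int8)
        th = GriddedSeries(ts, np.zeros(143), flags, "µm")
        psi = GriddedSeries(ts, np.zeros(143), flags.copy(), "MPa")
        with pytest.raises(AnchorError):
            build_design(th, psi)


class TestFitGlsAr1:
    def test_noise_free_recursion_recovered_exactly(self):
        """Self-consistency oracle: data from the recursion give back c1=10, c2=−0.1."""
        rng = np.random.default_rng(0)
        d = simulate_design(0.1, 100.0, 0.0, 0.0, 0.0, rng)
        f = fit_gls_ar1(d)
        assert f.alpha_beta == pytest.approx(10.0, rel=1e-8)
        assert f.alpha == pytest.approx(0.1, rel=1e-8)
        assert f.gamma == pytest.approx(0.0, abs=1e-10)
        assert f.r2_prediction == pytest.approx(1.0, abs=1e-9)

    def test_ar1_noise_mean_recovery_within_10pct(self):
        """50 replicate days with φ=0.6 noise: mean α, β within 10% of truth."""
        rng = np.random.default_rng(1)
        alphas, betas = [], []
        for _ in range(50):
            d = simulate_design(0.1, 100.0, 0.0, 0.6, 0.05, rng)
            f = fit_gls_ar1(d)
            alphas.append(f.alpha)
            betas.append(f.beta)
        assert np.mean(alphas) == pytest.approx(0.1, rel=0.10)
        assert np.mean(betas) == pytest.approx(100.0, rel=0.10)

    def test_confidence_interval_coverage_for_conductance(self):
        """95% intervals for c₁ = αβ cover the truth 90–99% of the time."""
        rng = np.random.default_rng(2)
        hits = 0
        n_days = 200
        for _ in range(n_days):
            alpha = rng.uniform(0.05, 0.3)
            beta = rng.uniform(30, 150)
            phi = rng.uniform(0.0, 0.8)
            d = simulate_design(alpha, beta, 0.0, phi, 0.05, rng)
            f = fit_gls_ar1(d)
            if abs(f.alpha_beta - alpha * beta) <= 1.96 * f.se["c1"]:
                hits += 1
        assert 0.90 <= hits / n_days <= 0.99

    def test_constant_psi_raises_collinearity(self):
        d = simulate_design(0.1, 100.0, 0.0, 0.0, 0.0, np.random.default_rng(0))
        d.delta_psi[:] = 0.0
        with pytest.raises(CollinearityError):
            fit_gls_ar1(d)

    def test_phi_zero_equals_ols(self):
        """With φ fixed at 0, the GLS fit is ordinary least squares to 1e-8."""
        rng = np.random.default_rng(3)
        d = simulate_design(0.12, 80.0, 0.2, 0.0, 0.1, rng)
        f = fit_gls_ar1(d, phi_grid=np.array([0.0]))
        X = np.column_stack([d.delta_psi, d.delta_th, np.ones_like(d.d_thickness)])
        coef, *_ = np.linalg.lstsq(X, d.d_thickness, rcond=None)
        assert f.alpha_beta == pytest.approx(coef[0], rel=1e-8)
        assert -f.alpha == pytest.approx(coef[1], rel=1e-8)
        assert f.gamma == pytest.approx(coef[2], rel=1e-8)

    def test_matches_statsmodels_glsar(self):
        """Independent oracle: iterative GLSAR lands on the same coefficients."""
        rng = np.random.default_rng(7)
        d = simulate_design(0.1, 80.0, 0.3, 0.6, 0.05, rng)
        f = fit_gls_ar1(d)
        X = np.column_stack([d.delta_psi, d.delta_th, np.ones_like(d.d_thickness)])
        m = sm.GLSAR(d.d_thickness, X, rho=1).iterative_fit(maxiter=50)
        assert f.alpha_beta == pytest.approx(m.params[0], rel=0.02)
        assert -f.alpha == pytest.approx(m.params[1], rel=0.05)
        assert f.phi == pytest.approx(float(m.model.rho[0]), abs=0.05)


class TestPredictThickness:
    def _fit(self, alpha, beta, gamma):
        return ExchangeModelFit(
            alpha=alpha,
            beta=beta,
            gamma=gamma,
            phi=0.0,
            alpha_beta=alpha * beta,
            se={"c1": 0.0, "c2": 0.0, "c0": 0.0},
            sigma2=0.0,
            loglik=0.0,
            r2_prediction=1.0,
        )

    def test_zero_forcing_zero_drift_stays_zero(self):
        pred = predict_thickness(self._fit(0.1, 100.0, 0.0), np.zeros(20))
        assert not pred.any()

    def test_step_response_matches_geometric_series(self):
        """Step ΔΨ = −0.5 MPa: ΔTh(10) = −50·(1 − 0.9¹⁰) = −32.566 µm."""
        pred = predict_thickness(self._fit(0.1, 100.0, 0.0), np.full(11, -0.5))
        assert pred[10] == pytest.approx(-50.0 * (1 - 0.9**10), rel=1e-12)
        assert pred[10] == pytest.approx(-32.566077995, abs=1e-9)
        long = predict_thickness(self._fit(0.1, 100.0, 0.0), np.full(200, -0.5))
        assert long[-1] == pytest.approx(-50.0, abs=1e-6)

    def test_drift_fixed_point_is_gamma_over_alpha(self):
        pred = predict_thickness(self._fit(0.1, 100.0, 1.0), np.zeros(300))
        assert pred[-1] == pytest.approx(10.0, rel=1e-6)

    def test_contraction_bound_for_bounded_forcing(self):
        rng = np.random.default_rng(5)
        alpha, beta, gamma = 0.3, 60.0, 0.5
        dpsi = rng.uniform(-0.8, 0.0, 500)
        pred = predict_thickness(self._fit(alpha, beta, gamma), dpsi)
        bound = beta * np.abs(dpsi).max() + abs(gamma) / alpha
        assert np.abs(pred).max() <= bound + 1e-9

    def test_rejected_fit_refuses_to_predict(self):
        f = accept_fit(self._fit(-0.1, 100.0, 0.0))
        with pytest.raises(DomainError):
            predict_thickness(f, np.zeros(10))


class TestTurgorSignal:
    def test_identical_series_zero_signal(self):
        sig = turgor_signal(np.arange(10.0), np.arange(10.0))
        assert not sig.series.any()
        assert sig.amplitude == 0.0

    def test_step_offset_appears_as_step(self):
        obs = np.zeros(100)
        obs[40:] += 7.5
        sig = turgor_signal(obs, np.zeros(100))
        assert sig.amplitude == pytest.approx(7.5)
        np.testing.assert_array_equal(sig.series[40:], 7.5)

    def test_pressure_amplitude_via_modulus(self):
        sig = turgor_signal(np.array([0.0, 50.0]), np.zeros(2), 20.0, 5000.0)
        assert sig.pressure_amplitude == pytest.approx(0.2)


class TestAcceptFit:
    def _fit(self, **kw):
        base = dict(
            alpha=0.1,
            beta=50.0,
            gamma=0.0,
            phi=0.5,
            alpha_beta=5.0,
            se={"c1": 0.5, "c2": 0.01, "c0": 0.1},
            sigma2=0.01,
            loglik=0.0,
            r2_prediction=0.8,
        )
        base.update(kw)
        return ExchangeModelFit(**base)

    def test_negative_rate_rejected_with_reason(self):
        f = accept_fit(self._fit(alpha=-0.05))
        assert f.accepted is False
        assert "negative rate" in f.reason

    def test_textbook_fit_accepted(self):
        f = accept_fit(self._fit())
        assert f.accepted is True
        assert f.reason == ""

    def test_prediction_worse_than_zero_model_rejected(self):
        f = accept_fit(self._fit(r2_prediction=-0.3))
        assert f.accepted is False
        assert "worse than zero model" in f.reason

    def test_uninformative_conductance_rejected(self):
        f = accept_fit(self._fit(se={"c1": 10.0, "c2": 0.01, "c0": 0.1}))
        assert f.accepted is False
        assert "relative SE" in f.reason

    def test_near_unit_root_rejected(self):
        f = accept_fit(self._fit(phi=0.995))
        assert f.accepted is False


class TestUnitConversions:
    @pytest.mark.parametrize(
        "native, si", [(4.8, 8.0e-9), (1.8, 3.0e-9), (0.0, 0.0)]
    )
    def test_radial_conductance_to_si(self, native, si):
        assert radial_conductance_si(native) == pytest.approx(si, rel=1e-12)

    @pytest.mark.parametrize(
        "amp, modulus, thickness, expected",
        [(50.0, 20.0, 5000.0, 0.2), (0.0, 15.0, 5000.0, 0.0), (100.0, 15.0, 7500.0, 0.2)],
    )
    def test_turgor_pressure_amplitude(self, amp, modulus, thickness, expected):
        assert turgor_pressure_amplitude(amp, modulus, thickness) == pytest.approx(expected)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(DomainError):
            turgor_pressure_amplitude(50.0, 20.0, 0.0)
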