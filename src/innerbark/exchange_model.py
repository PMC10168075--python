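"""Radial xylem–phloem water-exchange (capacitor) model and turgor signal.

The inner bark is treated as an elastic water reservoir connected to the
xylem through a finite radial hydraulic conductance.  Within one calendar
day, with ΔΨ_X and ΔTh_IB the changes in xylem water potential and inner
bark thickness relative to the first measurement at midnight, the thickness
obeys the first-order relaxation

    dTh_IB/dt = α (β ΔΨ_X − ΔTh_IB) + γ              (per 10-min step)

where α (step⁻¹) is the relaxation rate, β (µm MPa⁻¹) the equilibrium
thickness change per unit potential, and γ (µm step⁻¹) a drift term.  The
product αβ is the radial hydraulic conductance in native units
(µm MPa⁻¹ step⁻¹); × 10⁻⁶/600 converts it to m MPa⁻¹ s⁻¹.

Note the parenthesization: the model is fitted as the linear regression
dTh = c₁ ΔΨ + c₂ ΔTh + c₀ with α = −c₂, β = c₁/α, so that c₁ = αβ is the
conductance.  Residuals of the 10-min regression are strongly autocorrelated,
so the fit is generalized least squares with AR(1) errors; the AR coefficient
φ is profiled on a fixed grid with exact GLS whitening at each φ (no
iterative-convergence ambiguity), maximizing the Gaussian likelihood.

The fitted model predicts the thickness trajectory driven by Ψ_X alone
(constant osmoticum).  The observed-minus-predicted residual is the
turgor-related signal: thickness change attributable to varying solute
content of the phloem.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AnchorError, CollinearityError, DomainError, LengthError
from .timeseries_io import GriddedSeries, STEP_SECONDS

#: native→SI conversion for the conductance αβ: µm per step → m per second
SI_PER_NATIVE = 1e-6 / STEP_SECONDS


@dataclass
class ExchangeDesign:
    """Per-day regression arrays, all of length n_steps − 1.

    ``d_thickness[t] = Th[t+1] − Th[t]`` is regressed on ``delta_psi[t]`` and
    ``delta_th[t]`` (changes relative to the midnight anchor), making the
    fitted regression exactly consistent with the forward-difference
    prediction recursion.
    """

    d_thickness: np.ndarray  # µm per step
    delta_psi: np.ndarray  # MPa, anchored at midnight
    delta_th: np.ndarray  # µm, anchored at midnight
    n_steps: int
    date: pd.Timestamp | None = None
    delta_psi_full: np.ndarray | None = None  # length n_steps, for prediction
    delta_th_full: np.ndarray | None = None  # length n_steps, observed ΔTh


@dataclass
class ExchangeModelFit:
    alpha: float  # step⁻¹
    beta: float  # µm MPa⁻¹
    gamma: float  # µm step⁻¹
    phi: float  # AR(1) residual coefficient
    alpha_beta: float  # µm MPa⁻¹ step⁻¹ (= c₁, radial hydraulic conductance)
    se: dict  # standard errors of the regression coefficients c1, c2, c0
    sigma2: float
    loglik: float
    r2_prediction: float  # R² of the Eq.-3 trajectory against observed ΔTh
    date: pd.Timestamp | None = None
    accepted: bool | None = None
    reason: str = ""


@dataclass
class TurgorSignal:
    series: np.ndarray  # observed ΔTh − predicted ΔTh, µm, series[0] = 0
    amplitude: float  # µm, max − min ≥ 0
    pressure_amplitude: float | None = None  # MPa, via elastic modulus


def build_design(thickness_day: GriddedSeries, psi_day: GriddedSeries) -> ExchangeDesign:
    """Assemble the per-day regression arrays from detrended thickness and ψ_X.

    Requires a full day of valid samples for both series starting at the
    midnight anchor (first measurement of the calendar day).
    """
    if not thickness_day.same_grid(psi_day):
        raise AnchorError("thickness and ψ must share one day grid")
    if len(thickness_day) < 2:
        raise LengthError("day too short")
    t0 = thickness_day.timestamps[0]
    if not (t0.hour == 0 and t0.minute == 0):
        raise AnchorError("first sample must be the midnight anchor (00:00)")
    if not thickness_day.valid.all() or not psi_day.valid.all():
        raise AnchorError("full day of valid samples required (anchor or interior missing)")
    th = thickness_day.values
    psi = psi_day.values
    dth_full = th - th[0]
    dpsi_full = psi - psi[0]
    return ExchangeDesign(
        d_thickness=np.diff(th),
        delta_psi=dpsi_full[:-1],
        delta_th=dth_full[:-1],
        n_steps=len(th),
        date=t0.normalize(),
        delta_psi_full=dpsi_full,
        delta_th_full=dth_full,
    )


def _phi_grid(step: float = 0.01, phi_max: float = 0.98) -> np.ndarray:
    n = int(round(phi_max / step))
    return np.arange(-n, n + 1) * step


def fit_gls_ar1(
    design: ExchangeDesign,
    phi_grid: np.ndarray | None = None,
    min_steps: int = 48,
) -> ExchangeModelFit:
    """Fit the exchange model by AR(1) generalized least squares.

    For each candidate φ the data are whitened exactly (first row scaled by
    √(1−φ²), subsequent rows differenced by φ) and solved by least squares;
    φ is chosen to maximize the Gaussian log-likelihood.  Deterministic by
    construction.
    """
    if design.n_steps < min_steps:
        raise LengthError(f"need ≥ {min_steps} steps, got {design.n_steps}")
    y = np.asarray(design.d_thickness, dtype=float)
    Z = np.column_stack(
        [
            np.asarray(design.delta_psi, dtype=float),
            np.asarray(design.delta_th, dtype=float),
            np.ones_like(y),
        ]
    )
    m = len(y)
    if np.ptp(Z[:, 0]) < 1e-12 or np.linalg.matrix_rank(Z) < 3:
        raise CollinearityError("ΔΨ_X constant (or design otherwise singular)")

    phis = _phi_grid() if phi_grid is None else np.asarray(phi_grid, dtype=float)
    P = len(phis)
    ph = phis[:, None, None]
    # whitened designs for all φ at once: row 0 scaled, rows 1.. differenced
    Zt = np.concatenate(
        [np.sqrt(1.0 - phis[:, None, None] ** 2) * Z[None, :1, :], Z[None, 1:, :] - ph * Z[None, :-1, :]],
        axis=1,
    )
    yt = np.concatenate(
        [np.sqrt(1.0 - phis[:, None] ** 2) * y[None, :1], y[None, 1:] - phis[:, None] * y[None, :-1]],
        axis=1,
    )
    G = np.einsum("pij,pik->pjk", Zt, Zt)
    b = np.einsum("pij,pi->pj", Zt, yt)
    try:
        coefs = np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rank checked above
        raise CollinearityError("singular whitened design") from exc
    yty = np.einsum("pi,pi->p", yt, yt)
    rss = np.maximum(yty - np.einsum("pj,pj->p", b, coefs), 1e-300)
    # Gaussian profile log-likelihood up to constants
    loglik = -0.5 * m * np.log(rss / m) + 0.5 * np.log1p(-phis**2)
    k = int(np.argmax(loglik))
    phi = float(phis[k])
    c1, c2, c0 = (float(v) for v in coefs[k])
    dof = max(m - 3, 1)
    sigma2 = float(rss[k]) / dof
    cov = sigma2 * np.linalg.inv(G[k])
    se = {
        "c1": float(np.sqrt(cov[0, 0])),
        "c2": float(np.sqrt(cov[1, 1])),
        "c0": float(np.sqrt(cov[2, 2])),
    }

    alpha = -c2
    beta = c1 / alpha if alpha != 0 else np.nan
    fit = ExchangeModelFit(
        alpha=alpha,
        beta=beta,
        gamma=c0,
        phi=phi,
        alpha_beta=c1,
        se=se,
        sigma2=sigma2,
        loglik=float(loglik[k]),
        r2_prediction=np.nan,
        date=design.date,
    )
    if design.delta_psi_full is not None and design.delta_th_full is not None:
        pred = predict_thickness(fit, design.delta_psi_full, check_accepted=False)
        obs = design.delta_th_full
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        ss_res = float(((obs - pred) ** 2).sum())
        fit.r2_prediction = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return fit


def predict_thickness(
    fit: ExchangeModelFit, delta_psi: np.ndarray, check_accepted: bool = True
) -> np.ndarray:
    """Thickness trajectory driven by ψ_X alone (constant osmotic content).

    Recursion ΔTh(t+1) = ΔTh(t) + α(β ΔΨ_X(t) − ΔTh(t)) + γ with ΔTh(0)=0.
    For 0 < α < 1 this is a contraction: bounded ΔΨ gives bounded ΔTh
    (|ΔTh| ≤ β·max|ΔΨ| + |γ|/α).
    """
    if check_accepted and fit.accepted is False:
        raise DomainError(f"refusing to predict from a rejected fit ({fit.reason})")
    dpsi = np.asarray(delta_psi, dtype=float)
    n = len(dpsi)
    out = np.zeros(n)
    a, b, g = fit.alpha, fit.beta, fit.gamma
    for t in range(n - 1):
        out[t + 1] = out[t] + a * (b * dpsi[t] - out[t]) + g
    return out


def turgor_signal(
    observed_delta_th: np.ndarray,
    predicted_delta_th: np.ndarray,
    modulus_mpa: float | None = None,
    bark_thickness_um: float | None = None,
) -> TurgorSignal:
    """Observed − predicted thickness change: the turgor-related residual.

    When an elastic modulus and an absolute bark thickness are supplied the
    amplitude is also expressed as a pressure change (MPa).
    """
    obs = np.asarray(observed_delta_th, dtype=float)
    pred = np.asarray(predicted_delta_th, dtype=float)
    if obs.shape != pred.shape:
        raise DomainError("observed and predicted series must share one grid")
    series = obs - pred
    amplitude = float(np.nanmax(series) - np.nanmin(series)) if len(series) else 0.0
    pressure = None
    if modulus_mpa is not None and bark_thickness_um is not None:
        pressure = turgor_pressure_amplitude(amplitude, modulus_mpa, bark_thickness_um)
    return TurgorSignal(series=series, amplitude=amplitude, pressure_amplitude=pressure)


DEFAULT_REJECT = {
    "min_alpha": 0.0,  # α must be positive (thickness relaxes toward equilibrium)
    "min_beta": 0.0,  # β must be positive (tension thins the bark)
    "max_abs_phi": 0.99,
    "max_rel_se_c1": 1.0,  # |SE(c₁)/c₁| ≤ 100%
    "min_r2_prediction": 0.0,  # prediction must beat the zero model
}


def accept_fit(fit: ExchangeModelFit, criteria: dict | None = None) -> ExchangeModelFit:
    """Screen a daily fit against realism criteria; record the reason.

    Unrealistic adjustments (negative rates, wrong-signed elasticity,
    near-unit-root residuals, uninformative conductance, predictions worse
    than the zero model) are flagged rejected rather than silently kept.
    """
    c = dict(DEFAULT_REJECT)
    if criteria:
        c.update(criteria)
    reasons = []
    if not np.isfinite(fit.alpha) or fit.alpha <= c["min_alpha"]:
        reasons.append("negative rate")
    if not np.isfinite(fit.beta) or fit.beta <= c["min_beta"]:
        reasons.append("negative elasticity coefficient")
    if abs(fit.phi) >= c["max_abs_phi"]:
        reasons.append("near-unit-root residual autocorrelation")
    if fit.alpha_beta == 0 or not np.isfinite(fit.alpha_beta):
        reasons.append("zero conductance")
    elif abs(fit.se["c1"] / fit.alpha_beta) > c["max_rel_se_c1"]:
        reasons.append("uninformative conductance (relative SE > 100%)")
    if np.isfinite(fit.r2_prediction) and fit.r2_prediction < c["min_r2_prediction"]:
        reasons.append("prediction worse than zero model")
    return replace(fit, accepted=not reasons, reason="; ".join(reasons))


def radial_conductance_si(alpha_beta: float, step_seconds: int = STEP_SECONDS) -> float:
    """Convert αβ from µm MPa⁻¹ step⁻¹ to m MPa⁻¹ s⁻¹ (× 10⁻⁶ / 600)."""
    return alpha_beta * 1e-6 / step_seconds


def turgor_pressure_amplitude(
    signal_amplitude_um: float, modulus_mpa: float, bark_thickness_um: float
) -> float:
    """Pressure change implied by a turgor-signal amplitude via Hooke's law.

    ΔP = ε · (ΔTh / Th) with bulk elastic modulus ε and absolute inner-bark
    thickness Th.
    """
    if bark_thickness_um <= 0:
        raise DomainError("bark thickness must be positive")
    return modulus_mpa * signal_amplitude_um / bark_thickness_um
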