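"""Daily amplitude, extrema timing, ψ–thickness lag, and climate responses.

The diurnal amplitude of inner-bark thickness is max − min within a day; the
maximum is searched in [00:00, 24:00) and the minimum in the following 24 h
starting at the time of the maximum, because on some days the bark keeps
shrinking past midnight.  The lag of thickness behind xylem water potential
is the argmax of the normalized cross-correlation within ±12 h; negative lag
means thickness lags behind ψ_X.  Seasonal climate responses follow the
field convention: amplitude vs global radiation linear, vs VPD quadratic,
vs air temperature exponential (yielding an apparent Q10 = exp(10k)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DomainError,
    LengthError,
    UndefinedCorrelationError,
)
from .timeseries_io import GriddedSeries, SAMPLES_PER_DAY, STEP_SECONDS


@dataclass
class DailyMetrics:
    date: pd.Timestamp
    amplitude: float  # µm, max − min ≥ 0
    t_max: pd.Timestamp | None
    t_min: pd.Timestamp | None
    valid: bool
    reason: str = ""


@dataclass
class LagEstimate:
    date: pd.Timestamp
    lag_minutes: float  # negative: thickness lags behind ψ_X
    peak_correlation: float
    expected_sign_ok: bool = True  # QC: thickness should track ψ positively


@dataclass
class ClimateResponseFit:
    predictor: str  # R_G | VPD | T_A
    form: str  # linear | quadratic | exponential
    coefficients: dict
    scope: str  # tree id or "pooled"
    n_days: int
    r_squared: float
    q10: float | None = None
    tree_offsets: dict = field(default_factory=dict)


def daily_extrema(
    detrended: GriddedSeries, date, min_valid_fraction: float = 0.8
) -> DailyMetrics:
    """Amplitude and extrema clock times of one day's thickness cycle.

    Ties broken to the earliest time.  Days with fewer than
    ``min_valid_fraction`` of their 144 samples valid are marked invalid.
    """
    d0 = pd.Timestamp(date).normalize()
    day = detrended.day(d0)
    nvalid = int(day.valid.sum())
    if nvalid < min_valid_fraction * SAMPLES_PER_DAY:
        return DailyMetrics(d0, np.nan, None, None, False, reason="too many missing samples")

    vals = np.where(day.valid, day.values, -np.inf)
    imax = int(np.argmax(vals))  # argmax takes the first of tied maxima
    t_max = day.timestamps[imax]

    window = detrended.between(t_max, t_max + pd.Timedelta(days=1))
    wvals = np.where(window.valid, window.values, np.inf)
    imin = int(np.argmin(wvals))
    t_min = window.timestamps[imin]
    amplitude = float(day.values[imax] - window.values[imin])
    return DailyMetrics(d0, amplitude, t_max, t_min, True)


def xcorr_lag(
    thickness_day: GriddedSeries,
    psi_day: GriddedSeries,
    max_lag_minutes: int = 720,
    min_overlap: int = 36,
) -> LagEstimate:
    """Lag of thickness behind ψ_X by normalized cross-correlation.

    Both series are mean-centred over the day; the correlation at lag L
    (a multiple of 10 min) compares thickness(t) with ψ(t + L) over their
    overlap, so a thickness trace that is a delayed copy of ψ yields a
    negative lag.  The signed correlation (not its absolute value) is
    maximized; ties break toward the smallest |L|.
    """
    if not thickness_day.same_grid(psi_day):
        raise AlignmentError("thickness and ψ must share one day grid")
    both = thickness_day.valid & psi_day.valid
    x = np.where(both, thickness_day.values, np.nan)
    y = np.where(both, psi_day.values, np.nan)
    if np.nanstd(x) == 0 or np.nanstd(y) == 0 or both.sum() < min_overlap:
        raise UndefinedCorrelationError("zero-variance or empty day; correlation undefined")
    x = x - np.nanmean(x)
    y = y - np.nanmean(y)

    max_steps = max_lag_minutes * 60 // STEP_SECONDS
    n = len(x)
    best = (-np.inf, 0)
    for lag in range(-max_steps, max_steps + 1):
        if lag >= 0:
            xs, ys = x[: n - lag or None], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        m = np.isfinite(xs) & np.isfinite(ys)
        if m.sum() < min_overlap:
            continue
        a, b = xs[m], ys[m]
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        if denom == 0:
            continue
        r = float((a * b).sum() / denom)
        # strict improvement, or equal r at strictly smaller |lag|
        if r > best[0] + 1e-12 or (abs(r - best[0]) <= 1e-12 and abs(lag) < abs(best[1])):
            best = (r, lag)
    r, lag = best
    if not np.isfinite(r):
        raise UndefinedCorrelationError("no lag with sufficient overlap")
    date = thickness_day.timestamps[0].normalize()
    return LagEstimate(
        date,
        lag_minutes=lag * STEP_SECONDS / 60.0,
        peak_correlation=r,
        expected_sign_ok=r > 0,
    )


def q10_from_rate(k: float) -> float:
    """Apparent Q10: proportional amplitude change per 10 °C, exp(10k)."""
    return float(np.exp(10.0 * k))


_DEFAULT_FORMS = {"R_G": "linear", "VPD": "quadratic", "T_A": "exponential"}


def fit_climate_response(
    daily: pd.DataFrame,
    predictor: str,
    form: str | None = None,
    scope: str = "pooled",
    min_days: int = 10,
) -> ClimateResponseFit:
    """Least-squares fit of daily amplitude against one climate predictor.

    ``daily`` must hold columns ``amplitude``, the predictor, and (for pooled
    fits with per-tree offsets) ``tree_id``.  The exponential form is fitted
    by log-linearization (non-positive amplitudes dropped with a warning),
    and its apparent Q10 is exp(10k).  The pooled fit approximates the
    tree-as-random-factor structure with fixed per-tree intercept offsets.
    """
    form = form or _DEFAULT_FORMS.get(predictor)
    if form not in {"linear", "quadratic", "exponential"}:
        raise DomainError(f"unknown response form {form!r}")
    df = daily.dropna(subset=["amplitude", predictor]).copy()
    if scope != "pooled":
        df = df[df["tree_id"].astype(str) == str(scope)]
    if len(df) < min_days:
        raise LengthError(f"need ≥ {min_days} valid days, got {len(df)}")

    x = df[predictor].to_numpy(float)
    amp = df["amplitude"].to_numpy(float)
    if form == "exponential":
        pos = amp > 0
        if not pos.all():
            warnings.warn(
                f"dropping {int((~pos).sum())} non-positive amplitudes for exponential fit",
                stacklevel=2,
            )
        x, amp, df = x[pos], amp[pos], df[pos]
        if len(amp) < min_days:
            raise LengthError("too few positive amplitudes for exponential fit")
        yy = np.log(amp)
    else:
        yy = amp

    cols = [np.ones_like(x), x]
    if form == "quadratic":
        cols.append(x**2)
    offsets: dict = {}
    trees = None
    if scope == "pooled" and "tree_id" in df.columns:
        trees = sorted(df["tree_id"].astype(str).unique())
        for t in trees[1:]:  # first tree absorbed in the intercept
            cols.append((df["tree_id"].astype(str) == t).to_numpy(float))
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ coef
    ss_tot = float(((yy - yy.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0

    if trees:
        offsets = {trees[0]: 0.0}
        base = 3 if form == "quadratic" else 2
        for i, t in enumerate(trees[1:]):
            offsets[t] = float(coef[base + i])

    if form == "linear":
        coefficients = {"intercept": float(coef[0]), "slope": float(coef[1])}
        q10 = None
    elif form == "quadratic":
        coefficients = {
            "intercept": float(coef[0]),
            "b1": float(coef[1]),
            "b2": float(coef[2]),
        }
        q10 = None
    else:
        k = float(coef[1])
        coefficients = {"log_amplitude0": float(coef[0]), "amplitude0": float(np.exp(coef[0])), "k": k}
        q10 = q10_from_rate(k)

    return ClimateResponseFit(
        predictor=predictor,
        form=form,
        coefficients=coefficients,
        scope=scope,
        n_days=len(df),
        r_squared=r2,
        q10=q10,
        tree_offsets=offsets,
    )


def quadratic_vertex(fit: ClimateResponseFit) -> float:
    """Abscissa of the quadratic response's extremum (saturation point)."""
    if fit.form != "quadratic":
        raise DomainError("vertex defined for quadratic fits only")
    b1, b2 = fit.coefficients["b1"], fit.coefficients["b2"]
    if b2 == 0:
        raise DomainError("degenerate quadratic (b2 = 0)")
    return -b1 / (2.0 * b2)
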