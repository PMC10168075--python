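"""Derived series: inner-bark thickness, seasonal detrending, VPD.

Inner bark thickness is the pointwise difference between the trunk-surface
radius (dendrometer on the living bark) and the xylem-surface radius
(dendrometer on the wood).  Because both sensors share one frame, thermal
expansion of the frame cancels in the difference and no temperature
correction is applied.

The raw thickness mixes three signals: slow cambial growth (µm/day drift),
the diurnal shrink/swell cycle, and noise.  Seasonal-trend decomposition by
loess (period = one day = 144 ten-minute samples) separates the growth trend
from everything else; the analysis downstream runs on the detrended series
(raw minus trend, so the decomposition is exact by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.seasonal import STL

from .errors import AlignmentError, DomainError, LengthError
from .timeseries_io import Flag, GriddedSeries, SAMPLES_PER_DAY

# Saturation vapour pressure constants (Buck-type formulation, kPa over °C):
# e_s(T) = A * exp(B*T / (C + T)).  Fixed so results are bit-reproducible.
ES_A = 0.61365
ES_B = 17.502
ES_C = 240.97


def saturation_vapour_pressure(t_air):
    """Saturation vapour pressure e_s in kPa at air temperature t_air (°C)."""
    t = np.asarray(t_air, dtype=float)
    return ES_A * np.exp(ES_B * t / (ES_C + t))


def vpd_from_t_rh(t_air, rh):
    """Vapour pressure deficit (kPa) from air temperature (°C) and RH (%).

    VPD = e_s(T) * (1 - RH/100); RH must lie in [0, 100].
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise DomainError("relative humidity must be within [0, 100] %")
    out = saturation_vapour_pressure(t_air) * (1.0 - rh_arr / 100.0)
    if np.isscalar(rh) and np.isscalar(t_air):
        return float(out)
    return out


def bark_thickness(trunk_radius: GriddedSeries, xylem_radius: GriddedSeries) -> GriddedSeries:
    """Inner bark thickness = trunk radius − xylem radius, flag-propagating.

    A sample is missing when either input is invalid; discarded dominates
    missing, interpolated dominates ok.
    """
    if not trunk_radius.same_grid(xylem_radius):
        raise AlignmentError("trunk and xylem series must share one grid")
    vals = trunk_radius.values - xylem_radius.values
    flags = np.maximum(trunk_radius.flags, xylem_radius.flags)
    return GriddedSeries(trunk_radius.timestamps, vals, flags, unit=trunk_radius.unit or "µm")


@dataclass
class BarkThicknessSeries:
    """Exact decomposition raw = trend + detrended at every valid sample."""

    raw: GriddedSeries
    trend: GriddedSeries
    detrended: GriddedSeries


def detrend_seasonal(
    thickness: GriddedSeries,
    period: int = SAMPLES_PER_DAY,
    trend_days: float = 7.0,
    seasonal: int = 2001,
    robust: bool = True,
) -> BarkThicknessSeries:
    """Remove the seasonal (cambial growth) trend from a thickness series.

    Loess-based seasonal-trend decomposition with daily period.  The loess
    trend window defaults to 7 days, wide enough that the trend captures the
    µm/day growth drift but none of the diurnal cycle; the seasonal smoother
    window is effectively unbounded (periodic-like).  Missing samples are
    bridged by linear interpolation for the decomposition only and restored
    to NaN afterwards.  Returned ``detrended`` is raw − trend, exactly.
    """
    thickness.require_grid()
    valid = thickness.valid
    if valid.sum() < 3 * period:
        raise LengthError(
            f"detrending needs at least 3 full periods ({3 * period} samples), "
            f"got {int(valid.sum())} valid"
        )
    y = thickness.values.copy()
    n = len(y)
    idx = np.arange(n)
    y_filled = y.copy()
    y_filled[~valid] = np.interp(idx[~valid], idx[valid], y[valid])

    trend_window = int(trend_days * period)
    if trend_window % 2 == 0:
        trend_window += 1
    if seasonal % 2 == 0:
        seasonal += 1
    stl = STL(y_filled, period=period, seasonal=seasonal, trend=trend_window, robust=robust)
    # a few robustness sweeps suffice for dendrometer spikes; the statsmodels
    # default (15 outer iterations) costs 5x the runtime for no visible change
    res = stl.fit(outer_iter=3) if robust else stl.fit()
    trend_vals = np.asarray(res.trend, dtype=float)

    trend = GriddedSeries(
        thickness.timestamps,
        trend_vals,
        np.full(n, Flag.OK, dtype=np.int8),
        unit=thickness.unit,
    )
    det_vals = thickness.values - trend_vals
    detrended = GriddedSeries(
        thickness.timestamps, det_vals, thickness.flags.copy(), unit=thickness.unit
    )
    return BarkThicknessSeries(raw=thickness, trend=trend, detrended=detrended)
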