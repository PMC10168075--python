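"""Phloem hydrostatic pressure from sap osmolality (van 't Hoff) and gradients.

The hydrostatic pressure in the inner bark (turgor plus gravity) is
estimated by adding the osmotic pressure of the expressed sap to the xylem
water potential recorded at sampling time:

    P_H = Ψ_X + C_S · R · T

with C_S the sap osmotic concentration in mol/L (approximated by the
measured osmolality in mol/kg, no density correction), R = 0.008314
L MPa mol⁻¹ K⁻¹, and T in Kelvin (default 298.15 K, the osmometer's
operating temperature).  The axial gradient of P_H (upper − lower position
along the trunk) is the driving force for Münch pressure flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, LengthError, PairingError

#: universal gas constant, L MPa mol⁻¹ K⁻¹
R_GAS = 0.008314

#: default temperature for osmotic pressure (K)
T_DEFAULT = 298.15


@dataclass
class PressureEstimate:
    p_h: float  # MPa
    psi_term: float  # MPa (= Ψ_X)
    osmotic_term: float  # MPa (= C_S R T ≥ 0)


def hydrostatic_pressure(
    psi_x: float, osmolality: float, temperature_k: float = T_DEFAULT
) -> PressureEstimate:
    """P_H = Ψ_X + C_S·R·T (MPa) for one sample."""
    if temperature_k <= 0:
        raise DomainError("temperature must be positive (Kelvin)")
    osmotic = osmolality * R_GAS * temperature_k
    return PressureEstimate(p_h=psi_x + osmotic, psi_term=psi_x, osmotic_term=osmotic)


def axial_gradient(upper: float, lower: float) -> float:
    """Upper − lower difference (positive = downward-driving gradient)."""
    if upper is None or lower is None or not (np.isfinite(upper) and np.isfinite(lower)):
        raise PairingError("axial gradient requires a matched upper/lower pair")
    return upper - lower


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def fit_ph_vs_psi(psi_x, p_h) -> LinearFit:
    """Ordinary least squares of hydrostatic pressure on xylem potential."""
    x = np.asarray(psi_x, dtype=float)
    y = np.asarray(p_h, dtype=float)
    if len(x) < 3:
        raise LengthError("need at least 3 (Ψ_X, P_H) points")
    if np.ptp(x) == 0:
        raise DomainError("all Ψ_X identical; regression singular")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return LinearFit(float(slope), float(intercept), r2, len(x))


def zero_turgor_psi(slope: float, intercept: float) -> float:
    """Ψ_X at which the regression predicts zero hydrostatic pressure."""
    if slope == 0:
        raise DomainError("zero slope: no finite zero-pressure potential")
    return -intercept / slope


def equivalent_radius_change(delta_r_um: float, d_source_cm: float, d_target_cm: float) -> float:
    """Radius change at one stem diameter equivalent (in water volume per
    unit stem length, thin-annulus approximation V ∝ d·Δr) to a change at
    another diameter."""
    if d_source_cm <= 0 or d_target_cm <= 0:
        raise DomainError("stem diameters must be positive")
    return delta_r_um * d_source_cm / d_target_cm


def bulk_elastic_modulus(delta_psi_mpa: float, relative_water_change: float) -> float:
    """Bulk elastic modulus ε = |ΔΨ| / (ΔW/W) implied by a potential drop
    accompanying a relative water-content change."""
    if relative_water_change <= 0:
        raise DomainError("relative water change must be positive")
    return abs(delta_psi_mpa) / relative_water_change


REQUIRED_SAMPLE_COLUMNS = [
    "tree_id",
    "date",
    "time_class",
    "position",
    "osmolality",
    "water_content",
    "psi_x",
]


def summarize_osmotics(samples: pd.DataFrame, temperature_k: float = T_DEFAULT) -> pd.DataFrame:
    """Date × time-of-day × position summary of the osmotic sampling campaign.

    Per tree, replicate osmolalities are averaged and the hydrostatic
    pressure computed from that tree's Ψ_X at sampling; cell means and SDs
    are then taken over trees.  Cells with a single tree get an undefined
    (NaN) SD and are flagged.
    """
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise DomainError(f"osmotic sample table lacks columns {missing}")
    df = samples.copy()
    if "temperature_k" not in df.columns:
        df["temperature_k"] = temperature_k
    bad = df[(df["osmolality"] <= 0) | (df["water_content"] <= 0) | (df["psi_x"] > 0)]
    if len(bad):
        raise DomainError(
            "invalid osmotic samples (osmolality/water content must be > 0, Ψ_X ≤ 0)"
        )

    per_tree = (
        df.groupby(["date", "time_class", "position", "tree_id"], as_index=False)
        .agg(
            osmolality=("osmolality", "mean"),
            water_content=("water_content", "mean"),
            psi_x=("psi_x", "mean"),
            temperature_k=("temperature_k", "mean"),
            n_replicates=("osmolality", "size"),
        )
    )
    per_tree["p_h"] = [
        hydrostatic_pressure(r.psi_x, r.osmolality, r.temperature_k).p_h
        for r in per_tree.itertuples()
    ]

    cells = (
        per_tree.groupby(["date", "time_class", "position"], as_index=False)
        .agg(
            osmolality_mean=("osmolality", "mean"),
            osmolality_sd=("osmolality", "std"),
            water_content_mean=("water_content", "mean"),
            water_content_sd=("water_content", "std"),
            p_h_mean=("p_h", "mean"),
            p_h_sd=("p_h", "std"),
            n_trees=("tree_id", "nunique"),
        )
    )
    cells["single_tree"] = cells["n_trees"] < 2
    return cells


def gradient_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Axial (upper − lower) osmolality and pressure gradients per date × time."""
    rows = []
    for (date, tc), grp in summary.groupby(["date", "time_class"]):
        pos = {p: r for p, r in zip(grp["position"], grp.itertuples())}
        if "upper" not in pos or "lower" not in pos:
            raise PairingError(f"unmatched upper/lower pair for {date} {tc}")
        rows.append(
            {
                "date": date,
                "time_class": tc,
                "osmolality_gradient": axial_gradient(
                    pos["upper"].osmolality_mean, pos["lower"].osmolality_mean
                ),
                "p_h_gradient": axial_gradient(pos["upper"].p_h_mean, pos["lower"].p_h_mean),
            }
        )
    return pd.DataFrame(rows)
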