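"""Synthetic field campaigns with known ground truth.

Generates everything the analysis consumes — climate at 10-min cadence,
xylem water potential forced by radiation and VPD, dual-dendrometer pairs
whose bark thickness follows the capacitor recursion plus an injected turgor
waveform, growth trend and AR(1) sensor noise, and dawn/afternoon osmotic
sampling tables — so every downstream stage can be validated by parameter
recovery at desk scale.

Default parameter values emulate the field conditions of a late-summer
campaign on mature hinoki cypress: xylem potential bounded in (−1, 0] MPa
with daily maxima near zero, radial conductances αβ of 4.8 (upper) and 1.8
(lower) µm MPa⁻¹ step⁻¹ (i.e. 8×10⁻⁹ and 3×10⁻⁹ m MPa⁻¹ s⁻¹), a ~100-min
exchange time constant (α = 0.1 step⁻¹), a night-rising osmotic (turgor)
forcing, growth of 1–8 µm/day, and AR(1) sensor noise at the dendrometer's
resolution floor.

All generators are pure functions of (parameters, seed): one global seed
fans out into named substreams, so adding a stream never perturbs others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError
from .preprocessing import vpd_from_t_rh
from .timeseries_io import Flag, GriddedSeries, SAMPLES_PER_DAY, STEP_SECONDS


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic named substream of the global seed."""
    h = hashlib.sha256(("/".join(str(k) for k in keys)).encode()).digest()
    words = [int.from_bytes(h[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng([int(seed) % 2**31, *words])


# ---------------------------------------------------------------------------
# turgor waveform
# ---------------------------------------------------------------------------


@dataclass
class TurgorWaveform:
    """Daily-periodic osmotic (turgor) forcing of bark thickness.

    ``values`` is the equilibrium thickness offset (µm) that the varying
    solute content of the phloem would produce at rest.  The osmotically
    drawn water enters through the same radial conductance as the
    ψ_X-driven exchange, so the realized thickness contribution is this
    waveform passed through the capacitor's first-order dynamics (gain
    ≈ α/√(α² + ω²) at the daily frequency).

    The default ``night_rise`` shape increases through the night to a
    mid-morning maximum and fluctuates mildly during the day.
    """

    amplitude: float = 38.0  # µm nominal
    shape: str = "night_rise"  # night_rise | sinusoid | ramp_plateau
    peak_hour: float = 9.0
    day_fluctuation: float = 0.05

    def values(self, hours: np.ndarray) -> np.ndarray:
        h = np.asarray(hours, dtype=float) % 24.0
        base = 0.5 * (1.0 + np.cos(2.0 * np.pi * (h - self.peak_hour) / 24.0))
        if self.shape == "sinusoid":
            return self.amplitude * base
        if self.shape == "night_rise":
            fluct = self.day_fluctuation * np.sin(2.0 * np.pi * 3.0 * h / 24.0)
            return self.amplitude * (base + fluct * base)
        if self.shape == "ramp_plateau":
            trough = (self.peak_hour + 11.0) % 24.0  # rise starts in the evening
            rise_len = (self.peak_hour - trough) % 24.0
            since = (h - trough) % 24.0
            out = np.where(
                since <= rise_len,
                since / rise_len,
                np.maximum(0.0, 1.0 - (since - rise_len) / (24.0 - rise_len)),
            )
            return self.amplitude * out
        raise DomainError(f"unknown turgor waveform shape {self.shape!r}")

    def realized_amplitude(self) -> float:
        h = np.arange(SAMPLES_PER_DAY) * STEP_SECONDS / 3600.0
        v = self.values(h)
        return float(v.max() - v.min())


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class SensorTruth:
    """Per-sensor-pair generating parameters."""

    tree_id: str
    position: str  # upper | lower
    alpha: float = 0.1  # step⁻¹
    beta: float = 48.0  # µm MPa⁻¹
    gamma: float = 0.0  # µm step⁻¹ (drift beyond growth; growth is explicit)
    turgor: TurgorWaveform = field(default_factory=TurgorWaveform)
    growth_um_day: float = 5.0  # trunk radius growth at the sensor
    bark_base_um: float = 5000.0
    xylem_diurnal_um_mpa: float = 12.0  # xylem shrinkage per MPa of tension
    psi_scale: float = 0.75  # midday ψ depth multiplier
    phi_noise: float = 0.6  # AR(1) coefficient of thickness sensor noise
    # dendrometer noise at the datalogger resolution floor (0.022 µm);
    # ψ noise is the psychrometer's 10-min repeatability, not its absolute
    # accuracy (slow offsets cancel in the midnight-anchored differences)
    sigma_noise_um: float = 0.01
    sigma_psi_mpa: float = 0.001
    height_m: float = 1.5
    diameter_cm: float = 30.0

    @property
    def alpha_beta(self) -> float:
        return self.alpha * self.beta


@dataclass
class SimulationTruth:
    seed: int
    kind: str
    days: int
    start: str
    sensors: list  # list[SensorTruth]
    osmolality_profile: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        for s in d["sensors"]:
            s["alpha_beta"] = s["alpha"] * s["beta"]
            s["turgor"]["realized_amplitude"] = TurgorWaveform(**{
                k: v for k, v in s["turgor"].items() if k != "realized_amplitude"
            }).realized_amplitude()
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

CLIMATE_DEFAULTS = {
    "solar_peak_wm2": 900.0,  # clear-sky midday global radiation
    "t_mean_c": 24.0,  # campaign mean air temperature
    "t_day_sd": 2.5,  # day-to-day SD of the daily mean
    "t_diurnal_base": 4.0,  # diurnal half-amplitude, cloudy day
    "t_diurnal_sunny": 4.0,  # extra half-amplitude on clear days
    "rain_probability": 0.15,
    "rain_mm_mean": 8.0,
    "cloud_beta": (5.0, 1.5),  # Beta(a, b) day-scale clear-sky fraction
    # within-day cloud passage: AR(1) attenuation of the solar beam; field
    # radiation is broadband, not a smooth arch
    "cloud_ar": 0.85,
    "cloud_sd": 0.35,
}


def simulate_climate(
    days: int, seed: int, start: str = "2019-08-01", params: dict | None = None
) -> pd.DataFrame:
    """10-min climate record: global radiation, T_A, RH, rainfall, VPD."""
    if days < 1:
        raise DomainError("need at least one day")
    p = dict(CLIMATE_DEFAULTS)
    if params:
        p.update(params)
    rng = substream(seed, "climate")
    n = days * SAMPLES_PER_DAY
    ts = pd.date_range(start, periods=n, freq=f"{STEP_SECONDS}s")
    h = (ts.hour + ts.minute / 60.0).to_numpy()
    day_idx = np.repeat(np.arange(days), SAMPLES_PER_DAY)

    a, b = p["cloud_beta"]
    cloudfrac = rng.beta(a, b, size=days)
    rain_day = rng.random(days) < p["rain_probability"]
    cloudfrac[rain_day] *= 0.3
    t_mean = p["t_mean_c"] + rng.normal(0.0, p["t_day_sd"], size=days)

    sun = np.maximum(0.0, np.sin(np.pi * (h - 6.0) / 12.0)) ** 1.2
    # cloud passage: stationary AR(1) log-attenuation, stronger on cloudy days
    ar, sd = p["cloud_ar"], p["cloud_sd"]
    z = np.empty(n)
    z[0] = rng.normal(0.0, sd / np.sqrt(1.0 - ar**2))
    innov = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        z[t] = ar * z[t - 1] + innov[t - 1]
    passage = np.exp(-np.abs(z) * (1.5 - cloudfrac[day_idx]))
    rg = p["solar_peak_wm2"] * cloudfrac[day_idx] * sun * passage

    t_amp = p["t_diurnal_base"] + p["t_diurnal_sunny"] * cloudfrac
    t_a = t_mean[day_idx] - t_amp[day_idx] * np.cos(2.0 * np.pi * (h - 14.5) / 24.0)

    rh_base = 52.0 + 28.0 * (1.0 - cloudfrac)
    rh_base[rain_day] = 95.0
    rh = rh_base[day_idx] + 18.0 * np.cos(2.0 * np.pi * (h - 14.5) / 24.0)
    rh = rh + rng.normal(0.0, 1.5, size=n)
    rh = np.clip(rh, 5.0, 100.0)

    rainfall = np.zeros(n)
    for d in np.flatnonzero(rain_day):
        total = rng.lognormal(np.log(p["rain_mm_mean"]), 0.6)
        ticks = rng.integers(0, SAMPLES_PER_DAY, size=12)
        w = rng.random(12)
        w /= w.sum()
        np.add.at(rainfall, d * SAMPLES_PER_DAY + ticks, total * w)

    return pd.DataFrame(
        {
            "timestamp": ts,
            "rg_wm2": rg,
            "t_a_c": t_a,
            "rh_pct": rh,
            "rainfall_mm": rainfall,
            "vpd_kpa": vpd_from_t_rh(t_a, rh),
        }
    )


# ---------------------------------------------------------------------------
# xylem water potential
# ---------------------------------------------------------------------------

PSI_DEFAULTS = {
    "rg_weight": 0.45,
    "vpd_weight": 0.55,
    "vpd_ref_kpa": 3.5,
    # xylem tension follows transpiration quickly (tension propagates along
    # the water column within minutes), so drying tracks the forcing fast
    "smooth_rate": 0.5,
    # nocturnal rewetting is slower than transpiration-driven drying: the
    # stem refills through the same finite conductances, so ψ stays below
    # zero well into the night and the daily maximum sits just before dawn
    "recovery_rate": 0.08,
    "day_variability": 0.2,  # relative day-to-day spread of the depth
    "floor_mpa": -1.0,
}


def simulate_psi(
    climate: pd.DataFrame,
    seed: int,
    scale: float = 0.75,
    params: dict | None = None,
    stream: str = "psi",
) -> GriddedSeries:
    """Latent xylem water potential forced by radiation and VPD (MPa).

    ψ relaxes first-order toward a target −scale·g(R_G, VPD), recovers to
    ~0 overnight, and is clipped to the physiological floor of −1 MPa.
    """
    p = dict(PSI_DEFAULTS)
    if params:
        p.update(params)
    rng = substream(seed, stream)
    n = len(climate)
    days = n // SAMPLES_PER_DAY
    day_idx = np.repeat(np.arange(days + 1), SAMPLES_PER_DAY)[:n]
    depth = scale * (1.0 + p["day_variability"] * rng.standard_normal(days + 1))
    depth = np.clip(depth, 0.05, None)

    rg = climate["rg_wm2"].to_numpy(float)
    vpd = climate["vpd_kpa"].to_numpy(float)
    forcing = p["rg_weight"] * rg / 900.0 + p["vpd_weight"] * vpd / p["vpd_ref_kpa"]
    # at night radiation is zero and VPD small: ψ relaxes toward ~0
    target = -depth[day_idx] * forcing * (rg > 1.0)
    target = np.clip(target, p["floor_mpa"], 0.0)

    psi = np.zeros(n)
    r_dry, r_wet = p["smooth_rate"], p["recovery_rate"]
    psi[0] = target[0]
    for t in range(n - 1):
        r = r_dry if target[t] < psi[t] else r_wet
        psi[t + 1] = psi[t] + r * (target[t] - psi[t])
    psi = np.clip(psi, p["floor_mpa"], 0.0)
    return GriddedSeries(
        pd.DatetimeIndex(climate["timestamp"]),
        psi,
        np.full(n, Flag.OK, dtype=np.int8),
        unit="MPa",
    )


def observe_psi(psi_latent: GriddedSeries, truth: SensorTruth, seed: int) -> GriddedSeries:
    """Latent ψ plus psychrometer observation noise, kept ≤ 0."""
    rng = substream(seed, "psi-noise", truth.tree_id, truth.position)
    vals = psi_latent.values + rng.normal(0.0, truth.sigma_psi_mpa, size=len(psi_latent))
    vals = np.clip(vals, -1.0, 0.0)
    return GriddedSeries(psi_latent.timestamps, vals, psi_latent.flags.copy(), unit="MPa")


# ---------------------------------------------------------------------------
# dendrometer pair
# ---------------------------------------------------------------------------


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    if sigma == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma / np.sqrt(max(1.0 - phi**2, 1e-12)))
    innov = rng.normal(0.0, sigma, size=n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov[t - 1]
    return e


def simulate_dendrometer_pair(
    psi: GriddedSeries, truth: SensorTruth, seed: int
) -> tuple[GriddedSeries, GriddedSeries, GriddedSeries]:
    """Trunk- and xylem-radius series implied by ψ and the ground truth.

    Bark thickness integrates the capacitor recursion driven by the latent
    ψ with the osmotic (turgor) waveform as an additional equilibrium
    forcing inside the dynamics — osmotically drawn water crosses the same
    radial conductance — plus a linear growth ramp and AR(1) observation
    noise.  The xylem radius carries its own small diurnal signal and
    independent noise; trunk radius = xylem radius + thickness.

    Returns ``(trunk, xylem, turgor_component)`` where the last is the
    realized (dynamics-filtered) turgor contribution to thickness: the
    difference between the thickness trajectories with and without the
    osmotic forcing.  It is the ground truth the observed-minus-predicted
    residual should recover.
    """
    rng = substream(seed, "dendro", truth.tree_id, truth.position)
    n = len(psi)
    ts = psi.timestamps
    hours = (ts.hour + ts.minute / 60.0).to_numpy()
    pvals = psi.values
    s_pi = truth.turgor.values(hours)

    # capacitor dynamics toward equilibrium thickness base + β·ψ + s_π
    a, b = truth.alpha, truth.beta
    cap = np.empty(n)
    cap0 = np.empty(n)  # same dynamics without the osmotic forcing
    cap[0] = truth.bark_base_um + b * pvals[0] + s_pi[0]
    cap0[0] = truth.bark_base_um + b * pvals[0]
    for t in range(n - 1):
        eq = truth.bark_base_um + b * pvals[t]
        cap[t + 1] = cap[t] + a * (eq + s_pi[t] - cap[t]) + truth.gamma
        cap0[t + 1] = cap0[t] + a * (eq - cap0[t]) + truth.gamma

    t_steps = np.arange(n)
    bark_growth = 0.3 * truth.growth_um_day * t_steps / SAMPLES_PER_DAY
    xylem_growth = 0.7 * truth.growth_um_day * t_steps / SAMPLES_PER_DAY

    thickness_obs = cap + bark_growth + _ar1_noise(
        rng, n, truth.phi_noise, truth.sigma_noise_um
    )
    xylem = (
        10000.0
        + xylem_growth
        + truth.xylem_diurnal_um_mpa * pvals
        + _ar1_noise(rng, n, truth.phi_noise, 0.5 * truth.sigma_noise_um)
    )
    trunk = xylem + thickness_obs
    flags = np.full(n, Flag.OK, dtype=np.int8)
    return (
        GriddedSeries(ts, trunk, flags, unit="µm"),
        GriddedSeries(ts, xylem, flags.copy(), unit="µm"),
        GriddedSeries(ts, cap - cap0, flags.copy(), unit="µm"),
    )


# ---------------------------------------------------------------------------
# osmotic sampling
# ---------------------------------------------------------------------------

OSMOLALITY_PROFILE = {
    # mol/kg means by position × season; winter values higher (cold
    # acclimation), upper above lower at all times
    "summer": {"upper": 0.46, "lower": 0.39},
    "winter": {"upper": 0.61, "lower": 0.47},
}

WATER_CONTENT_PROFILE = {"summer": 1.4, "winter": 1.3}

SAMPLING_HOURS = {"dawn": 5.5, "early_afternoon": 15.0}


def _season(date: pd.Timestamp) -> str:
    return "winter" if date.month in (12, 1, 2) else "summer"


def simulate_osmotic_samples(
    truth: SimulationTruth,
    psi_by_sensor: dict,
    dates,
    seed: int,
    replicate_sd: float = 0.03,
    tree_sd: float = 0.02,
    n_replicates: int = 2,
    profile: dict | None = None,
) -> pd.DataFrame:
    """Dawn/early-afternoon osmolality sampling table with concurrent ψ_X."""
    prof = profile or truth.osmolality_profile or OSMOLALITY_PROFILE
    rng = substream(seed, "osmotic")
    trees = sorted({s.tree_id for s in truth.sensors})
    positions = sorted({s.position for s in truth.sensors})
    rows = []
    for date in dates:
        date = pd.Timestamp(date).normalize()
        season = _season(date)
        for time_class, hour in SAMPLING_HOURS.items():
            t_sample = date + pd.Timedelta(hours=hour)
            for position in positions:
                for tree in trees:
                    mu = prof[season][position] + rng.normal(0.0, tree_sd)
                    psi_series = psi_by_sensor.get((tree, position))
                    psi_val = 0.0
                    if psi_series is not None:
                        m = psi_series.timestamps == t_sample
                        if m.any():
                            psi_val = float(psi_series.values[m][0])
                    for _ in range(n_replicates):
                        rows.append(
                            {
                                "tree_id": tree,
                                "date": date.date().isoformat(),
                                "time_class": time_class,
                                "position": position,
                                "osmolality": max(
                                    0.05, mu + rng.normal(0.0, replicate_sd)
                                ),
                                "water_content": max(
                                    0.5,
                                    WATER_CONTENT_PROFILE[season]
                                    + rng.normal(0.0, 0.15),
                                ),
                                "psi_x": min(0.0, psi_val),
                                "temperature_k": 298.15,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# campaigns and fixtures
# ---------------------------------------------------------------------------

#: tree geometry emulating a mature even-aged stand: (tree, position) →
#: (sensor height m, trunk diameter cm, growth µm/day, β multiplier)
TREE_LAYOUT = {
    ("1", "lower"): (1.5, 29.2, 2.4, 1.0),
    ("1", "upper"): (17.1, 13.7, 7.1, 1.0),
    ("2", "lower"): (1.7, 18.7, 1.0, 0.8),
    ("2", "upper"): (18.6, 7.4, 4.2, 0.8),
    ("3", "lower"): (1.3, 53.5, 8.3, 1.25),
    ("3", "upper"): (19.5, 14.2, 3.4, 1.25),
}

POSITION_DEFAULTS = {
    # β set so αβ matches field conductance medians (4.8 / 1.8 µm MPa⁻¹
    # step⁻¹).  The osmotic forcing amplitude is kept a minor within-day
    # perturbation (~15-20% of the ψ-driven amplitude): a forcing of the
    # same order as the ψ-driven signal renders the per-day regression
    # unidentifiable (the state is the filtered forcing), which is a
    # documented limitation of the residual method, not of this generator.
    # ψ depth scales put sunny-day minima at −0.6..−0.8 MPa (never < −1),
    # slightly shallower at the trunk base than at the crown base
    "upper": {"beta": 48.0, "turgor": 6.0, "psi_scale": 1.5},
    "lower": {"beta": 18.0, "turgor": 3.0, "psi_scale": 1.2},
}

KINDS = {"tiny": 3, "paper_scale": 9, "stress": 9}


@dataclass
class SensorData:
    truth: SensorTruth
    psi_latent: GriddedSeries
    psi: GriddedSeries
    trunk: GriddedSeries
    xylem: GriddedSeries
    turgor_component: GriddedSeries  # realized turgor contribution (truth)


@dataclass
class Campaign:
    kind: str
    seed: int
    start: str
    days: int
    climate: pd.DataFrame
    sensors: dict  # (tree_id, position) → SensorData
    osmotic_samples: pd.DataFrame
    truth: SimulationTruth


def default_sensor_truths(kind: str) -> list[SensorTruth]:
    layout = TREE_LAYOUT
    if kind == "tiny":
        layout = {k: v for k, v in TREE_LAYOUT.items() if k[0] == "1"}
    elif kind == "stress":
        layout = {k: v for k, v in TREE_LAYOUT.items() if k[0] == "1"}
    truths = []
    for (tree, position), (h, d, growth, mult) in sorted(layout.items()):
        pos = POSITION_DEFAULTS[position]
        truths.append(
            SensorTruth(
                tree_id=tree,
                position=position,
                beta=pos["beta"] * mult,
                turgor=TurgorWaveform(amplitude=pos["turgor"] * mult),
                growth_um_day=growth,
                psi_scale=pos["psi_scale"],
                height_m=h,
                diameter_cm=d,
            )
        )
    return truths


def simulate_campaign(
    kind: str = "paper_scale",
    seed: int = 0,
    days: int | None = None,
    start: str = "2019-08-01",
    sensor_truths: list | None = None,
    climate_params: dict | None = None,
) -> Campaign:
    """Generate a full synthetic campaign of the requested kind."""
    if kind not in KINDS:
        raise DomainError(f"unknown fixture kind {kind!r}; choose from {sorted(KINDS)}")
    days = days or KINDS[kind]
    truths = sensor_truths or default_sensor_truths(kind)

    cp = dict(climate_params or {})
    if kind == "stress":
        cp.setdefault("rain_probability", 0.35)
    climate = simulate_climate(days, seed, start=start, params=cp or None)

    sensors = {}
    for truth in truths:
        stream = f"psi/{truth.tree_id}/{truth.position}"
        psi_lat = simulate_psi(climate, seed, scale=truth.psi_scale, stream=stream)
        if kind == "stress" and days >= 7:
            # one near-flat ψ day (deep overcast): provokes a rejected fit
            vals = psi_lat.values.copy()
            lo, hi = 5 * SAMPLES_PER_DAY, 6 * SAMPLES_PER_DAY
            vals[lo:hi] *= 0.02
            psi_lat = GriddedSeries(psi_lat.timestamps, vals, psi_lat.flags, psi_lat.unit)
        psi_obs = observe_psi(psi_lat, truth, seed)
        trunk, xylem, turgor_comp = simulate_dendrometer_pair(psi_lat, truth, seed)
        if kind == "stress":
            trunk, xylem, psi_obs = _stress_dropouts(truth, trunk, xylem, psi_obs)
        sensors[(truth.tree_id, truth.position)] = SensorData(
            truth=truth,
            psi_latent=psi_lat,
            psi=psi_obs,
            trunk=trunk,
            xylem=xylem,
            turgor_component=turgor_comp,
        )

    sim_truth = SimulationTruth(
        seed=seed,
        kind=kind,
        days=days,
        start=start,
        sensors=truths,
        osmolality_profile=OSMOLALITY_PROFILE,
    )
    sample_dates = [pd.Timestamp(start) + pd.Timedelta(days=min(2, days - 1))]
    if days >= 8:
        sample_dates.append(pd.Timestamp(start) + pd.Timedelta(days=7))
    osmotic = simulate_osmotic_samples(
        sim_truth,
        {k: v.psi for k, v in sensors.items()},
        sample_dates,
        seed,
    )
    return Campaign(
        kind=kind,
        seed=seed,
        start=start,
        days=days,
        climate=climate,
        sensors=sensors,
        osmotic_samples=osmotic,
        truth=sim_truth,
    )


def _stress_dropouts(truth, trunk, xylem, psi):
    """Punch sensor gaps into a stress campaign (upper sensors only)."""
    if truth.position != "upper":
        return trunk, xylem, psi

    def punch(series, lo, hi):
        flags = series.flags.copy()
        vals = series.values.copy()
        flags[lo:hi] = Flag.MISSING
        vals[lo:hi] = np.nan
        return GriddedSeries(series.timestamps, vals, flags, series.unit)

    # 2-h dendrometer gap on day 3 and a 1.5-day psychrometer dropout
    lo = 3 * SAMPLES_PER_DAY + 60
    trunk = punch(trunk, lo, lo + 12)
    plo = 7 * SAMPLES_PER_DAY
    psi = punch(psi, plo, plo + SAMPLES_PER_DAY + SAMPLES_PER_DAY // 2)
    return trunk, xylem, psi


def make_fixture(kind: str, outdir, seed: int = 0) -> Path:
    """Write a complete input-file bundle plus ground-truth manifest.

    Emits the climate table, one trunk/xylem/ψ file per sensor pair, the
    osmotic sampling table, ``truth.json``, and a ready-to-run pipeline
    ``config.yaml``.  Deterministic per (kind, seed).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    camp = simulate_campaign(kind, seed=seed)

    camp.climate.to_csv(out / "climate.csv", index=False)
    sensor_entries = []
    for (tree, position), sd in sorted(camp.sensors.items()):
        stem = f"tree{tree}_{position}"
        sd.trunk.write(out / f"{stem}_trunk.csv")
        sd.xylem.write(out / f"{stem}_xylem.csv")
        sd.psi.write(out / f"{stem}_psi.csv")
        sensor_entries.append(
            {
                "tree_id": tree,
                "position": position,
                "trunk": f"{stem}_trunk.csv",
                "xylem": f"{stem}_xylem.csv",
                "psi": f"{stem}_psi.csv",
                "height_m": sd.truth.height_m,
                "diameter_cm": sd.truth.diameter_cm,
            }
        )
    camp.osmotic_samples.to_csv(out / "osmotic_samples.csv", index=False)
    (out / "truth.json").write_text(camp.truth.to_json(), encoding="utf-8")

    config = {
        "seed": seed,
        "input_dir": ".",
        "output_dir": "results",
        "climate": "climate.csv",
        "osmotic_samples": "osmotic_samples.csv",
        "sensors": sensor_entries,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False), encoding="utf-8")
    return out
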