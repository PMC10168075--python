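"""End-to-end orchestration: files in, tidy tables and a run manifest out.

Stages: regularize → bark thickness → seasonal detrend → daily
amplitude/timing/lag metrics → per-day exchange-model fits and turgor
signals → climate-response fits → osmotics summary → report.  Every stage
is also reachable through the library API; the pipeline only wires them
together, applies the day-screening rules (rainy days and days with missing
samples are excluded from model fitting) and records what it did.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diurnal_metrics import daily_extrema, fit_climate_response, xcorr_lag
from .errors import (
    ConfigError,
    InnerbarkError,
    LengthError,
    UndefinedCorrelationError,
)
from .exchange_model import (
    accept_fit,
    build_design,
    fit_gls_ar1,
    predict_thickness,
    radial_conductance_si,
    turgor_signal,
)
from .osmotics import gradient_table, summarize_osmotics
from .preprocessing import bark_thickness, detrend_seasonal, vpd_from_t_rh
from .timeseries_io import (
    GriddedSeries,
    SAMPLES_PER_DAY,
    STEP_SECONDS,
    discard_interval,
    read_series,
    regularize,
)

DEFAULT_CONFIG = {
    "seed": 0,
    "input_dir": ".",
    "output_dir": "results",
    "climate": "climate.csv",
    "osmotic_samples": None,
    "sensors": [],  # list of {tree_id, position, trunk, xylem, psi, ...}
    "discards": [],  # list of {sensor, series, start, end, reason}
    "grid": {"interval_s": STEP_SECONDS, "max_gap_s": 1800},
    "stl": {"period": SAMPLES_PER_DAY, "trend_window_days": 7.0, "seasonal": 2001, "robust": True},
    "metrics": {"min_valid_fraction": 0.8, "max_lag_minutes": 720},
    "fit": {
        "min_steps": 48,
        "phi_step": 0.01,
        "phi_max": 0.98,
        "rain_mm_threshold": 1.0,
        "reject": {
            "max_abs_phi": 0.99,
            "max_rel_se_c1": 1.0,
            "min_r2_prediction": 0.0,
        },
    },
    "climate_response": {"min_days": 10},
    "osmotics": {"temperature_k": 298.15},
}


def _merge_validated(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_validated(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration; every knob has a documented default."""

    options: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))
    base_dir: Path = Path(".")

    @classmethod
    def from_dict(cls, d: dict, base_dir=".") -> "RunConfig":
        return cls(options=_merge_validated(DEFAULT_CONFIG, d), base_dir=Path(base_dir))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d, base_dir=path.parent)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.options, sort_keys=False)

    def __getitem__(self, key):
        return self.options[key]

    @property
    def input_dir(self) -> Path:
        return self.base_dir / self.options["input_dir"]

    @property
    def output_dir(self) -> Path:
        return self.base_dir / self.options["output_dir"]


# ---------------------------------------------------------------------------
# climate helpers
# ---------------------------------------------------------------------------


def read_climate(path, sep: str | None = None) -> pd.DataFrame:
    """Wide climate table (timestamp, rg_wm2, t_a_c, rh_pct, rainfall_mm)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if "timestamp" not in df.columns:
        raise ConfigError(f"{path}: climate table needs a 'timestamp' column")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if "vpd_kpa" not in df.columns:
        df["vpd_kpa"] = vpd_from_t_rh(
            df["t_a_c"].to_numpy(float), df["rh_pct"].clip(0, 100).to_numpy(float)
        )
    return df


def daily_climate(climate: pd.DataFrame) -> pd.DataFrame:
    """Per-day aggregates: R_G (MJ m⁻² d⁻¹), mean/max T_A, max VPD, rainfall."""
    df = climate.copy()
    df["date"] = df["timestamp"].dt.normalize()
    out = df.groupby("date").agg(
        rg_mj=("rg_wm2", lambda v: float(np.nansum(v) * STEP_SECONDS / 1e6)),
        t_a_mean=("t_a_c", "mean"),
        t_a_max=("t_a_c", "max"),
        vpd_max=("vpd_kpa", "max"),
        rainfall_mm=("rainfall_mm", "sum"),
    )
    return out.reset_index()


# ---------------------------------------------------------------------------
# per-sensor analysis
# ---------------------------------------------------------------------------


@dataclass
class SensorResult:
    tree_id: str
    position: str
    daily_metrics: pd.DataFrame
    fits: pd.DataFrame
    turgor: dict  # date → TurgorSignal


def analyze_sensor(
    tree_id: str,
    position: str,
    trunk: GriddedSeries,
    xylem: GriddedSeries,
    psi: GriddedSeries,
    rain_by_date: dict,
    cfg: dict,
) -> SensorResult:
    """Run the full per-sensor analysis on regularized series."""
    thickness = bark_thickness(trunk, xylem)
    decomp = detrend_seasonal(
        thickness,
        period=cfg["stl"]["period"],
        trend_days=cfg["stl"]["trend_window_days"],
        seasonal=cfg["stl"]["seasonal"],
        robust=cfg["stl"]["robust"],
    )
    det = decomp.detrended

    metric_rows = []
    fit_rows = []
    turgor = {}
    for date in det.dates():
        day_th = det.day(date)
        day_psi = psi.day(date)
        if len(day_th) < SAMPLES_PER_DAY:
            continue
        dm = daily_extrema(det, date, cfg["metrics"]["min_valid_fraction"])
        row = {
            "tree_id": tree_id,
            "position": position,
            "date": date,
            "amplitude": dm.amplitude,
            "t_max": dm.t_max,
            "t_min": dm.t_min,
            "valid": dm.valid,
            "lag_minutes": np.nan,
            "peak_correlation": np.nan,
        }
        if dm.valid and len(day_psi) == len(day_th):
            try:
                lag = xcorr_lag(day_th, day_psi, cfg["metrics"]["max_lag_minutes"])
                row["lag_minutes"] = lag.lag_minutes
                row["peak_correlation"] = lag.peak_correlation
            except UndefinedCorrelationError:
                pass
        metric_rows.append(row)

        # day screening for model fitting: complete day, no rain
        rain = rain_by_date.get(pd.Timestamp(date), 0.0)
        frow = {
            "tree_id": tree_id,
            "position": position,
            "date": date,
            "alpha": np.nan,
            "beta": np.nan,
            "gamma": np.nan,
            "phi": np.nan,
            "alpha_beta": np.nan,
            "alpha_beta_si": np.nan,
            "se_c1": np.nan,
            "r2_prediction": np.nan,
            "turgor_amplitude": np.nan,
            "accepted": False,
            "reason": "",
        }
        if rain > cfg["fit"]["rain_mm_threshold"]:
            frow["reason"] = "rainy day"
            fit_rows.append(frow)
            continue
        if not (day_th.valid.all() and day_psi.valid.all() and len(day_psi) == len(day_th)):
            frow["reason"] = "incomplete day"
            fit_rows.append(frow)
            continue
        try:
            design = build_design(day_th, day_psi)
            fit = fit_gls_ar1(design, min_steps=cfg["fit"]["min_steps"])
        except InnerbarkError as exc:
            frow["reason"] = f"fit failed: {exc}"
            fit_rows.append(frow)
            continue
        fit = accept_fit(fit, cfg["fit"]["reject"])
        frow.update(
            alpha=fit.alpha,
            beta=fit.beta,
            gamma=fit.gamma,
            phi=fit.phi,
            alpha_beta=fit.alpha_beta,
            alpha_beta_si=radial_conductance_si(fit.alpha_beta),
            se_c1=fit.se["c1"],
            r2_prediction=fit.r2_prediction,
            accepted=bool(fit.accepted),
            reason=fit.reason,
        )
        if fit.accepted:
            pred = predict_thickness(fit, design.delta_psi_full)
            sig = turgor_signal(design.delta_th_full, pred)
            turgor[pd.Timestamp(date)] = sig
            frow["turgor_amplitude"] = sig.amplitude
        fit_rows.append(frow)

    return SensorResult(
        tree_id=tree_id,
        position=position,
        daily_metrics=pd.DataFrame(metric_rows),
        fits=pd.DataFrame(fit_rows),
        turgor=turgor,
    )


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute every stage; return (and optionally write) the result bundle."""
    cfg = config.options
    indir = config.input_dir
    outdir = config.output_dir

    climate_path = indir / cfg["climate"]
    climate = read_climate(climate_path)
    daily_clim = daily_climate(climate)
    rain_by_date = dict(zip(daily_clim["date"], daily_clim["rainfall_mm"]))

    manifest = {
        "version": __version__,
        "config": cfg,
        "inputs": {str(cfg["climate"]): _sha256(climate_path)},
        "discards": [],
        "stages": {},
    }

    results = []
    for sensor in cfg["sensors"]:
        series = {}
        for kind in ("trunk", "xylem", "psi"):
            p = indir / sensor[kind]
            unit = "MPa" if kind == "psi" else "µm"
            try:
                # fixture files carry flags and a unit header
                s = GriddedSeries.read(p)
            except InnerbarkError:
                s = read_series(p, {"timestamp": "timestamp", "value": "value", "unit": unit})
            s = regularize(s, cfg["grid"]["interval_s"], cfg["grid"]["max_gap_s"])
            for disc in cfg["discards"]:
                if disc.get("sensor") == f"{sensor['tree_id']}_{sensor['position']}" and disc.get(
                    "series", kind
                ) == kind:
                    s = discard_interval(s, disc["start"], disc["end"], disc.get("reason", ""))
                    manifest["discards"].append(disc)
            series[kind] = s
            manifest["inputs"][str(sensor[kind])] = _sha256(p)
        try:
            res = analyze_sensor(
                sensor["tree_id"],
                sensor["position"],
                series["trunk"],
                series["xylem"],
                series["psi"],
                rain_by_date,
                cfg,
            )
        except InnerbarkError as exc:
            raise InnerbarkError(
                f"stage analyze_sensor failed for tree {sensor['tree_id']} "
                f"{sensor['position']}: {exc}"
            ) from exc
        results.append(res)

    daily_metrics = (
        pd.concat([r.daily_metrics for r in results], ignore_index=True)
        if results
        else pd.DataFrame()
    )
    fits = pd.concat([r.fits for r in results], ignore_index=True) if results else pd.DataFrame()

    # climate-response fits per position (amplitude vs daily climate)
    response_rows = []
    if len(daily_metrics):
        merged = daily_metrics[daily_metrics["valid"]].merge(
            daily_clim.rename(
                columns={"rg_mj": "R_G", "vpd_max": "VPD", "t_a_mean": "T_A"}
            ),
            on="date",
        )
        for position, grp in merged.groupby("position"):
            for predictor in ("R_G", "VPD", "T_A"):
                try:
                    f = fit_climate_response(
                        grp, predictor, min_days=cfg["climate_response"]["min_days"]
                    )
                except LengthError:
                    continue
                response_rows.append(
                    {
                        "position": position,
                        "predictor": predictor,
                        "form": f.form,
                        "n_days": f.n_days,
                        "r_squared": f.r_squared,
                        "q10": f.q10,
                        **{f"coef_{k}": v for k, v in f.coefficients.items()},
                    }
                )
    responses = pd.DataFrame(response_rows)

    osmotics_summary = pd.DataFrame()
    gradients = pd.DataFrame()
    if cfg["osmotic_samples"]:
        samples = pd.read_csv(indir / cfg["osmotic_samples"])
        manifest["inputs"][str(cfg["osmotic_samples"])] = _sha256(indir / cfg["osmotic_samples"])
        osmotics_summary = summarize_osmotics(
            samples, temperature_k=cfg["osmotics"]["temperature_k"]
        )
        gradients = gradient_table(osmotics_summary)

    turgor_long = []
    for r in results:
        for date, sig in sorted(r.turgor.items()):
            for i, v in enumerate(sig.series):
                turgor_long.append(
                    {
                        "tree_id": r.tree_id,
                        "position": r.position,
                        "date": date,
                        "step": i,
                        "turgor_um": v,
                    }
                )
    turgor_df = pd.DataFrame(turgor_long)

    manifest["stages"] = {
        "sensors": len(results),
        "days_with_metrics": int(daily_metrics["valid"].sum()) if len(daily_metrics) else 0,
        "fits_total": len(fits),
        "fits_accepted": int(fits["accepted"].sum()) if len(fits) else 0,
    }

    bundle = {
        "daily_metrics": daily_metrics,
        "fits": fits,
        "climate_daily": daily_clim,
        "climate_responses": responses,
        "osmotics_summary": osmotics_summary,
        "osmotic_gradients": gradients,
        "turgor": turgor_df,
        "manifest": manifest,
    }

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "daily_metrics",
            "fits",
            "climate_daily",
            "climate_responses",
            "osmotics_summary",
            "osmotic_gradients",
            "turgor",
        ):
            bundle[name].to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8"
        )
        (outdir / "report.md").write_text(report_summary(bundle), encoding="utf-8")
    return bundle


def report_summary(bundle: dict) -> str:
    """Human-readable summary mirroring the campaign's headline results."""
    lines = ["# Inner-bark diurnal dynamics — run summary", ""]
    dm = bundle["daily_metrics"]
    if len(dm):
        lines.append("## Diurnal amplitude and lag by position")
        for position, grp in dm[dm["valid"]].groupby("position"):
            med_amp = grp["amplitude"].median()
            med_lag = grp["lag_minutes"].median()
            lines.append(
                f"- {position}: median amplitude {med_amp:.1f} µm over {len(grp)} days; "
                f"median lag {med_lag:.0f} min"
            )
        lines.append("")
    fits = bundle["fits"]
    if len(fits):
        lines.append("## Exchange-model fits")
        acc = fits[fits["accepted"]]
        lines.append(
            f"- accepted {len(acc)} of {len(fits)} day-fits"
            + (
                ""
                if len(fits) == len(acc)
                else f" (rejected: {', '.join(sorted(set(fits.loc[~fits['accepted'], 'reason'])))} )"
            )
        )
        for position, grp in acc.groupby("position"):
            lines.append(
                f"- {position}: median radial conductance "
                f"{grp['alpha_beta_si'].median():.2e} m MPa⁻¹ s⁻¹; "
                f"median turgor-signal amplitude {grp['turgor_amplitude'].median():.1f} µm"
            )
        lines.append("")
    else:
        lines.append("## Exchange-model fits")
        lines.append("- zero accepted fits")
        lines.append("")
    osm = bundle["osmotics_summary"]
    if len(osm):
        lines.append("## Osmotics (date × time × position)")
        for r in osm.itertuples():
            lines.append(
                f"- {r.date} {r.time_class} {r.position}: osmolality "
                f"{r.osmolality_mean:.2f} mol/kg (SD {r.osmolality_sd:.2f}), "
                f"P_H {r.p_h_mean:.2f} MPa (SD {r.p_h_sd:.2f})"
            )
        grad = bundle["osmotic_gradients"]
        for r in grad.itertuples():
            lines.append(
                f"- gradient {r.date} {r.time_class}: ΔC_S {r.osmolality_gradient:+.3f} mol/kg, "
                f"ΔP_H {r.p_h_gradient:+.3f} MPa"
            )
        lines.append("")
    return "\n".join(lines)
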