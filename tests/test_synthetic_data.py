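"""Generator realism, determinism, and end-to-end parameter recovery."""

import dataclasses
import hashlib
import json

import numpy as np
import pandas as pd
import pytest

from innerbark.errors import DomainError
from innerbark.exchange_model import accept_fit, build_design, fit_gls_ar1, predict_thickness, turgor_signal
from innerbark.preprocessing import bark_thickness, detrend_seasonal
from innerbark.synthetic_data import (
    SensorTruth,
    TurgorWaveform,
    default_sensor_truths,
    make_fixture,
    simulate_campaign,
    simulate_climate,
    simulate_dendrometer_pair,
    simulate_osmotic_samples,
    simulate_psi,
)
from innerbark.timeseries_io import SAMPLES_PER_DAY


class TestClimate:
    def test_deterministic_per_seed(self):
        a = simulate_climate(4, seed=9)
        b = simulate_climate(4, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_climate(4, seed=10)
        assert not np.allclose(a["rg_wm2"], c["rg_wm2"])

    def test_cloudy_days_reduce_radiation(self):
        clear = simulate_climate(10, 1, params={"cloud_beta": (50.0, 1.0), "rain_probability": 0.0})
        cloudy = simulate_climate(10, 1, params={"cloud_beta": (1.0, 9.0), "rain_probability": 0.0})
        assert cloudy["rg_wm2"].sum() < clear["rg_wm2"].sum()

    def test_physical_ranges(self):
        c = simulate_climate(30, 2)
        assert c["rh_pct"].between(0, 100).all()
        assert (c["rainfall_mm"] >= 0).all()
        assert (c["vpd_kpa"] >= 0).all()
        assert (c["rg_wm2"] >= 0).all()

    def test_needs_at_least_one_day(self):
        with pytest.raises(DomainError):
            simulate_climate(0, 1)


class TestPsi:
    def test_zero_forcing_gives_zero_psi(self):
        c = simulate_climate(3, 1)
        c["rg_wm2"] = 0.0
        c["vpd_kpa"] = 0.0
        psi = simulate_psi(c, seed=1)
        np.testing.assert_allclose(psi.values, 0.0, atol=1e-12)

    def test_bounded_by_physiological_floor(self):
        c = simulate_climate(60, 3)
        psi = simulate_psi(c, seed=3, scale=2.5)
        assert psi.values.min() >= -1.0
        assert psi.values.max() <= 0.0

    def test_daily_minimum_tracks_daily_max_vpd(self):
        """Across ≥60 days the ψ-min / VPD-max correlation is field-like."""
        c = simulate_climate(60, 4)
        psi = simulate_psi(c, seed=4, scale=1.5)
        daymin = psi.values.reshape(60, SAMPLES_PER_DAY).min(axis=1)
        vpdmax = c["vpd_kpa"].to_numpy().reshape(60, SAMPLES_PER_DAY).max(axis=1)
        r = np.corrcoef(daymin, vpdmax)[0, 1]
        assert -0.95 <= r <= -0.40  # deeper tension on drier days

    def test_dawn_psi_near_zero(self):
        c = simulate_climate(10, 5)
        psi = simulate_psi(c, seed=5, scale=1.5)
        dawn = psi.values.reshape(10, SAMPLES_PER_DAY)[:, 33]  # 05:30
        assert (dawn > -0.25).all()


class TestDendrometerPair:
    def test_noise_free_pipeline_recovers_conductance_within_1pct(self):
        """End-to-end oracle: no noise, no turgor, no growth → αβ exact to <1%."""
        truth = SensorTruth(
            tree_id="1",
            position="upper",
            turgor=TurgorWaveform(amplitude=0.0),
            growth_um_day=0.0,
            sigma_noise_um=0.0,
            sigma_psi_mpa=0.0,
        )
        c = simulate_climate(9, 6)
        psi = simulate_psi(c, seed=6, scale=1.5)
        trunk, xylem, _ = simulate_dendrometer_pair(psi, truth, seed=6)
        det = detrend_seasonal(bark_thickness(trunk, xylem)).detrended
        errs = []
        for date in det.dates()[2:7]:
            f = fit_gls_ar1(build_design(det.day(date), psi.day(date)))
            errs.append(abs(f.alpha_beta - truth.alpha_beta) / truth.alpha_beta)
        assert np.median(errs) < 0.01

    def test_turgor_component_recovered_by_residual(self, field_campaign):
        """Residual correlates with the injected component (r > 0.9) and its
        amplitude is recovered within 25% (median over accepted day-fits)."""
        from innerbark.recovery import analyze_campaign_fits

        sd = field_campaign.sensors[("1", "upper")]
        det = detrend_seasonal(bark_thickness(sd.trunk, sd.xylem)).detrended
        corrs, amp_errs = [], []
        for date in det.dates()[1:8]:
            day_th, day_psi = det.day(date), sd.psi.day(date)
            if not (day_th.valid.all() and day_psi.valid.all()):
                continue
            design = build_design(day_th, day_psi)
            f = accept_fit(fit_gls_ar1(design))
            if not f.accepted:
                continue
            sig = turgor_signal(design.delta_th_full, predict_thickness(f, design.delta_psi_full))
            comp = sd.turgor_component.day(date).values
            comp = comp - comp[0]
            corrs.append(np.corrcoef(sig.series, comp)[0, 1])
            true_amp = comp.max() - comp.min()
            amp_errs.append(abs(sig.amplitude - true_amp) / true_amp)
        assert len(corrs) >= 4
        assert np.median(corrs) > 0.9
        assert np.median(amp_errs) < 0.25

    def test_growth_ramp_recovered_in_trend(self):
        truth = SensorTruth(
            tree_id="1",
            position="lower",
            turgor=TurgorWaveform(amplitude=0.0),
            growth_um_day=5.0,
            sigma_noise_um=0.0,
            sigma_psi_mpa=0.0,
        )
        # repeatable weather so growth is the only drift in the trend
        c = simulate_climate(
            30, 7, params={"cloud_beta": (5000.0, 1.0), "rain_probability": 0.0, "cloud_sd": 0.0, "t_day_sd": 0.0}
        )
        psi = simulate_psi(c, seed=7, scale=1.2, params={"day_variability": 0.0})
        trunk, xylem, _ = simulate_dendrometer_pair(psi, truth, seed=7)
        decomp = detrend_seasonal(bark_thickness(trunk, xylem))
        t_days = np.arange(len(decomp.trend)) / SAMPLES_PER_DAY
        slope = np.polyfit(t_days, decomp.trend.values, 1)[0]
        assert slope == pytest.approx(0.3 * truth.growth_um_day, rel=0.05)

    def test_no_turgor_residual_sits_at_noise_floor(self):
        """Without an injected waveform the residual amplitude is
        indistinguishable from the procedure's noise floor: the expected
        range of the AR(1) observation noise plus the first-order
        propagation of coefficient uncertainty through the prediction
        recursion (a conductance error δc₁ scales the whole ψ-driven
        trajectory by δc₁/c₁)."""
        truth = SensorTruth(
            tree_id="1", position="upper", turgor=TurgorWaveform(amplitude=0.0)
        )
        c = simulate_climate(9, 8)
        psi = simulate_psi(c, seed=8, scale=1.5)
        trunk, xylem, _ = simulate_dendrometer_pair(psi, truth, seed=8)
        det = detrend_seasonal(bark_thickness(trunk, xylem)).detrended
        psi_obs = psi  # latent ψ: isolates the thickness-noise floor
        amps, floors = [], []
        for date in det.dates()[1:8]:
            design = build_design(det.day(date), psi_obs.day(date))
            f = accept_fit(fit_gls_ar1(design))
            if not f.accepted:
                continue
            sig = turgor_signal(
                design.delta_th_full, predict_thickness(f, design.delta_psi_full)
            )
            amps.append(sig.amplitude)
            obs_amp = design.delta_th_full.max() - design.delta_th_full.min()
            floors.append(2 * abs(f.se["c1"] / f.alpha_beta) * obs_amp)
        sigma_marginal = truth.sigma_noise_um / np.sqrt(1 - truth.phi_noise**2)
        noise_range = 2 * sigma_marginal * np.sqrt(2 * np.log(SAMPLES_PER_DAY))
        assert np.median(amps) < 3 * (noise_range + np.median(floors))


class TestOsmoticSamples:
    def _campaign_truth(self):
        from innerbark.synthetic_data import SimulationTruth, OSMOLALITY_PROFILE

        return SimulationTruth(
            seed=0,
            kind="paper_scale",
            days=9,
            start="2019-08-01",
            sensors=default_sensor_truths("paper_scale"),
            osmolality_profile=OSMOLALITY_PROFILE,
        )

    def test_zero_replicate_sd_gives_identical_replicates(self):
        df = simulate_osmotic_samples(
            self._campaign_truth(), {}, ["2019-08-03"], seed=1, replicate_sd=0.0
        )
        g = df.groupby(["tree_id", "time_class", "position"])["osmolality"].nunique()
        assert (g == 1).all()

    def test_constructed_axial_gradient_recovered(self):
        profile = {"summer": {"upper": 0.46, "lower": 0.40}, "winter": {"upper": 0.6, "lower": 0.5}}
        df = simulate_osmotic_samples(
            self._campaign_truth(),
            {},
            ["2019-08-03"],
            seed=2,
            replicate_sd=0.0,
            tree_sd=0.0,
            profile=profile,
        )
        by_pos = df.groupby("position")["osmolality"].mean()
        assert by_pos["upper"] - by_pos["lower"] == pytest.approx(0.06, abs=1e-12)

    def test_dawn_psi_at_sampling_near_zero(self, field_campaign):
        dawn = field_campaign.osmotic_samples.query("time_class == 'dawn'")
        assert (dawn["psi_x"] <= 0).all()
        assert (dawn["psi_x"] > -0.3).all()


class TestFixtures:
    def test_tiny_fixture_runs_full_pipeline(self, tmp_path):
        from innerbark.pipeline import RunConfig, run_pipeline

        out = make_fixture("tiny", tmp_path / "fix", seed=2)
        bundle = run_pipeline(RunConfig.from_yaml(out / "config.yaml"))
        assert len(bundle["fits"]) == 6  # 3 days × 2 sensors
        assert (tmp_path / "fix" / "results" / "manifest.json").exists()

    def test_stress_fixture_yields_a_recorded_rejection(self, tmp_path):
        from innerbark.pipeline import RunConfig, run_pipeline

        out = make_fixture("stress", tmp_path / "stress", seed=2)
        bundle = run_pipeline(RunConfig.from_yaml(out / "config.yaml"))
        rejected = bundle["fits"].query("~accepted")
        assert len(rejected) >= 1
        assert (rejected["reason"].str.len() > 0).all()

    def test_fixture_regeneration_is_bit_identical(self, tmp_path):
        h = []
        for sub in ("a", "b"):
            out = make_fixture("paper_scale", tmp_path / sub, seed=3)
            digest = hashlib.sha256()
            for f in sorted(out.glob("*.csv")) + [out / "truth.json"]:
                digest.update(f.read_bytes())
            h.append(digest.hexdigest())
        assert h[0] == h[1]

    def test_truth_manifest_records_generating_parameters(self, tmp_path):
        out = make_fixture("tiny", tmp_path / "fix", seed=4)
        truth = json.loads((out / "truth.json").read_text())
        assert truth["kind"] == "tiny"
        assert truth["days"] == 3
        sensors = {(s["tree_id"], s["position"]): s for s in truth["sensors"]}
        assert sensors[("1", "upper")]["alpha_beta"] == pytest.approx(4.8)
        assert sensors[("1", "lower")]["alpha_beta"] == pytest.approx(1.8)

    def test_unknown_kind_rejected(self):
        with pytest.raises(DomainError):
            simulate_campaign("huge", seed=0)
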