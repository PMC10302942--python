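"""Tests of the scenario generator: determinism, channel asymmetry of the
white→brown shift, POF closed forms, CIP bookkeeping, and the two-phase
carbon-rate template."""

import numpy as np
import pytest

from biofoulmon import (
    PofParams,
    ScenarioConfig,
    coverage_timeline,
    load_series,
    simulate_image_series,
    simulate_pof_series,
    simulate_process_series,
    write_scenario,
)
from biofoulmon.errors import ConfigurationError


class TestConfigValidation:
    def test_bad_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(frame_height=0)
        with pytest.raises(ConfigurationError):
            ScenarioConfig(frame_interval_h=0.0)

    def test_channel_attenuation_must_order_blue_strongest(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(channel_attenuation=(0.8, 0.5, 0.2))

    def test_cip_efficacy_bounds(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(cip_events=((100.0, 1.5),))

    def test_negative_pof_tau_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(pof_params=PofParams(decay_tau_h=-1.0))


class TestImageSeries:
    def test_same_seed_byte_identical(self, tiny_config):
        f1, c1, o1 = simulate_image_series(tiny_config)
        f2, c2, o2 = simulate_image_series(tiny_config)
        assert o1 == o2
        np.testing.assert_array_equal(c1.fraction, c2.fraction)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_null_scenario_blue_mean_constant_within_noise(self, null_config):
        cfg = null_config.with_(illumination_drift=0.0)
        frames, coverage, _ = simulate_image_series(cfg)
        assert np.all(coverage.fraction == 0.0)
        blues = np.array([f.pixels[..., 2].mean() for f in frames])
        # mean over ~25k pixels: noise on the mean is tiny
        assert np.ptp(blues) < 3.0 * cfg.noise_sd

    def test_fouling_hits_blue_harder_than_red(self, tiny_config):
        frames, coverage, _ = simulate_image_series(tiny_config)
        assert coverage.fraction[-1] > 0.01
        first, last = frames[0].pixels, frames[-1].pixels
        rel = [
            last[..., ch].mean() / first[..., ch].mean() for ch in range(3)
        ]
        # relative intensity loss ordered blue >= green >= red
        assert rel[2] < rel[0]
        assert rel[2] <= rel[1] <= rel[0]

    def test_planted_offsets_within_jitter_and_reference_zero(self, tiny_config):
        _, _, offsets = simulate_image_series(tiny_config)
        assert offsets[0] == (0, 0)
        j = tiny_config.jitter_max
        assert all(abs(dr) <= j and abs(dc) <= j for dr, dc in offsets)

    def test_coverage_monotone_and_reduced_at_cip(self):
        cfg = ScenarioConfig.scaled(
            128, 192, seed=5, duration_h=240.0, onset_h=48.0,
            frame_interval_h=6.0, cip_events=((150.0, 0.8),),
        )
        _, coverage, _ = simulate_image_series(cfg)
        t = cfg.frame_times
        frac = coverage.fraction
        assert np.all(frac <= 1.0)
        pre_cip = t < 150.0  # the event applies at exactly t = 150
        assert np.all(np.diff(frac[pre_cip]) >= -1e-12)
        i = int(np.searchsorted(t, 150.0, side="left"))
        assert frac[i] < frac[i - 1]  # CIP knocks coverage down


class TestPofSeries:
    def test_no_fouling_attenuation_sensor_equals_reference(self, tiny_config):
        cfg = tiny_config.with_(
            pof_noise_sd=0.0,
            pof_params=PofParams(fouling_attenuation=0.0),
        )
        pof = simulate_pof_series(cfg)
        np.testing.assert_array_equal(pof["sensor"], pof["reference"])

    def test_conditioning_decay_closed_form(self):
        # tau=24 h, amplitude 0.2 -> value at 96 h is 0.8 + 0.2 e^-4
        cfg = ScenarioConfig(
            seed=1, duration_h=120.0, nucleation_rate=0.0, pof_noise_sd=0.0,
            pof_params=PofParams(
                decay_amplitude=0.2, decay_tau_h=24.0, diurnal_amplitude=0.01
            ),
        )
        pof = simulate_pof_series(cfg)
        at96 = float(pof.loc[pof["time_h"] == 96.0, "sensor"].iloc[0])
        # sin(2*pi*96/24) = 0, so the diurnal factor drops out exactly
        np.testing.assert_allclose(at96, 0.8 + 0.2 * np.exp(-4.0), rtol=1e-12)

    def test_full_efficacy_cip_returns_to_clean_envelope(self):
        cfg = ScenarioConfig.scaled(
            128, 192, seed=9, duration_h=200.0, onset_h=60.0,
            pof_noise_sd=0.0, cip_events=((70.0, 1.0),),
        )
        pof = simulate_pof_series(cfg)
        i = int(np.searchsorted(pof["time_h"].to_numpy(), 70.0, side="right"))
        sensor = pof["sensor"].iloc[i]
        reference = pof["reference"].iloc[i]
        assert abs(sensor / reference - 1.0) < 0.01

    def test_plateau_caps_fouling_response(self):
        cfg = ScenarioConfig.scaled(
            128, 192, seed=2, duration_h=300.0, onset_h=24.0,
            nucleation_rate=2.0, pof_noise_sd=0.0,
        )
        cov = coverage_timeline(cfg)
        cap = cfg.pof_params.plateau_coverage
        assert cov[-1] > cap, "scenario must overgrow the fiber"
        pof = simulate_pof_series(cfg)
        ratio = (pof["sensor"] / pof["reference"]).to_numpy()
        capped = cov >= cap
        expected = np.exp(-cfg.pof_params.fouling_attenuation * cap)
        np.testing.assert_allclose(ratio[capped], expected, rtol=1e-9)


class TestProcessSeries:
    def test_null_scenario_carbon_rate_near_zero(self, null_config):
        table, truth = simulate_process_series(null_config.with_(sensor_interval_h=1.0))
        c = (
            table["TOC_Ret"] * table["Vdot_Ret"]
            - table["TOC_Feed"] * table["Vdot_Feed"]
        ).to_numpy()
        sd = null_config.toc_noise_sd * np.hypot(
            null_config.process_params.feed_flow_l_h,
            null_config.process_params.retentate_flow_l_h,
        )
        assert np.all(truth["carbon_rate_true"] == 0.0)
        assert abs(c.mean()) < sd / 3
        assert np.all(np.abs(c) < 5 * sd)

    def test_true_carbon_rate_changes_sign_exactly_once(self, tiny_config):
        _, truth = simulate_process_series(tiny_config)
        sign = np.sign(truth["carbon_rate_true"])
        sign = sign[sign != 0]
        flips = np.diff(sign) != 0
        assert flips.sum() == 1
        assert sign[0] == -1 and sign[-1] == 1  # attachment then detachment

    def test_phase_boundaries_order_pof_first_fcp_last(self, tiny_config):
        _, truth = simulate_process_series(tiny_config)
        assert (
            truth["onset_h"]
            < truth["perm_decline_start_h"]
            < truth["fcp_start_h"]
        )


class TestScenarioOnDisk:
    def test_write_scenario_round_trips(self, tmp_path):
        cfg = ScenarioConfig.scaled(
            64, 96, seed=3, duration_h=24.0, onset_h=6.0, frame_interval_h=6.0
        )
        paths = write_scenario(cfg, tmp_path / "scn")
        frames = load_series(paths["manifest"])
        assert len(frames) == cfg.n_frames
        assert frames[0].shape == (64, 96, 3)
        import json

        truth = json.loads(paths["truth"].read_text())
        assert truth["onset_h"] == 6.0
        assert len(truth["planted_offsets"]) == cfg.n_frames
        assert paths["pof"].exists() and paths["process"].exists()
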