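"""Scenario configuration for the synthetic accelerated-biofouling experiment.

A :class:`ScenarioConfig` is the full stated world of one simulated run of a
reverse-osmosis flat module under nutrient dosing: camera frames of the
membrane/spacer surface, polymer-optical-fiber (POF) transmission traces, and
process records (TOC mass balance, permeability, feed-channel pressure drop).
All randomness derives from the single ``seed``; the same config produces
byte-identical output.

Default geometry matches the monitoring camera (2064×3088 px, 8-bit RGB, one
frame per hour). Rates that are resolution-dependent (patch growth, jitter)
can be rescaled for smaller frames with :meth:`ScenarioConfig.scaled`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

from .errors import ConfigurationError

#: Reference camera geometry the default rates are expressed in.
REF_HEIGHT = 2064
REF_WIDTH = 3088


@dataclass(frozen=True)
class PofParams:
    """Polymer-optical-fiber transmission model parameters.

    The clean-fiber envelope is ``(1 - decay_amplitude) +
    decay_amplitude * exp(-t / decay_tau_h)``: an asymptotic conditioning
    decay caused by water uptake and mechanical stress, reaching its limiting
    value within a few time constants. A multiplicative 24 h sinusoid models
    the daily temperature cycle. Fouling attenuates the sensor fiber by
    ``exp(-fouling_attenuation * coverage)``, with coverage capped at
    ``plateau_coverage`` (a fully overgrown sensing zone stops responding).
    """

    decay_amplitude: float = 0.2
    decay_tau_h: float = 24.0
    diurnal_amplitude: float = 0.01
    fouling_attenuation: float = 2.0
    plateau_coverage: float = 0.6

    def validate(self) -> None:
        if self.decay_tau_h <= 0:
            raise ConfigurationError("POF decay time constant must be positive")
        if not 0.0 <= self.decay_amplitude < 1.0:
            raise ConfigurationError("POF decay amplitude must be in [0, 1)")
        if self.diurnal_amplitude < 0 or self.fouling_attenuation < 0:
            raise ConfigurationError("POF amplitudes must be non-negative")
        if not 0.0 < self.plateau_coverage <= 1.0:
            raise ConfigurationError("plateau coverage must be in (0, 1]")


@dataclass(frozen=True)
class ProcessParams:
    """Plant operating point for the process-data simulator.

    Feed flow 11.5 L/h is the pilot plant's stated rate; the retentate flow of
    10 L/h leaves 1.5 L/h of permeate. The flat-module membrane area is never
    published and defaults to 0.01 m² (a plausible lab flat cell); it is a
    plain input everywhere it matters.
    """

    baseline_toc_mg_l: float = 1.0
    feed_flow_l_h: float = 11.5
    retentate_flow_l_h: float = 10.0
    membrane_area_m2: float = 0.01
    baseline_tmp_bar: float = 10.0

    def validate(self) -> None:
        if min(self.feed_flow_l_h, self.retentate_flow_l_h) < 0:
            raise ConfigurationError("flows must be non-negative")
        if self.feed_flow_l_h < self.retentate_flow_l_h:
            raise ConfigurationError("feed flow must be >= retentate flow")
        if self.membrane_area_m2 <= 0 or self.baseline_tmp_bar <= 0:
            raise ConfigurationError("area and TMP must be positive")
        if self.baseline_toc_mg_l < 0:
            raise ConfigurationError("baseline TOC must be non-negative")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic biofouling experiment."""

    seed: int = 0
    duration_h: float = 360.0
    frame_interval_h: float = 1.0
    frame_height: int = REF_HEIGHT
    frame_width: int = REF_WIDTH
    #: max |integer translation| per axis of the camera view, in pixels
    jitter_max: int = 20
    #: hours at which nutrient dosing starts and biofilm patches may nucleate
    onset_h: float = 120.0
    #: expected new biofilm patches per hour after onset
    nucleation_rate: float = 0.5
    #: patch radius growth, pixels per hour
    patch_growth_rate: float = 2.0
    #: per-unit-coverage intensity loss for (R, G, B); blue attenuated most —
    #: this is the white→brown color shift of a growing biofilm
    channel_attenuation: Tuple[float, float, float] = (0.15, 0.45, 0.75)
    #: multiplicative illumination gain, fraction per 100 h
    illumination_drift: float = 0.02
    #: additive pixel noise standard deviation, 8-bit intensity units
    noise_sd: float = 2.0
    #: cleaning-in-place events as (time_h, efficacy in [0, 1])
    cip_events: Tuple[Tuple[float, float], ...] = ()
    pof_params: PofParams = field(default_factory=PofParams)
    process_params: ProcessParams = field(default_factory=ProcessParams)
    #: sampling interval of POF and process records (independent of the camera)
    sensor_interval_h: float = 1.0
    #: relative POF intensity measurement noise
    pof_noise_sd: float = 0.002
    #: TOC measurement noise, mg/L
    toc_noise_sd: float = 0.01
    #: relative TMPnet measurement noise
    tmp_noise_rel: float = 0.005
    fcp_baseline_mbar: float = 50.0
    fcp_noise_sd_mbar: float = 0.5
    #: magnitude of the two-phase carbon-rate template, mg/h
    carbon_pulse_mg_h: float = 1.5
    #: hours after onset at which biofilm detachment (positive carbon rate) starts
    detach_lag_h: float = 50.0
    #: hours after onset at which permeability starts to decline
    perm_decline_lag_h: float = 80.0
    #: hours after onset at which the feed-channel pressure drop starts to rise
    fcp_lag_h: float = 100.0

    def __post_init__(self) -> None:
        if self.frame_height <= 0 or self.frame_width <= 0:
            raise ConfigurationError("frame dimensions must be positive")
        if self.frame_interval_h <= 0 or self.sensor_interval_h <= 0:
            raise ConfigurationError("sampling intervals must be positive")
        if self.duration_h < self.frame_interval_h:
            raise ConfigurationError("duration must cover at least one interval")
        if self.jitter_max < 0:
            raise ConfigurationError("jitter_max must be non-negative")
        if self.onset_h < 0:
            raise ConfigurationError("onset_h must be non-negative")
        if self.nucleation_rate < 0 or self.patch_growth_rate < 0:
            raise ConfigurationError("growth rates must be non-negative")
        r, g, b = self.channel_attenuation
        if not (0 <= r <= g <= b <= 1):
            raise ConfigurationError(
                "channel_attenuation must satisfy 0 <= R <= G <= B <= 1"
            )
        if self.noise_sd < 0 or self.pof_noise_sd < 0 or self.toc_noise_sd < 0:
            raise ConfigurationError("noise levels must be non-negative")
        for t_e, eff in self.cip_events:
            if not 0.0 <= eff <= 1.0:
                raise ConfigurationError(f"CIP efficacy {eff} outside [0, 1]")
            if not 0.0 <= t_e <= self.duration_h:
                raise ConfigurationError(f"CIP time {t_e} outside the experiment")
        self.pof_params.validate()
        self.process_params.validate()

    # -- derived geometry ----------------------------------------------------

    @property
    def scene_shape(self) -> Tuple[int, int]:
        """Shape of the latent membrane scene (frame plus jitter room)."""
        return (
            self.frame_height + 2 * self.jitter_max,
            self.frame_width + 2 * self.jitter_max,
        )

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h + 1e-9, self.frame_interval_h)

    @property
    def sensor_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h + 1e-9, self.sensor_interval_h)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    # -- constructors --------------------------------------------------------

    @classmethod
    def scaled(cls, frame_height: int, frame_width: int, **overrides) -> "ScenarioConfig":
        """Default scenario rescaled to a smaller camera frame.

        Length-like rates (patch growth, jitter) shrink with the linear scale
        ``frame_height / 2064``; the nucleation rate is kept, which leaves the
        coverage-fraction trajectory invariant (coverage ~ rate · growth² · t³
        / area, and growth²/area is scale-free).
        """
        s = frame_height / REF_HEIGHT
        params = dict(
            frame_height=frame_height,
            frame_width=frame_width,
            jitter_max=max(1, round(20 * s)),
            patch_growth_rate=2.0 * s,
        )
        params.update(overrides)
        return cls(**params)

    def with_(self, **overrides) -> "ScenarioConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


def default_margins(config: ScenarioConfig) -> Tuple[int, int]:
    """Registration crop margins appropriate for a scenario's geometry.

    At the reference camera size these are (127, 175), which turns a
    2064×3088 frame into the 1937×2913 registered frame; for smaller frames
    they shrink proportionally but always leave room for the configured
    jitter (anchor = floor(margin/2) must be >= jitter_max).
    """
    s = config.frame_height / REF_HEIGHT
    mr = max(int(round(127 * s)), 2 * config.jitter_max)
    mc = max(int(round(175 * s)), 2 * config.jitter_max)
    return mr, mc
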