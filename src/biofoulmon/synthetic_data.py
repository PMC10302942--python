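"""Synthetic accelerated-biofouling experiment generator.

Emulates the three data streams of a membrane flat-module monitoring setup:

* time-lapse RGB frames of the membrane/spacer surface with camera jitter,
  illumination drift, pixel noise and a white→brown biofilm color shift in
  which the blue channel is attenuated most and the red channel least;
* polymer-optical-fiber (POF) transmission with an asymptotic conditioning
  decay, a 24 h diurnal modulation, fouling attenuation that plateaus once
  the fiber is overgrown, and stepwise recovery at cleaning-in-place events;
* process records (TOC mass balance, permeability, feed-channel pressure
  drop) following the canonical attachment → detachment phase sequence.

The latent state behind the image color shift is a per-pixel biofilm
*coverage field* in [0, 1]: circular patches nucleate at Poisson times after
``onset_h``, their radii grow linearly, and overlapping deposit density ``d``
saturates as coverage ``c = 1 - exp(-d)``. A CIP event multiplies the
accumulated density by ``1 - efficacy``.

All randomness derives from ``config.seed`` through named
``numpy.random.SeedSequence`` child streams (texture, patches, jitter,
image noise, POF noise, process noise), so a fixed config reproduces output
byte-for-byte and the image and fiber simulators see the same patch history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import ScenarioConfig
from .errors import ConfigurationError
from .image_io import ImageFrame, write_frame, write_manifest

_STREAMS = ("texture", "patches", "jitter", "image_noise", "pof_noise", "process_noise")


def _rng_streams(config: ScenarioConfig) -> Dict[str, np.random.Generator]:
    root = np.random.SeedSequence(config.seed)
    return {
        name: np.random.default_rng(child)
        for name, child in zip(_STREAMS, root.spawn(len(_STREAMS)))
    }


# ---------------------------------------------------------------------------
# latent scene and biofilm state
# ---------------------------------------------------------------------------


@dataclass
class PatchSet:
    """Nucleation times and scene positions of biofilm patches."""

    times_h: np.ndarray
    rows: np.ndarray
    cols: np.ndarray

    def __len__(self) -> int:
        return len(self.times_h)


@dataclass
class CoverageField:
    """Biofilm coverage ground truth for an image series.

    ``fraction`` holds the mean coverage of the visible frame per timepoint;
    ``final_field`` is the full per-pixel field (scene coordinates) at the
    last frame. Per-frame fields are kept only when the series was simulated
    with ``keep_fields=True`` (they are large).
    """

    fraction: np.ndarray
    final_field: np.ndarray
    fields: Optional[List[np.ndarray]] = None


def make_clean_scene(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Clean (pre-fouling) membrane luminance on the latent scene grid.

    Low-frequency smoothed noise plus a periodic diamond spacer mesh: the
    registration step locks onto the spacer features, so the texture must be
    feature-rich. Returned as a 2-D float32 array in 8-bit intensity units;
    a clean membrane is near-white, so all three channels share it.
    """
    h, w = config.scene_shape
    sigma = max(2.0, config.frame_height / 160)
    base = gaussian_filter(rng.standard_normal((h, w)), sigma=sigma, mode="reflect")
    sd = base.std()
    if sd > 0:
        base /= sd
    tex = 0.82 + 0.05 * base

    # diamond feed-spacer mesh, darker than the membrane
    period = max(12, config.frame_height // 12)
    lw = max(1, period // 8)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    mesh = ((rows + cols) % period < lw) | ((rows - cols) % period < lw)
    tex = np.where(mesh, tex * 0.72, tex)
    tex = gaussian_filter(tex, sigma=0.7)
    return (np.clip(tex, 0.05, 0.98) * 255.0).astype(np.float32)


def draw_patches(config: ScenarioConfig, rng: np.random.Generator) -> PatchSet:
    """Poisson patch nucleation after onset, uniform over the scene."""
    span = config.duration_h - config.onset_h
    if config.nucleation_rate <= 0 or span <= 0:
        empty = np.empty(0)
        return PatchSet(empty, empty.copy(), empty.copy())
    n = int(rng.poisson(config.nucleation_rate * span))
    t = config.onset_h + rng.uniform(0.0, span, n)
    h, w = config.scene_shape
    r = rng.uniform(0.0, h, n)
    c = rng.uniform(0.0, w, n)
    order = np.argsort(t, kind="stable")
    return PatchSet(t[order], r[order], c[order])


def _raw_count_field(
    patches: PatchSet, t: float, growth: float, shape: Tuple[int, int]
) -> np.ndarray:
    """Number of patch disks covering each scene pixel at time ``t``."""
    field = np.zeros(shape, dtype=np.float32)
    h, w = shape
    for ti, r0, c0 in zip(patches.times_h, patches.rows, patches.cols):
        if ti > t:
            break  # patches sorted by nucleation time
        radius = growth * (t - ti)
        if radius < 0.5:
            continue
        rlo, rhi = max(0, int(r0 - radius)), min(h, int(r0 + radius) + 2)
        clo, chi = max(0, int(c0 - radius)), min(w, int(c0 + radius) + 2)
        if rlo >= rhi or clo >= chi:
            continue
        dy = (np.arange(rlo, rhi) - r0)[:, None]
        dx = (np.arange(clo, chi) - c0)[None, :]
        field[rlo:rhi, clo:chi] += (dy * dy + dx * dx) <= radius * radius
    return field


def _raw_area_fraction(patches: PatchSet, t: float, growth: float, area: float) -> float:
    """Total (overlap-counted) disk area fraction at time ``t``."""
    dt = t - patches.times_h
    dt = dt[dt > 0]
    return float(np.pi * np.sum((growth * dt) ** 2) / area)


def _cip_factor(config: ScenarioConfig, t_prev: float, t_now: float) -> float:
    """Product of (1 - efficacy) over CIP events in (t_prev, t_now]."""
    f = 1.0
    for t_e, eff in config.cip_events:
        if t_prev < t_e <= t_now:
            f *= 1.0 - eff
    return f


def coverage_timeline(
    config: ScenarioConfig, times: Optional[np.ndarray] = None
) -> np.ndarray:
    """Scene-mean coverage fraction over time (scalar latent trajectory).

    Shares the patch stream with :func:`simulate_image_series`, so the fiber
    and image simulators respond to the same biofilm history. Deposit density
    accumulates between CIP events and is multiplied by ``1 - efficacy`` at
    each event; coverage is ``1 - exp(-density)``.
    """
    if times is None:
        times = config.sensor_times
    patches = draw_patches(config, _rng_streams(config)["patches"])
    h, w = config.scene_shape
    area = float(h) * float(w)
    cov = np.zeros(len(times))
    density = 0.0
    prev_raw = 0.0
    t_prev = -np.inf
    for j, t in enumerate(times):
        raw = _raw_area_fraction(patches, t, config.patch_growth_rate, area)
        density = density * _cip_factor(config, t_prev, t) + (raw - prev_raw)
        prev_raw, t_prev = raw, t
        cov[j] = -np.expm1(-density)
    return cov


# ---------------------------------------------------------------------------
# image series
# ---------------------------------------------------------------------------


def simulate_image_series(
    config: ScenarioConfig, keep_fields: bool = False
) -> Tuple[List[ImageFrame], CoverageField, List[Tuple[int, int]]]:
    """Simulate the camera time series.

    Returns ``(frames, coverage, planted_offsets)``. Frame 0 is the clean
    reference with planted offset (0, 0); every later frame is a crop of the
    latent scene translated by an integer offset drawn uniformly in
    ``[-jitter_max, jitter_max]²`` (the offset of the sensed frame relative
    to the reference, i.e. what registration should recover). Pixel
    intensity per channel is::

        clean · (1 - coverage · attenuation_channel) · illumination + noise

    clipped to the 8-bit range. Coverage is zero before ``onset_h``.
    """
    rngs = _rng_streams(config)
    scene = make_clean_scene(config, rngs["texture"])
    patches = draw_patches(config, rngs["patches"])
    times = config.frame_times
    jmax = config.jitter_max

    offsets: List[Tuple[int, int]] = [(0, 0)]
    if len(times) > 1:
        draws = rngs["jitter"].integers(-jmax, jmax + 1, size=(len(times) - 1, 2))
        offsets += [(int(dr), int(dc)) for dr, dc in draws]

    h, w = config.frame_height, config.frame_width
    atten = np.asarray(config.channel_attenuation, dtype=np.float32)
    noise_rng = rngs["image_noise"]

    frames: List[ImageFrame] = []
    fractions = np.zeros(len(times))
    fields: Optional[List[np.ndarray]] = [] if keep_fields else None
    density = np.zeros(config.scene_shape, dtype=np.float32)
    prev_raw = np.zeros_like(density)
    cov = np.zeros_like(density)
    t_prev = -np.inf

    for j, t in enumerate(times):
        if len(patches):
            raw = _raw_count_field(patches, t, config.patch_growth_rate, config.scene_shape)
            density = density * _cip_factor(config, t_prev, t) + (raw - prev_raw)
            prev_raw = raw
            cov = -np.expm1(-density)
        t_prev = t

        dr, dc = offsets[j]
        r0, c0 = jmax - dr, jmax - dc
        view = scene[r0 : r0 + h, c0 : c0 + w]
        cov_view = cov[r0 : r0 + h, c0 : c0 + w]
        illum = np.float32(1.0 + config.illumination_drift * t / 100.0)

        shaded = view[:, :, None] * (1.0 - cov_view[:, :, None] * atten) * illum
        if config.noise_sd > 0:
            shaded = shaded + config.noise_sd * noise_rng.standard_normal(
                (h, w, 3), dtype=np.float32
            )
        pixels = np.clip(np.rint(shaded), 0, 255).astype(np.uint8)

        frames.append(ImageFrame(pixels, time_h=float(t), source_id=f"frame_{j:05d}"))
        fractions[j] = float(cov_view.mean())
        if fields is not None:
            fields.append(cov.copy())

    coverage = CoverageField(fractions, cov.copy(), fields)
    return frames, coverage, offsets


# ---------------------------------------------------------------------------
# POF transmission
# ---------------------------------------------------------------------------


def simulate_pof_series(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate sensor- and reference-fiber transmission.

    sensor(t) = envelope(t) · (1 + a·sin(2πt/24)) · exp(-k · min(c(t), cap))
    with envelope(t) = (1 - A) + A·exp(-t/τ); the reference fiber omits the
    fouling factor. Both traces are normalized to 1 at t = 0. Columns:
    ``time_h, sensor, reference``.
    """
    p = config.pof_params
    t = config.sensor_times
    cov = coverage_timeline(config, t)
    env = (1.0 - p.decay_amplitude) + p.decay_amplitude * np.exp(-t / p.decay_tau_h)
    diurnal = 1.0 + p.diurnal_amplitude * np.sin(2.0 * np.pi * t / 24.0)
    capped = np.minimum(cov, p.plateau_coverage)
    sensor = env * diurnal * np.exp(-p.fouling_attenuation * capped)
    reference = env * diurnal
    if config.pof_noise_sd > 0:
        rng = _rng_streams(config)["pof_noise"]
        sensor = sensor * (1.0 + rng.normal(0.0, config.pof_noise_sd, len(t)))
        reference = reference * (1.0 + rng.normal(0.0, config.pof_noise_sd, len(t)))
    sensor = sensor / sensor[0]
    reference = reference / reference[0]
    return pd.DataFrame({"time_h": t, "sensor": sensor, "reference": reference})


# ---------------------------------------------------------------------------
# process records
# ---------------------------------------------------------------------------


def _ramp(t: np.ndarray, start: float, width: float) -> np.ndarray:
    return np.clip((t - start) / width, 0.0, 1.0)


def simulate_process_series(
    config: ScenarioConfig,
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Simulate the process-data table and its phase ground truth.

    The carbon rate follows a two-phase template: zero before onset, a ramp
    to ``-carbon_pulse_mg_h`` during the attachment phase, then a single sign
    change to ``+carbon_pulse_mg_h`` once detachment starts at
    ``onset + detach_lag_h``. Permeability rises slightly after the feed
    switch (pH-driven surface-charge effect) and declines from
    ``onset + perm_decline_lag_h``; the feed-channel pressure drop (FCP) is
    flat and starts rising last, at ``onset + fcp_lag_h``.

    Returns ``(table, truth)`` where ``truth`` records the phase boundaries
    and the noise-free carbon-rate template.
    """
    pp = config.process_params
    t = config.sensor_times
    n = len(t)
    rng = _rng_streams(config)["process_noise"]

    fouling = config.nucleation_rate > 0 and config.onset_h < config.duration_h
    onset = config.onset_h
    ramp_h = 20.0

    c_true = np.zeros(n)
    if fouling:
        t_detach = onset + config.detach_lag_h
        amp = config.carbon_pulse_mg_h
        c_true = -amp * _ramp(t, onset, ramp_h) + 2.0 * amp * _ramp(t, t_detach, ramp_h)
        carbon_sign_change = t_detach + ramp_h / 2.0
    else:
        t_detach = None
        carbon_sign_change = None

    vdot_feed = np.full(n, pp.feed_flow_l_h)
    vdot_ret = np.full(n, pp.retentate_flow_l_h)
    vdot_p = vdot_feed - vdot_ret

    toc_feed = pp.baseline_toc_mg_l + rng.normal(0.0, config.toc_noise_sd, n)
    toc_ret = (
        c_true + pp.baseline_toc_mg_l * vdot_feed
    ) / vdot_ret + rng.normal(0.0, config.toc_noise_sd, n)

    # permeability: pH-driven rise after the feed switch, fouling decline later
    base_pw = vdot_p / (pp.membrane_area_m2 * pp.baseline_tmp_bar)
    rise = 1.0 + 0.05 * (1.0 - np.exp(-np.maximum(t - onset, 0.0) / 40.0)) * (t >= onset)
    perm_decline_start = onset + config.perm_decline_lag_h if fouling else None
    decline = np.ones(n)
    if fouling:
        decline = 1.0 - 0.3 * _ramp(t, perm_decline_start, 60.0)
    pw_true = base_pw * rise * decline
    tmp_net = vdot_p / (pp.membrane_area_m2 * pw_true)
    tmp_net = tmp_net * (1.0 + rng.normal(0.0, config.tmp_noise_rel, n))

    fcp_start = onset + config.fcp_lag_h if fouling else None
    fcp = np.full(n, config.fcp_baseline_mbar)
    if fouling:
        dt = np.maximum(t - fcp_start, 0.0)
        fcp = fcp + 0.05 * dt + 0.002 * dt * dt
    fcp = fcp + rng.normal(0.0, config.fcp_noise_sd_mbar, n)

    table = pd.DataFrame(
        {
            "time_h": t,
            "TOC_Feed": toc_feed,
            "TOC_Ret": toc_ret,
            "Vdot_Feed": vdot_feed,
            "Vdot_Ret": vdot_ret,
            "Vdot_p": vdot_p,
            "TMPnet": tmp_net,
            "FCP": fcp,
            "membrane_area": np.full(n, pp.membrane_area_m2),
        }
    )
    truth: Dict[str, object] = {
        "onset_h": onset if fouling else None,
        "detach_start_h": t_detach,
        "carbon_sign_change_h": carbon_sign_change,
        "perm_decline_start_h": perm_decline_start,
        "fcp_start_h": fcp_start,
        "carbon_rate_true": c_true,
        "permeability_true": pw_true,
    }
    return table, truth


# ---------------------------------------------------------------------------
# on-disk scenario
# ---------------------------------------------------------------------------


def write_scenario(
    config: ScenarioConfig, outdir: Union[str, Path]
) -> Dict[str, Path]:
    """Materialize a full scenario on disk.

    Writes ``frame_<index:05d>.tiff`` + ``manifest.csv``, ground truth as
    ``truth.json`` (planted offsets, onset, phase boundaries, coverage per
    frame, RNG contract), and ``pof.csv`` / ``process.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    frames, coverage, offsets = simulate_image_series(config)
    entries = []
    for j, frame in enumerate(frames):
        name = f"frame_{j:05d}.tiff"
        write_frame(frame, outdir / name)
        entries.append((frame.time_h, name))
    manifest = write_manifest(entries, outdir / "manifest.csv")

    pof = simulate_pof_series(config)
    pof_path = outdir / "pof.csv"
    pof.to_csv(pof_path, index=False)

    process, proc_truth = simulate_process_series(config)
    process_path = outdir / "process.csv"
    process.to_csv(process_path, index=False)

    truth = {
        "rng": "numpy PCG64 via SeedSequence child streams "
        + "/".join(_STREAMS),
        "seed": config.seed,
        "onset_h": config.onset_h,
        "planted_offsets": [list(o) for o in offsets],
        "coverage_fraction": coverage.fraction.tolist(),
        "cip_events": [list(e) for e in config.cip_events],
        "phase_boundaries": {
            k: (None if v is None else float(v))
            for k, v in proc_truth.items()
            if k.endswith("_h")
        },
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))

    return {
        "manifest": manifest,
        "truth": truth_path,
        "pof": pof_path,
        "process": process_path,
    }
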