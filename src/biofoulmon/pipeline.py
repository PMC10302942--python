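"""End-to-end analysis of one scenario: simulate → register → similarity →
process metrics → onset detection.

This is glue over the library modules, used by the CLI, the test suite and
the acceptance script. Detector baselines are expressed in *hours* here
(24 h, matching the 24-sample default at the 1 h sampling interval) and
converted to samples per signal, so image series sampled more coarsely than
1 h still use a comparable baseline span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ScenarioConfig, default_margins
from .onset_detection import CIPReport, OnsetReport, detect_onset, evaluate_cip
from .process_metrics import derive_series
from .registration import RegistrationResult, TemplateROI, register_series
from .similarity import similarity_series
from .synthetic_data import (
    simulate_image_series,
    simulate_pof_series,
    simulate_process_series,
)

#: signal name → (direction, series description) analysed by default
SIGNAL_DIRECTIONS = {
    "pof_sensor": "decrease",
    "r_blue": "decrease",
    "permeability": "decrease",
    "fcp": "increase",
}


def centered_roi(shape: Tuple[int, int], size: int = 64) -> TemplateROI:
    """A square feature ROI centered on the frame (the spacer mesh is
    everywhere, so the center is always feature-rich)."""
    h, w = shape[:2]
    size = min(size, h // 2, w // 2)
    size = max(size, 8)
    return TemplateROI((h - size) // 2, (w - size) // 2, size, size)


def _baseline_samples(interval_h: float, baseline_h: float = 24.0) -> int:
    return max(8, int(round(baseline_h / interval_h)))


@dataclass
class ScenarioAnalysis:
    similarity: pd.DataFrame
    pof: pd.DataFrame
    derived: pd.DataFrame
    onsets: Dict[str, OnsetReport]
    cip: List[CIPReport]
    registration: RegistrationResult
    planted_offsets: List[Tuple[int, int]]
    truth: Dict[str, object]

    def ordering_ok(self) -> bool:
        """Canonical early-warning ordering of the detected onsets.

        Fiber transmission and the blue-layer correlation react first, then
        permeability declines, and the feed-channel pressure drop rises
        last. Requires every signal to have reported an onset.
        """
        o = {k: v.onset_time_h for k, v in self.onsets.items()}
        if any(o.get(k) is None for k in SIGNAL_DIRECTIONS):
            return False
        return (
            max(o["pof_sensor"], o["r_blue"]) < o["permeability"] < o["fcp"]
        )


def detect_all(
    similarity: pd.DataFrame,
    pof: pd.DataFrame,
    derived: pd.DataFrame,
    k: float = 3.0,
    persistence: int = 5,
    conditioning_cutoff_h: Optional[float] = 96.0,
    baseline_h: float = 24.0,
    detrend: bool = False,
) -> Dict[str, OnsetReport]:
    """Run the onset detector on the four standard indicator series."""
    onsets: Dict[str, OnsetReport] = {}

    def _run(name: str, t, v, direction: str, interval: float) -> None:
        onsets[name] = detect_onset(
            t,
            v,
            direction,
            baseline_window=_baseline_samples(interval, baseline_h),
            k=k,
            persistence=persistence,
            conditioning_cutoff_h=conditioning_cutoff_h,
            detrend=detrend,
            signal=name,
        )

    ts = similarity["time_h"].to_numpy()
    img_dt = float(np.median(np.diff(ts))) if len(ts) > 1 else 1.0
    _run("r_blue", ts, similarity["r_blue"].to_numpy(), "decrease", img_dt)

    tp = pof["time_h"].to_numpy()
    pof_dt = float(np.median(np.diff(tp))) if len(tp) > 1 else 1.0
    _run("pof_sensor", tp, pof["sensor"].to_numpy(), "decrease", pof_dt)

    td = derived["time_h"].to_numpy()
    proc_dt = float(np.median(np.diff(td))) if len(td) > 1 else 1.0
    _run("permeability", td, derived["permeability"].to_numpy(), "decrease", proc_dt)
    if "FCP" in derived.columns:
        _run("fcp", td, derived["FCP"].to_numpy(), "increase", proc_dt)
    return onsets


def analyze_scenario(
    config: ScenarioConfig,
    roi: Optional[TemplateROI] = None,
    margins: Optional[Tuple[int, int]] = None,
    reference_index: int = 0,
    k: float = 3.0,
    persistence: int = 5,
    conditioning_cutoff_h: Optional[float] = 96.0,
) -> ScenarioAnalysis:
    """Simulate a scenario and run the full monitoring pipeline on it."""
    frames, _coverage, planted = simulate_image_series(config)
    if margins is None:
        margins = default_margins(config)
    if roi is None:
        roi = centered_roi(frames[0].pixels.shape)
    reg = register_series(
        frames, roi, reference_index=reference_index, margins=margins
    )
    sim = similarity_series(reg.frames, reference_index=reference_index)
    pof = simulate_pof_series(config)
    process, truth = simulate_process_series(config)
    derived = derive_series(process)

    onsets = detect_all(
        sim,
        pof,
        derived,
        k=k,
        persistence=persistence,
        conditioning_cutoff_h=conditioning_cutoff_h,
    )
    cip: List[CIPReport] = []
    if config.cip_events:
        pof96 = pof[pof["time_h"] >= (conditioning_cutoff_h or 0.0)]
        cip = evaluate_cip(
            pof96["time_h"].to_numpy(),
            pof96["sensor"].to_numpy(),
            [t for t, _ in config.cip_events],
        )
    return ScenarioAnalysis(
        similarity=sim,
        pof=pof,
        derived=derived,
        onsets=onsets,
        cip=cip,
        registration=reg,
        planted_offsets=planted,
        truth=truth,
    )
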