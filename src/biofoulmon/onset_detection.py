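"""Onset, plateau and cleaning-recovery calls on monitoring time series.

Detection is a deliberately simple baseline-threshold rule: estimate the
baseline mean μ and standard deviation σ from the first ``baseline_window``
samples (after an optional conditioning cutoff — fiber transmission is not
trustworthy until its conditioning decay has leveled off), then report an
onset at the first time the signal stays beyond μ ∓ k·σ in the stated
direction for at least ``persistence`` consecutive samples. All parameters
are exposed; defaults are k = 3, persistence = 5, baseline of 24 samples,
conditioning cutoff 96 h. The optional diurnal filter (off by default)
replaces the signal by its centered 24 h rolling median before detection,
which cancels the daily temperature cycle.

Note that on gradually growing signals the *detected* onset necessarily lags
the physical one: the deviation must first grow past k·σ. An optional 24 h
rolling-median detrend (off by default) removes diurnal modulation before
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import InputError

Series = Union[pd.Series, np.ndarray, Sequence[float]]


@dataclass
class OnsetReport:
    signal: str
    onset_time_h: Optional[float]
    baseline_mean: float
    baseline_sd: float
    direction: str
    k: float
    persistence: int
    baseline_window: int
    plateau_time_h: Optional[float] = None


@dataclass
class CIPReport:
    """Recovery bookkeeping for one cleaning-in-place event."""

    time_h: float
    pre_level: float
    post_level: float
    #: fraction of the cumulative loss (baseline − pre) regained, clamped [0, 1]
    recovery: float


def _validate_xy(time_h: Series, values: Series) -> Tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise InputError("time and values must be equal-length 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise InputError("time axis must be strictly increasing")
    return t, v


def _diurnal_median_filter(t: np.ndarray, v: np.ndarray, window_h: float = 24.0) -> np.ndarray:
    """Centered rolling median over one diurnal period.

    The median over a full 24 h window is phase-independent, so the daily
    temperature cycle drops out while persistent level shifts survive.
    """
    return (
        pd.Series(v, index=pd.to_timedelta(t, unit="h"))
        .rolling(pd.Timedelta(hours=window_h), center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def detect_onset(
    time_h: Series,
    values: Series,
    direction: str,
    baseline_window: int = 24,
    k: float = 3.0,
    persistence: int = 5,
    conditioning_cutoff_h: Optional[float] = 96.0,
    detrend: bool = False,
    signal: str = "",
) -> OnsetReport:
    """First persistent deviation beyond the baseline band.

    ``direction`` is ``"decrease"`` or ``"increase"``. Samples before
    ``conditioning_cutoff_h`` are discarded before anything else (pass
    ``None`` to keep the full series). Raises :class:`InputError` when fewer
    than ``baseline_window + persistence`` samples remain.
    """
    if direction not in ("decrease", "increase"):
        raise InputError(f"direction must be 'decrease' or 'increase', got {direction!r}")
    if baseline_window < 2 or persistence < 1:
        raise InputError("baseline_window must be >= 2 and persistence >= 1")
    t, v = _validate_xy(time_h, values)
    if conditioning_cutoff_h is not None:
        keep = t >= conditioning_cutoff_h
        t, v = t[keep], v[keep]
    if len(t) <= baseline_window + persistence:
        raise InputError(
            f"series too short: {len(t)} samples <= baseline_window "
            f"({baseline_window}) + persistence ({persistence})"
        )
    if detrend:
        v = _diurnal_median_filter(t, v)

    mu = float(np.mean(v[:baseline_window]))
    sd = float(np.std(v[:baseline_window], ddof=1))
    if direction == "decrease":
        beyond = v < mu - k * sd
    else:
        beyond = v > mu + k * sd
    beyond = beyond[baseline_window:]
    t_post = t[baseline_window:]

    onset: Optional[float] = None
    run = 0
    for i, flag in enumerate(beyond):
        run = run + 1 if flag else 0
        if run >= persistence:
            onset = float(t_post[i - persistence + 1])
            break
    return OnsetReport(
        signal=signal,
        onset_time_h=onset,
        baseline_mean=mu,
        baseline_sd=sd,
        direction=direction,
        k=k,
        persistence=persistence,
        baseline_window=baseline_window,
    )


def detect_plateau(
    time_h: Series,
    values: Series,
    window: int = 24,
    slope_tol: float = 1e-3,
    after_time_h: Optional[float] = None,
) -> Optional[float]:
    """Earliest time a rolling least-squares slope stays within ±slope_tol.

    The slope (signal units per hour) is fit over each run of ``window``
    consecutive samples starting at or after ``after_time_h`` (typically a
    detected onset); the reported plateau time is the *end* of the first
    quiet window — constancy is only confirmed after observing it. Returns
    ``None`` when the series never settles.
    """
    t, v = _validate_xy(time_h, values)
    if window < 3:
        raise InputError("plateau window must span at least 3 samples")
    if len(t) <= window:
        raise InputError("series shorter than the plateau window")
    start = 0
    if after_time_h is not None:
        start = int(np.searchsorted(t, after_time_h, side="left"))
    for i in range(start, len(t) - window + 1):
        tw = t[i : i + window]
        vw = v[i : i + window]
        slope = np.polyfit(tw - tw[0], vw, 1)[0]
        if abs(slope) <= slope_tol:
            return float(tw[-1])
    return None


def evaluate_cip(
    time_h: Series,
    values: Series,
    cip_times: Sequence[float],
    flank: int = 5,
    baseline_window: int = 24,
) -> List[CIPReport]:
    """Recovery magnitude per cleaning-in-place event.

    ``recovery = (post − pre) / (baseline − pre)`` with medians over
    ``flank`` samples immediately before/after each event and the baseline
    median over the first ``baseline_window`` samples (the pre-fouling
    level). Clamped to [0, 1]; an event with no signal change scores 0.
    """
    t, v = _validate_xy(time_h, values)
    if flank < 1 or baseline_window < 1:
        raise InputError("flank and baseline_window must be positive")
    baseline = float(np.median(v[: min(baseline_window, len(v))]))
    reports: List[CIPReport] = []
    for t_e in sorted(float(x) for x in cip_times):
        if not t[0] < t_e < t[-1]:
            raise InputError(
                f"CIP event at {t_e} h outside the series range "
                f"[{t[0]}, {t[-1]}] h"
            )
        i = int(np.searchsorted(t, t_e, side="left"))
        pre_lo = max(0, i - flank)
        if pre_lo == i or i + flank > len(v):
            raise InputError(f"CIP event at {t_e} h too close to the series edge")
        pre = float(np.median(v[pre_lo:i]))
        post = float(np.median(v[i : i + flank]))
        denom = baseline - pre
        recovery = 0.0 if denom == 0.0 else (post - pre) / denom
        reports.append(
            CIPReport(
                time_h=t_e,
                pre_level=pre,
                post_level=post,
                recovery=float(np.clip(recovery, 0.0, 1.0)),
            )
        )
    return reports
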