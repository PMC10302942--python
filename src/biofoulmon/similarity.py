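"""Per-RGB-layer 2-D Pearson similarity against a clean reference frame.

The biofouling indicator: each registered frame is split into its R, G and B
layers and each layer is correlated pixel-by-pixel with the corresponding
layer of the reference frame (the initial, pre-fouling photo),

    r = Σ_m Σ_n (A_mn - Ā)(B_mn - B̄)
        / sqrt( Σ(A_mn - Ā)² · Σ(B_mn - B̄)² ),

which is exactly the Pearson coefficient of the flattened pixel vectors.
Biofilm turns the near-white membrane brown, so the blue layer decorrelates
first and hardest while the red layer stays close to 1 — the per-layer split
is what makes the indicator sensitive.

Layers are correlated on their native [0, 255] scale in double precision;
Pearson r is scale-invariant so no normalization is needed. A zero-variance
layer makes r undefined and is reported as missing with a reason, never as a
numeric value (a constant frame is an instrument fault).
"""

from __future__ import annotations

from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DimensionError, UndefinedSimilarityError
from .image_io import GrayImage

ArrayLike = Union[np.ndarray, GrayImage]


def _as_matrix(x: ArrayLike) -> np.ndarray:
    pixels = x.pixels if isinstance(x, GrayImage) else np.asarray(x)
    return np.asarray(pixels, dtype=np.float64)


def split_channels(frame) -> Tuple[GrayImage, GrayImage, GrayImage]:
    """Split an RGB frame into its R, G, B layers, values preserved.

    Accepts anything with an ``H×W×3`` ``pixels`` attribute (ImageFrame or
    RegisteredFrame).
    """
    pixels = np.asarray(frame.pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise DimensionError(f"expected H×W×3 pixels, got shape {pixels.shape}")
    sid = getattr(frame, "source_id", "")
    return tuple(
        GrayImage(pixels[..., ch].astype(np.float64), provenance=f"{sid}:{name}")
        for ch, name in enumerate("RGB")
    )


def pearson2d(a: ArrayLike, b: ArrayLike) -> float:
    """2-D Pearson correlation coefficient between two equal-sized matrices.

    Raises :class:`DimensionError` on shape mismatch and
    :class:`UndefinedSimilarityError` when either matrix has zero variance.
    The result is clamped to [-1, 1] against rounding.
    """
    am, bm = _as_matrix(a), _as_matrix(b)
    if am.shape != bm.shape:
        raise DimensionError(f"shape mismatch: {am.shape} vs {bm.shape}")
    ac = am - am.mean()
    bc = bm - bm.mean()
    ssa = float(np.sum(ac * ac))
    ssb = float(np.sum(bc * bc))
    if ssa == 0.0 or ssb == 0.0:
        raise UndefinedSimilarityError(
            "Pearson r undefined: zero variance in "
            + ("both matrices" if ssa == ssb == 0.0 else "one matrix")
        )
    r = float(np.sum(ac * bc)) / np.sqrt(ssa * ssb)
    return float(np.clip(r, -1.0, 1.0))


def similarity_series(
    frames: Sequence, reference_index: int = 0
) -> pd.DataFrame:
    """Per-frame, per-layer Pearson r against the reference frame.

    Returns a DataFrame with columns ``time_h, r_red, r_green, r_blue,
    status`` sorted by time; ``status`` is ``"ok"`` or the reason a value is
    missing (recorded as NaN). The reference frame scores r = 1 in every
    layer by construction.
    """
    if len(frames) < 2:
        raise DimensionError("similarity series needs at least 2 frames")
    shapes = {np.asarray(f.pixels).shape for f in frames}
    if len(shapes) != 1:
        raise DimensionError(f"frames have inconsistent shapes: {sorted(shapes)}")
    if not 0 <= reference_index < len(frames):
        raise DimensionError(f"reference index {reference_index} out of range")

    ref_layers = split_channels(frames[reference_index])
    rows = []
    for frame in frames:
        layers = split_channels(frame)
        values = []
        status = "ok"
        for ref, layer in zip(ref_layers, layers):
            try:
                values.append(pearson2d(ref, layer))
            except UndefinedSimilarityError as exc:
                values.append(np.nan)
                sid = getattr(frame, "source_id", "") or f"t={frame.time_h}"
                status = f"undefined ({sid}): {exc}"
        rows.append((frame.time_h, *values, status))
    df = pd.DataFrame(
        rows, columns=["time_h", "r_red", "r_green", "r_blue", "status"]
    )
    df = df.sort_values("time_h", kind="stable").reset_index(drop=True)
    df.attrs["reference_time_h"] = float(frames[reference_index].time_h)
    return df
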