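"""Template-matching image registration.

Every sensed frame is aligned to a common coordinate system by normalized
cross-correlation (NCC) between a manually chosen feature template from the
reference frame and the grayscale version of each sensed frame: feature
selection, NCC matching, peak extraction, and a compensating crop. The motion
model is a pure integer translation — the camera and module wobble, they do
not rotate — and the crop sacrifices a margin of the frame as movement room,
so a 2064×3088 input with the default (127, 175) margins yields 1937×2913
registered frames.

NCC scores are the Pearson correlation between the template and each
same-sized, fully contained ("valid") image window; windows with zero
variance have no defined score and are excluded from the peak search. The
map itself is computed with :func:`skimage.feature.match_template` (FFT
based) and agrees with the brute-force per-window Pearson definition to
better than 1e-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .errors import (
    DimensionError,
    ExcessiveMotionError,
    FeaturelessTemplateError,
    InputError,
    UndefinedPeakError,
)
from .image_io import GrayImage, ImageFrame, to_grayscale

logger = logging.getLogger(__name__)

#: default crop margins (rows, cols): 2064×3088 → 1937×2913
DEFAULT_MARGINS = (127, 175)


@dataclass(frozen=True)
class TemplateROI:
    """Feature region on the reference frame, 0-based half-open intervals."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise InputError("template ROI must be at least 8×8")
        if self.row0 < 0 or self.col0 < 0:
            raise InputError("ROI origin must be non-negative")

    @property
    def slices(self) -> Tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


@dataclass
class NCCMap:
    """Correlation score per valid template placement.

    ``scores[u, v]`` is the Pearson r between the template and the image
    window whose top-left corner is (u, v); undefined placements (zero
    window variance) are NaN. ``origin`` is the template's position in the
    reference frame so that peak locations convert to offsets.
    """

    scores: np.ndarray
    origin: Tuple[int, int] = (0, 0)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.scores.shape


@dataclass(frozen=True)
class Offset:
    """Integer translation of a sensed frame relative to the reference."""

    drow: int
    dcol: int
    peak_score: float = float("nan")


@dataclass
class RegisteredFrame:
    """A color frame cropped into the common registered coordinate system."""

    pixels: np.ndarray
    time_h: float
    offset: Offset
    source_id: str = ""

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.pixels.shape


def extract_template(reference: GrayImage, roi: TemplateROI) -> GrayImage:
    """Pixel-exact crop of the feature region from the reference image."""
    h, w = reference.shape
    if roi.row0 + roi.height > h or roi.col0 + roi.width > w:
        raise InputError(
            f"ROI {roi} does not fit inside a {h}×{w} reference image"
        )
    crop = reference.pixels[roi.slices]
    if float(np.ptp(crop)) == 0.0:
        raise FeaturelessTemplateError(
            "featureless template: zero variance, NCC undefined"
        )
    return GrayImage(crop.copy(), provenance=f"{reference.provenance}:roi{roi}")


def _window_variance_mask(image: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Boolean mask of sliding windows with (numerically) zero variance."""
    n = th * tw
    ii = np.zeros((image.shape[0] + 1, image.shape[1] + 1))
    ii2 = np.zeros_like(ii)
    np.cumsum(np.cumsum(image, axis=0), axis=1, out=ii[1:, 1:])
    np.cumsum(np.cumsum(image * image, axis=0), axis=1, out=ii2[1:, 1:])
    s = ii[th:, tw:] - ii[:-th, tw:] - ii[th:, :-tw] + ii[:-th, :-tw]
    s2 = ii2[th:, tw:] - ii2[:-th, tw:] - ii2[th:, :-tw] + ii2[:-th, :-tw]
    var_mean = (s2 - s * s / n) / n
    mean_sq = s2 / n
    # relative threshold: cumsum cancellation error is far below 1e-9 of the
    # mean square for any genuinely textured window
    return var_mean <= 1e-9 * np.maximum(mean_sq, 1e-30)


def ncc_map(
    template: GrayImage, sensed: GrayImage, origin: Tuple[int, int] = (0, 0)
) -> NCCMap:
    """Normalized cross-correlation over all valid template placements.

    Output shape is ``(H - h + 1, W - w + 1)`` for an ``H×W`` sensed image
    and ``h×w`` template. Zero-variance windows are NaN.
    """
    th, tw = template.shape
    sh, sw = sensed.shape
    if th >= sh or tw >= sw:
        raise DimensionError(
            f"template {th}×{tw} must be strictly smaller than sensed "
            f"image {sh}×{sw} in both dimensions"
        )
    if float(np.ptp(template.pixels)) == 0.0:
        raise FeaturelessTemplateError(
            "featureless template: zero variance, NCC undefined"
        )
    scores = match_template(sensed.pixels, template.pixels, pad_input=False)
    scores = np.clip(scores.astype(np.float64), -1.0, 1.0)
    undefined = _window_variance_mask(sensed.pixels, th, tw)
    if undefined.any():
        scores = scores.copy()
        scores[undefined] = np.nan
    return NCCMap(scores, origin=origin)


def locate_peak(nmap: NCCMap) -> Offset:
    """Argmax of the NCC map, as an offset relative to the reference ROI.

    Ties break to the smallest row, then smallest column (row-major first
    maximum). Raises :class:`UndefinedPeakError` if no placement is defined.
    """
    scores = nmap.scores
    finite = np.isfinite(scores)
    if not finite.any():
        raise UndefinedPeakError("all NCC placements are undefined")
    flat = np.where(finite, scores, -np.inf)
    idx = int(np.argmax(flat))  # first occurrence in row-major order
    r, c = np.unravel_index(idx, scores.shape)
    return Offset(
        drow=int(r) - nmap.origin[0],
        dcol=int(c) - nmap.origin[1],
        peak_score=float(scores[r, c]),
    )


def register_frame(
    frame: ImageFrame,
    offset: Offset,
    margins: Tuple[int, int] = DEFAULT_MARGINS,
) -> RegisteredFrame:
    """Crop a frame so its features land on the common coordinate origin.

    The crop window of size ``(H - Mr) × (W - Mc)`` is anchored at
    ``floor(margin / 2)`` in the reference and shifted by the estimated
    offset in each sensed frame; offsets beyond ``floor(margin / 2)`` exceed
    the movement room and raise :class:`ExcessiveMotionError`.
    """
    mr, mc = margins
    h, w = frame.pixels.shape[:2]
    if mr <= 0 or mc <= 0 or mr >= h or mc >= w:
        raise InputError(f"margins {margins} invalid for a {h}×{w} frame")
    anchor_r, anchor_c = mr // 2, mc // 2
    if abs(offset.drow) > anchor_r or abs(offset.dcol) > anchor_c:
        raise ExcessiveMotionError(
            f"frame {frame.source_id or frame.time_h}: offset "
            f"({offset.drow}, {offset.dcol}) exceeds movement room "
            f"(±{anchor_r}, ±{anchor_c})"
        )
    r0 = anchor_r + offset.drow
    c0 = anchor_c + offset.dcol
    pixels = frame.pixels[r0 : r0 + h - mr, c0 : c0 + w - mc].copy()
    return RegisteredFrame(
        pixels, time_h=frame.time_h, offset=offset, source_id=frame.source_id
    )


@dataclass
class RegistrationResult:
    frames: List[RegisteredFrame]
    offsets: pd.DataFrame  # columns: time_h, drow, dcol, peak_score
    dropped: List[str] = field(default_factory=list)


def register_series(
    frames: Sequence[ImageFrame],
    roi: TemplateROI,
    reference_index: int = 0,
    margins: Tuple[int, int] = DEFAULT_MARGINS,
    on_failure: str = "abort",
    search_room: Optional[Tuple[int, int]] = None,
) -> RegistrationResult:
    """Register a whole time series against one reference frame.

    The translation is estimated on grayscale images and applied to the
    color frames. ``on_failure`` is either ``"abort"`` (default: the first
    frame whose motion exceeds the margins raises) or ``"drop"`` (failing
    frames are logged and omitted).

    The peak search is confined to ``search_room = (±rows, ±cols)`` around
    the ROI, by default the movement room ``floor(margin / 2)`` left by the
    crop: camera motion is bounded, an offset beyond the movement room could
    never be registered anyway, and a wider search invites false matches on
    the periodic spacer mesh (period ≈ frame_height/12) once the feature
    region itself becomes overgrown late in an experiment. Pass a larger
    ``search_room`` to *observe* excessive motion and exercise the abort /
    drop policy instead of silently clamping the search.
    """
    if on_failure not in ("abort", "drop"):
        raise InputError(f"unknown failure policy {on_failure!r}")
    if not frames:
        raise InputError("empty frame series")
    if not 0 <= reference_index < len(frames):
        raise InputError(f"reference index {reference_index} out of range")
    shapes = {f.pixels.shape for f in frames}
    if len(shapes) != 1:
        raise InputError(f"frames have inconsistent shapes: {sorted(shapes)}")

    reference_gray = to_grayscale(frames[reference_index])
    template = extract_template(reference_gray, roi)

    h, w = frames[0].pixels.shape[:2]
    if search_room is None:
        search_room = (margins[0] // 2, margins[1] // 2)
    rlo = max(0, roi.row0 - search_room[0])
    rhi = min(h, roi.row0 + roi.height + search_room[0])
    clo = max(0, roi.col0 - search_room[1])
    chi = min(w, roi.col0 + roi.width + search_room[1])
    # template position relative to the search window
    origin = (roi.row0 - rlo, roi.col0 - clo)

    registered: List[RegisteredFrame] = []
    records = []
    dropped: List[str] = []
    for frame in frames:
        gray = to_grayscale(frame)
        window = GrayImage(gray.pixels[rlo:rhi, clo:chi], provenance=gray.provenance)
        offset = locate_peak(ncc_map(template, window, origin=origin))
        try:
            registered.append(register_frame(frame, offset, margins))
        except ExcessiveMotionError as exc:
            if on_failure == "abort":
                raise
            logger.warning("dropping frame: %s", exc)
            dropped.append(frame.source_id or str(frame.time_h))
            continue
        records.append(
            (frame.time_h, offset.drow, offset.dcol, offset.peak_score)
        )
    offsets = pd.DataFrame(
        records, columns=["time_h", "drow", "dcol", "peak_score"]
    )
    return RegistrationResult(registered, offsets, dropped)
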