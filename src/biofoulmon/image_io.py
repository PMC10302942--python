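"""Reading and writing membrane-surface frames.

Frames are 8-bit RGB TIFFs (uncompressed, contiguous); a time series is a
directory of ``frame_<index:05d>.tiff`` files plus a ``manifest.csv`` mapping
``time_h`` to ``filename``. Anything that is not plain 8-bit RGB is rejected
rather than silently converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InputError

#: ITU-R BT.601 luma weights used for the RGB → grayscale conversion.
#: The exact coefficients (sum = 1) so an all-white frame maps to exactly 1.0.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class ImageFrame:
    """One RGB frame of the membrane surface.

    ``pixels`` is an ``H×W×3`` uint8 array in R,G,B channel order;
    ``time_h`` is the acquisition time in hours since the start of the run.
    """

    pixels: np.ndarray
    time_h: float
    source_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise FormatError(
                f"expected H×W×3 RGB pixels, got shape {p.shape}"
            )
        if p.shape[0] <= 0 or p.shape[1] <= 0:
            raise FormatError("frame dimensions must be positive")
        if p.dtype != np.uint8:
            raise FormatError(f"expected 8-bit pixels, got dtype {p.dtype}")
        self.pixels = p

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class GrayImage:
    """A single 2-D intensity matrix with provenance.

    Outputs of :func:`to_grayscale` are normalized to [0, 1]; channel layers
    split from an RGB frame keep their native [0, 255] scale (Pearson r and
    NCC are scale-invariant, so no rescaling is ever needed).
    """

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise FormatError(f"expected a 2-D matrix, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise FormatError("gray image contains non-finite values")
        self.pixels = p

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


def to_grayscale(frame: ImageFrame) -> GrayImage:
    """Convert an RGB frame to a [0, 1] grayscale matrix (BT.601 luma)."""
    wr, wg, wb = LUMA_WEIGHTS
    p = frame.pixels.astype(np.float64)
    gray = (wr * p[..., 0] + wg * p[..., 1] + wb * p[..., 2]) / 255.0
    return GrayImage(gray, provenance=f"{frame.source_id}:luma601")


def write_frame(frame: ImageFrame, path: Union[str, Path]) -> Path:
    """Write a frame as an uncompressed contiguous 8-bit RGB TIFF."""
    path = Path(path)
    tifffile.imwrite(path, frame.pixels, photometric="rgb", compression=None)
    return path


def load_frame(path: Union[str, Path], time_h: float = 0.0) -> ImageFrame:
    """Load an 8-bit RGB TIFF; pixel-exact round trip with :func:`write_frame`.

    Raises :class:`FormatError` for any other bit depth, channel count, or
    compressed data.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"frame file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        if page.compression != 1:  # 1 == no compression
            raise FormatError(
                f"{path.name}: expected uncompressed TIFF, got compression "
                f"{page.compression!r}"
            )
        pixels = tif.asarray()
    if pixels.dtype != np.uint8:
        raise FormatError(
            f"{path.name}: expected 8-bit unsigned samples, got {pixels.dtype}"
        )
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise FormatError(
            f"{path.name}: expected an H×W×3 RGB layout, got shape {pixels.shape}"
        )
    return ImageFrame(pixels, time_h=time_h, source_id=path.name)


def write_manifest(
    entries: Iterable[Tuple[float, str]], path: Union[str, Path]
) -> Path:
    """Write a ``manifest.csv`` with columns ``time_h, filename``."""
    path = Path(path)
    df = pd.DataFrame(list(entries), columns=["time_h", "filename"])
    df.to_csv(path, index=False)
    return path


def read_manifest(path: Union[str, Path]) -> List[Tuple[float, Path]]:
    """Read a frame manifest, sorted ascending by ``time_h``.

    Frame paths are resolved relative to the manifest's directory. Duplicate
    timestamps and missing columns are input errors naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = {"time_h", "filename"} - set(df.columns)
    if missing:
        raise InputError(
            f"{path.name}: missing manifest column(s) {sorted(missing)}"
        )
    df = df.sort_values("time_h", kind="stable").reset_index(drop=True)
    dup = df["time_h"].duplicated()
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise InputError(
            f"{path.name}: duplicate time_h={row['time_h']} "
            f"(filename {row['filename']})"
        )
    base = path.parent
    return [
        (float(t), base / str(name))
        for t, name in zip(df["time_h"], df["filename"])
    ]


def load_series(manifest_path: Union[str, Path]) -> List[ImageFrame]:
    """Load every frame listed in a manifest, in time order."""
    return [load_frame(p, time_h=t) for t, p in read_manifest(manifest_path)]
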