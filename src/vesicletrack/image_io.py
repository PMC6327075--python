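"""Reading ordered grayscale frame sequences.

Confocal exports are often stored as RGB files whose three channels are
identical; this module reduces them to single-channel arrays and enforces a
consistent frame order and geometry across the sequence.

Coordinate convention: pixel (row, col), 0-based, row increasing downward.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError, VesicleTrackError

logger = logging.getLogger(__name__)

#: file name patterns recognised when scanning a directory
DEFAULT_PATTERNS = ("*.tif", "*.tiff", "*.png")


@dataclass(frozen=True)
class GrayscaleFrame:
    """One frame's pixel intensities, the unit of detection.

    Attributes
    ----------
    pixels:
        2-D array of intensities. 8-bit input lies in [0, 254]; 16-bit
        input is kept as-is (detection thresholds are relative after
        normalization, so absolute depth is harmless).
    frame_index:
        1-based position of the frame in its sequence.
    """

    pixels: np.ndarray = field(repr=False)
    frame_index: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"frame pixels must be 2-D, got shape {px.shape}")
        if px.size == 0:
            raise FormatError("frame must contain at least one pixel")
        if not np.all(np.isfinite(px.astype(np.float64, copy=False))):
            raise FormatError("frame contains non-finite intensities")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _to_grayscale(arr: np.ndarray, origin: str) -> np.ndarray:
    """Reduce a decoded image to a single channel.

    3-channel input: take channel 0 (channels are identical for grayscale
    acquisitions; a warning is logged if they are not, which flags
    accidentally colored input).
    """
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] == 3:
        if not (np.array_equal(arr[..., 0], arr[..., 1]) and np.array_equal(arr[..., 0], arr[..., 2])):
            logger.warning("channels differ in %s; taking channel 0", origin)
        return arr[..., 0]
    raise FormatError(
        f"{origin}: expected 1 or 3 channels, got array of shape {arr.shape}"
    )


def read_frame(path: str | Path, frame_index: int = 1) -> GrayscaleFrame:
    """Read one image file as a :class:`GrayscaleFrame`.

    Raises
    ------
    FormatError
        If the file cannot be decoded or has an unsupported channel count.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder-specific failure modes vary
        raise FormatError(f"cannot decode image file {path}: {exc}") from exc
    return GrayscaleFrame(_to_grayscale(np.asarray(arr), str(path)), frame_index)


_NUM_RE = re.compile(r"(\d+)")


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically, so f2 sorts before f10."""
    return tuple(
        int(tok) if tok.isdigit() else tok for tok in _NUM_RE.split(name)
    )


def _check_dims(frames: Sequence[GrayscaleFrame], names: Sequence[str]) -> None:
    shape = frames[0].shape
    for frame, name in zip(frames, names):
        if frame.shape != shape:
            raise FormatError(
                f"frame {name} has shape {frame.shape}, expected {shape}"
            )


def read_sequence(
    source: str | Path, patterns: Iterable[str] = DEFAULT_PATTERNS
) -> list[GrayscaleFrame]:
    """Read an ordered frame sequence from a directory or a multi-page stack.

    Directory input is scanned with ``patterns`` and ordered by a natural
    numeric sort of file names. A single file is read as a multi-page stack.
    All frames must share dimensions.
    """
    source = Path(source)
    if source.is_dir():
        paths = sorted(
            {p for pat in patterns for p in source.glob(pat)},
            key=lambda p: _natural_key(p.name),
        )
        if not paths:
            raise VesicleTrackError(f"no frames found in directory {source}")
        frames = [read_frame(p, i + 1) for i, p in enumerate(paths)]
        _check_dims(frames, [p.name for p in paths])
        return frames

    if not source.exists():
        raise FileNotFoundError(f"no such file or directory: {source}")

    try:
        if source.suffix.lower() in (".tif", ".tiff"):
            pages = tifffile.imread(source)
        else:
            pages = iio.imread(source)
    except Exception as exc:
        raise FormatError(f"cannot decode stack {source}: {exc}") from exc

    pages = np.asarray(pages)
    if pages.ndim == 2:  # single-page stack
        pages = pages[None]
    elif pages.ndim == 3 and pages.shape[-1] == 3:  # one RGB page
        pages = pages[None]
    if pages.shape[0] == 0:
        raise VesicleTrackError(f"empty stack: {source}")
    frames = [
        GrayscaleFrame(_to_grayscale(page, f"{source}[page {i}]"), i + 1)
        for i, page in enumerate(pages)
    ]
    _check_dims(frames, [f"page {i + 1}" for i in range(len(frames))])
    return frames


def write_frames(frames: Sequence[GrayscaleFrame], directory: str | Path) -> list[Path]:
    """Write frames as numbered single-page TIFFs; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames))))
    paths = []
    for frame in frames:
        path = directory / f"frame_{frame.frame_index:0{width}d}.tif"
        tifffile.imwrite(path, np.asarray(frame.pixels))
        paths.append(path)
    return paths
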