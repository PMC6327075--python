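"""Per-frame vesicle detection.

Pipeline: Laplacian-of-Gaussian filtering -> global normalization to [0, 1]
-> thresholding to a binary mask -> connected-component labeling (iterative
flood fill) -> size filtering and centroid extraction.

The LOG kernel is built from the analytic formula with the sign flipped so
bright point-like features produce large positive responses, and it is
adjusted to sum exactly to zero (a constant image maps to an identically
zero response).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    ContractViolationError,
    DegenerateInputError,
    ParameterError,
)
from .image_io import GrayscaleFrame

logger = logging.getLogger(__name__)


def default_kernel_size(sigma: float) -> int:
    """Odd kernel side length covering +-3 sigma."""
    return 2 * math.ceil(3.0 * sigma) + 1


@dataclass(frozen=True)
class DetectionParams:
    """Detector configuration.

    ``response_lower_bound`` thresholds the normalized LOG response; it is
    calibrated per data set (typically by inspecting a threshold sweep).
    ``min_blob_size`` should be roughly the pixel count of the smallest real
    vesicle, so smaller noise blobs are discarded.
    """

    log_sigma: float = 2.0
    log_kernel_size: int | None = None  # None -> 2*ceil(3*sigma)+1
    response_lower_bound: float = 0.5
    min_blob_size: int = 4
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.log_sigma <= 0:
            raise ParameterError(f"log_sigma must be > 0, got {self.log_sigma}")
        size = self.kernel_size
        if size < 3 or size % 2 == 0:
            raise ParameterError(f"log_kernel_size must be odd and >= 3, got {size}")
        if not 0.0 <= self.response_lower_bound <= 1.0:
            raise ParameterError(
                f"response_lower_bound must be in [0, 1], got {self.response_lower_bound}"
            )
        if self.min_blob_size < 1:
            raise ParameterError(f"min_blob_size must be >= 1, got {self.min_blob_size}")
        if self.connectivity not in (4, 8):
            raise ParameterError(f"connectivity must be 4 or 8, got {self.connectivity}")

    @property
    def kernel_size(self) -> int:
        if self.log_kernel_size is not None:
            return self.log_kernel_size
        return default_kernel_size(self.log_sigma)


@dataclass(frozen=True)
class Blob:
    """A connected set of foreground pixels, presumed to be one vesicle."""

    pixels: np.ndarray = field(repr=False)  # (n, 2) int array of (row, col)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.pixels.mean(axis=0)
        return float(r), float(c)


@dataclass(frozen=True)
class DetectionSet:
    """Centroids and blob sizes of one frame's vesicles.

    Vesicle indices are 1-based and dense: vesicle ``k`` has centroid
    ``positions[k - 1]``.
    """

    frame_index: int
    positions: np.ndarray = field(repr=False)  # (K, 2) float, (row, col)
    sizes: np.ndarray = field(repr=False)  # (K,) int

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = np.empty((0, 2), dtype=float)
        sizes = np.asarray(self.sizes, dtype=int)
        if pos.shape[0] != sizes.shape[0]:
            raise ContractViolationError("positions and sizes length mismatch")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "sizes", sizes)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def position(self, vesicle_id: int) -> tuple[float, float]:
        """Centroid of the 1-based vesicle index."""
        if not 1 <= vesicle_id <= len(self):
            raise ContractViolationError(
                f"vesicle {vesicle_id} out of range 1..{len(self)} in frame {self.frame_index}"
            )
        r, c = self.positions[vesicle_id - 1]
        return float(r), float(c)


def log_kernel(sigma: float, size: int) -> np.ndarray:
    """Negated Laplacian-of-Gaussian kernel, adjusted to sum exactly to zero.

    Positive at the center, so bright blobs of matching scale give positive
    responses.
    """
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    r2 = x * x + y * y
    s2 = sigma * sigma
    kern = (1.0 - r2 / (2.0 * s2)) * np.exp(-r2 / (2.0 * s2)) / (math.pi * s2 * s2)
    kern -= kern.mean()  # truncation leaves a tiny residual sum
    return kern


def log_filter(frame: GrayscaleFrame, params: DetectionParams) -> np.ndarray:
    """Convolve the frame with the LOG kernel (edge-replicated borders)."""
    size = params.kernel_size
    if frame.height < size or frame.width < size:
        raise ParameterError(
            f"frame {frame.shape} smaller than LOG kernel ({size}x{size})"
        )
    kern = log_kernel(params.log_sigma, size)
    return ndimage.convolve(frame.pixels.astype(np.float64), kern, mode="nearest")


def normalize_response(response: np.ndarray) -> np.ndarray:
    """Affine-map the response range onto [0, 1], preserving pixel order."""
    response = np.asarray(response, dtype=np.float64)
    lo = response.min()
    hi = response.max()
    if hi == lo:
        raise DegenerateInputError("constant response: no vesicles detectable")
    return (response - lo) / (hi - lo)


def binarize(normalized: np.ndarray, lower_bound: float) -> np.ndarray:
    """Threshold with >= : pixel -> 1 iff value >= lower_bound."""
    return (np.asarray(normalized) >= lower_bound).astype(np.uint8)


_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def find_blobs(binary: np.ndarray, connectivity: int = 8) -> list[Blob]:
    """Label connected foreground components with an iterative flood fill.

    Blobs are returned in row-major discovery order of their first pixel.
    The explicit-stack fill matches the recursive formulation but cannot
    overflow on large blobs.
    """
    binary = np.asarray(binary)
    if not np.isin(binary, (0, 1)).all():
        raise ContractViolationError("find_blobs expects a {0,1} image")
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8

    h, w = binary.shape
    visited = np.zeros_like(binary, dtype=bool)
    blobs: list[Blob] = []
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] == 0 or visited[r0, c0]:
                continue
            stack = [(r0, c0)]
            visited[r0, c0] = True
            member: list[tuple[int, int]] = []
            while stack:
                r, c = stack.pop()
                member.append((r, c))
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not visited[rr, cc]:
                        visited[rr, cc] = True
                        stack.append((rr, cc))
            blobs.append(Blob(np.array(member, dtype=int)))
    return blobs


def filter_and_centroid(
    blobs: list[Blob], min_blob_size: int, frame_index: int = 1
) -> DetectionSet:
    """Drop undersized blobs and assign dense 1-based vesicle indices.

    Survivors keep discovery order (row-major first-pixel order), which makes
    vesicle indices deterministic; centroids are unweighted pixel means.
    """
    kept = [b for b in blobs if b.size >= min_blob_size]
    positions = np.array([b.centroid for b in kept], dtype=float).reshape(len(kept), 2)
    sizes = np.array([b.size for b in kept], dtype=int)
    return DetectionSet(frame_index, positions, sizes)


def detect_frame(frame: GrayscaleFrame, params: DetectionParams) -> DetectionSet:
    """Full single-frame detection pipeline. Deterministic for fixed inputs."""
    response = log_filter(frame, params)
    try:
        normalized = normalize_response(response)
    except DegenerateInputError:
        logger.info("frame %d: constant response, no detections", frame.frame_index)
        return DetectionSet(frame.frame_index, np.empty((0, 2)), np.empty(0, dtype=int))
    binary = binarize(normalized, params.response_lower_bound)
    blobs = find_blobs(binary, params.connectivity)
    return filter_and_centroid(blobs, params.min_blob_size, frame.frame_index)


def detect_sequence(
    frames: list[GrayscaleFrame], params: DetectionParams
) -> list[DetectionSet]:
    """Run :func:`detect_frame` over an ordered sequence."""
    out = []
    for frame in frames:
        det = detect_frame(frame, params)
        logger.debug("frame %d: %d detections", frame.frame_index, len(det))
        out.append(det)
    return out


def detections_to_frame_table(detections: list[DetectionSet]) -> pd.DataFrame:
    """Flatten per-frame detections to a table (frame, vesicle_id, row, col, size)."""
    rows = []
    for det in detections:
        for k in range(len(det)):
            rows.append(
                (det.frame_index, k + 1, det.positions[k, 0], det.positions[k, 1], int(det.sizes[k]))
            )
    return pd.DataFrame(rows, columns=["frame", "vesicle_id", "row", "col", "size"])


def detections_from_frame_table(
    table: pd.DataFrame, n_frames: int | None = None
) -> list[DetectionSet]:
    """Inverse of :func:`detections_to_frame_table`."""
    if n_frames is None:
        n_frames = int(table["frame"].max()) if len(table) else 0
    out = []
    for f in range(1, n_frames + 1):
        sub = table[table["frame"] == f].sort_values("vesicle_id")
        if len(sub) and not np.array_equal(sub["vesicle_id"].to_numpy(), np.arange(1, len(sub) + 1)):
            raise ContractViolationError(f"frame {f}: vesicle ids are not dense 1..K")
        out.append(
            DetectionSet(
                f,
                sub[["row", "col"]].to_numpy(dtype=float).reshape(len(sub), 2),
                sub["size"].to_numpy(dtype=int),
            )
        )
    return out
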