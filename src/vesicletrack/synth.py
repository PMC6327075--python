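"""Ground-truth movie generator.

Scripts point tracks with the movement repertoire seen in live movies —
local oscillation, steady drift, vanishing, appearing, merging, and
branching — and renders them as Gaussian spots on a dark noisy background.
Everything is driven by one seed, so the frames are byte-identical across
runs, which makes the generator the verification surface for detection,
linking, tracing and kinematics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .image_io import GrayscaleFrame

DEFAULT_SHAPE = (128, 128)


@dataclass
class Track:
    """One scripted point track; positions cover frames birth..death inclusive."""

    track_id: int
    birth: int
    death: int
    positions: np.ndarray = field(repr=False)  # (death - birth + 1, 2) float

    def position_at(self, frame: int) -> np.ndarray:
        if not self.birth <= frame <= self.death:
            raise ParameterError(f"track {self.track_id} not alive at frame {frame}")
        return self.positions[frame - self.birth]


@dataclass
class TrackScript:
    """A full scripted movie: tracks, events, and rendering parameters."""

    tracks: list[Track]
    n_frames: int
    shape: tuple[int, int] = DEFAULT_SHAPE
    spot_sigma: float = 2.0
    peak: float = 200.0
    background: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0
    events: dict = field(default_factory=dict)


def _grid_anchors(
    n: int, shape: tuple[int, int], pitch: float, margin: float, reserve: np.ndarray, rng
) -> np.ndarray:
    """Deterministically place n anchors on a jittered grid with the given pitch.

    ``reserve`` is extra room (row, col) kept free so drifting tracks stay in
    bounds for the whole movie.
    """
    lo = np.array([margin, margin])
    hi = np.array(shape, dtype=float) - margin - np.abs(reserve)
    start = np.where(reserve < 0, lo + np.abs(reserve), lo)
    usable = hi - start
    if np.any(usable <= 0):
        raise GenerationError(
            f"image {shape} too small for margin {margin} and travel {reserve}"
        )
    n_r = int(usable[0] // pitch) + 1
    n_c = int(usable[1] // pitch) + 1
    if n_r * n_c < n:
        raise GenerationError(
            f"cannot place {n} tracks with spacing {pitch:.1f} in image {shape}"
        )
    cells = rng.choice(n_r * n_c, size=n, replace=False)
    jitter = rng.uniform(-0.25 * min(pitch, 4.0), 0.25 * min(pitch, 4.0), size=(n, 2))
    anchors = np.empty((n, 2))
    for k, cell in enumerate(cells):
        anchors[k] = start + np.array([cell // n_c, cell % n_c]) * pitch + jitter[k]
    return anchors


def make_script(
    n_tracks: int,
    n_frames: int,
    motion: str = "oscillate",
    *,
    oscillate_radius: float = 2.0,
    drift_speed: float = 1.0,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    min_spacing: float = 16.0,
    merges: list[tuple[int, int, int]] = (),
    branches: list[tuple[int, int]] = (),
    vanish: list[tuple[int, int]] = (),
    appear: list[tuple[int, int]] = (),
    spot_sigma: float = 2.0,
    peak: float = 200.0,
    background: float = 10.0,
    noise_sigma: float = 0.0,
    merge_gap: float = 10.0,
    approach_speed: float = 6.0,
    branch_gap: float = 8.0,
    branch_speed: float = 3.0,
    seed: int = 0,
) -> TrackScript:
    """Build a reproducible movie script.

    ``motion`` is ``"oscillate"`` (positions jitter inside a disk of
    ``oscillate_radius`` around a fixed anchor) or ``"drift"`` (all tracks
    translate with a common velocity of magnitude ``drift_speed``, which
    keeps pairwise spacing constant). Events, all with 1-based track ids
    and frames:

    - ``merges``: (a, b, f) — track b approaches track a and coincides with
      it from frame f on; b is scripted as a separate spot only up to f-1.
    - ``branches``: (a, f) — a new track detaches from track a at frame f,
      starting ``branch_gap`` px away and receding at ``branch_speed`` px
      per frame.
    - ``vanish`` / ``appear``: (track, f) — clip a track's death / birth.

    The minimum pairwise spacing is honored except around scripted merge
    and branch frames, where convergence is the point.
    """
    if n_tracks < 1 or n_frames < 1:
        raise ParameterError("n_tracks and n_frames must be >= 1")
    if motion not in ("oscillate", "drift"):
        raise ParameterError(f"unknown motion model: {motion!r}")
    rng = np.random.default_rng(seed)

    margin = 3.0 * spot_sigma + 2.0
    if motion == "drift":
        theta = rng.uniform(0.0, 2.0 * math.pi)
        step = drift_speed * np.array([math.sin(theta), math.cos(theta)])
        reserve = step * (n_frames - 1)
        pitch = min_spacing
    else:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        step = np.zeros(2)
        reserve = np.zeros(2)
        pitch = min_spacing + 2.0 * oscillate_radius
    anchors = _grid_anchors(n_tracks, shape, pitch, margin, reserve, rng)

    births = {t: 1 for t in range(1, n_tracks + 1)}
    deaths = {t: n_frames for t in range(1, n_tracks + 1)}
    for tid, f in appear:
        births[tid] = max(births[tid], int(f))
    for tid, f in vanish:
        deaths[tid] = min(deaths[tid], int(f))
    for a, b, f in merges:
        deaths[b] = min(deaths[b], int(f) - 1)
    for tid in births:
        if births[tid] > deaths[tid]:
            raise GenerationError(f"track {tid}: birth {births[tid]} after death {deaths[tid]}")

    tracks: list[Track] = []
    for tid in range(1, n_tracks + 1):
        b, d = births[tid], deaths[tid]
        frames = np.arange(b, d + 1)
        if motion == "drift":
            pos = anchors[tid - 1] + np.outer(frames - 1, step)
        else:
            radius = oscillate_radius * np.sqrt(rng.uniform(0, 1, size=frames.size))
            angle = rng.uniform(0, 2 * math.pi, size=frames.size)
            pos = anchors[tid - 1] + np.stack(
                [radius * np.sin(angle), radius * np.cos(angle)], axis=1
            )
        tracks.append(Track(tid, b, d, pos))

    by_id = {t.track_id: t for t in tracks}

    if merges and approach_speed >= merge_gap:
        # keeps each approaching step smaller than the cross-track distance,
        # so the approaching track stays its own mutual nearest neighbor
        raise ParameterError("approach_speed must be smaller than merge_gap")
    for a, b, f in merges:
        ta, tb = by_id[a], by_id[b]
        if not ta.birth <= f <= ta.death:
            raise GenerationError(f"merge target track {a} not alive at frame {f}")
        target = ta.position_at(f)
        u = by_id[b].positions[0] - target
        norm = np.linalg.norm(u)
        u = u / norm if norm > 0 else np.array([0.0, 1.0])
        for t in range(tb.birth, tb.death + 1):
            dist = merge_gap + approach_speed * (f - 1 - t)
            tb.positions[t - tb.birth] = target + u * dist

    for a, f in branches:
        ta = by_id[a]
        if not ta.birth < f <= ta.death:
            raise GenerationError(f"branch parent track {a} has no frame {f - 1}->{f} step")
        origin = ta.position_at(f - 1)
        u = np.array([math.sin(theta + math.pi / 2), math.cos(theta + math.pi / 2)])
        frames = np.arange(f, n_frames + 1)
        pos = origin + np.outer(branch_gap + branch_speed * (frames - f), u)
        cid = len(tracks) + 1
        child = Track(cid, int(f), n_frames, pos)
        tracks.append(child)
        by_id[cid] = child

    hi = np.array(shape, dtype=float) - 1.5
    for t in tracks:
        np.clip(t.positions, 1.5, hi, out=t.positions)

    return TrackScript(
        tracks=tracks,
        n_frames=n_frames,
        shape=shape,
        spot_sigma=spot_sigma,
        peak=peak,
        background=background,
        noise_sigma=noise_sigma,
        seed=seed,
        events={"merges": list(merges), "branches": list(branches)},
    )


def script_truth(script: TrackScript) -> pd.DataFrame:
    """Ground-truth table (frame, track_id, row, col) of all scripted spots."""
    rows = []
    for frame in range(1, script.n_frames + 1):
        for t in script.tracks:
            if t.birth <= frame <= t.death:
                r, c = t.position_at(frame)
                rows.append((frame, t.track_id, float(r), float(c)))
    return pd.DataFrame(rows, columns=["frame", "track_id", "row", "col"])


def _add_spot(canvas: np.ndarray, center: np.ndarray, sigma: float, peak: float) -> None:
    """Accumulate one Gaussian spot into the canvas (local window, +-4 sigma)."""
    h, w = canvas.shape
    half = int(math.ceil(4.0 * sigma))
    r0, c0 = center
    rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    canvas[rlo:rhi, clo:chi] += peak * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma * sigma)
    )


def render_movie(script: TrackScript) -> tuple[list[GrayscaleFrame], pd.DataFrame]:
    """Render the script to 8-bit frames plus its ground-truth table.

    Each frame is background + the sum of Gaussian spots at the scripted
    positions + seeded additive Gaussian noise, clipped to [0, 254].
    """
    rng = np.random.default_rng(script.seed + 1)  # noise stream, independent of scripting
    frames = []
    for frame_no in range(1, script.n_frames + 1):
        canvas = np.full(script.shape, float(script.background))
        for t in script.tracks:
            if t.birth <= frame_no <= t.death:
                _add_spot(canvas, t.position_at(frame_no), script.spot_sigma, script.peak)
        if script.noise_sigma > 0:
            canvas += rng.normal(0.0, script.noise_sigma, size=script.shape)
        frames.append(
            GrayscaleFrame(np.clip(np.rint(canvas), 0, 254).astype(np.uint8), frame_no)
        )
    return frames, script_truth(script)
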