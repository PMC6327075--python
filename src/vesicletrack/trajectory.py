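"""The compound trajectory store (TRJ) and the tracing loop.

Each trajectory is an ordered list of segment rows ``[iframe, pid1, pid2]``
where ``iframe`` is the current image index, ``pid1`` the vesicle index in
the previous image and ``pid2`` the vesicle index in the current image.
Vesicle indices are reassigned per frame by the detector, so trajectories
must chain indices frame by frame; positions are resolved later against the
detection data.

Tracing per frame: link the previous and current detections, resolve merges
(trajectories that have converged onto an identical tail: only the longest
stays alive), then insert the new segments — continuations extend live
trajectories, branches spawn new ones, begin segments seed new ones, and
end segments close their trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import DetectionSet
from .errors import (
    ContractViolationError,
    IntegrityError,
    ParameterError,
    SequencingError,
)
from .linking import LinkSet, multi_cutoff_link

logger = logging.getLogger(__name__)

SegmentRow = tuple[int, int, int]  # (iframe, pid1, pid2)


@dataclass
class TRJ:
    """Compound trajectory store.

    Attributes
    ----------
    counter: number of trajectories stored.
    nframe: number of images used for tracing.
    dat: per-trajectory ordered segment rows.
    alive: per-trajectory live flag (False once ended or killed by merge).
    capacity: allocation hint; informational in Python, kept for trimming.
    """

    counter: int = 0
    nframe: int = 1
    dat: list[list[SegmentRow]] = field(default_factory=list)
    alive: list[bool] = field(default_factory=list)
    capacity: int = 0

    @property
    def pos(self) -> list[int]:
        """Access pointers: trajectory t's data lives at ``dat[pos[t]]``."""
        return list(range(self.counter))

    def tail(self, tid: int) -> SegmentRow:
        """Last segment row of 0-based trajectory ``tid``."""
        return self.dat[tid][-1]

    def length(self, tid: int) -> int:
        return len(self.dat[tid])


def trj_init(expected: int, nframe: int) -> TRJ:
    """Create an empty store sized for ``expected`` trajectories."""
    if expected < 1 or nframe < 1:
        raise ParameterError(
            f"expected and nframe must be >= 1, got {expected}, {nframe}"
        )
    return TRJ(counter=0, nframe=nframe, capacity=expected)


def trj_new(trj: TRJ, head: SegmentRow) -> int:
    """Add a new live trajectory holding exactly ``head``; returns its id."""
    iframe, pid1, pid2 = head
    if pid2 <= 0:
        raise ContractViolationError(f"new trajectory head must have pid2 > 0, got {head}")
    trj.dat.append([(int(iframe), int(pid1), int(pid2))])
    trj.alive.append(True)
    trj.counter += 1
    return trj.counter - 1


def trj_tails(trj: TRJ) -> list[tuple[int, int, int]]:
    """Tails of all live trajectories, after merge resolution.

    Live trajectories sharing an identical tail (same frame, same vesicle)
    have converged: only the longest stays alive, ties going to the lowest
    trajectory id; the rest are killed (merged). Returns
    ``(trajectory_id, tail_vesicle, tail_frame)`` per surviving live
    trajectory, in trajectory-id order.
    """
    groups: dict[tuple[int, int], list[int]] = {}
    for tid in range(trj.counter):
        if not trj.alive[tid]:
            continue
        iframe, _, pid2 = trj.tail(tid)
        groups.setdefault((iframe, pid2), []).append(tid)

    out = []
    for (iframe, pid2), tids in groups.items():
        if len(tids) > 1:
            survivor = max(tids, key=lambda t: (trj.length(t), -t))
            for tid in tids:
                if tid != survivor:
                    trj.alive[tid] = False
            tids = [survivor]
        out.append((tids[0], pid2, iframe))
    out.sort()
    return out


def trj_insert(trj: TRJ, links: LinkSet) -> None:
    """Append one frame pair's segments to the store.

    Continuation segments (pid1 > 0, pid2 > 0) extend the live trajectory
    whose tail vesicle equals pid1; when one tail has several outgoing
    segments (a branch), the parent continues along the smallest-distance
    one and each remaining segment spawns a new trajectory headed by the
    branch segment itself. Segments with pid1 = 0 seed new trajectories;
    segments with pid2 = 0 close theirs.
    """
    live_tails: dict[int, int] = {}
    tail_frame = None
    for tid in range(trj.counter):
        if trj.alive[tid]:
            iframe, _, pid2 = trj.tail(tid)
            live_tails[pid2] = tid
            tail_frame = iframe if tail_frame is None else max(tail_frame, iframe)
    if tail_frame is not None and links.iframe != tail_frame + 1:
        raise SequencingError(
            f"links are for frame {links.iframe}, expected frame {tail_frame + 1}"
        )

    outgoing: dict[int, list] = {}
    for seg in links.segments:
        if seg.pid1 > 0 and seg.pid2 > 0:
            outgoing.setdefault(seg.pid1, []).append(seg)

    for pid1 in sorted(outgoing):
        segs = sorted(outgoing[pid1], key=lambda s: (s.distance, s.pid2))
        tid = live_tails.get(pid1)
        row = (links.iframe, pid1, segs[0].pid2)
        if tid is None:
            # no live trajectory owns this tail: start one from the segment
            trj_new(trj, row)
        else:
            trj.dat[tid].append(row)
        for seg in segs[1:]:  # extra branches spawn new trajectories
            trj_new(trj, (links.iframe, pid1, seg.pid2))

    for seg in links.segments:
        if seg.category == "end":
            tid = live_tails.get(seg.pid1)
            if tid is not None:
                trj.alive[tid] = False
        elif seg.category == "begin":
            trj_new(trj, (links.iframe, 0, seg.pid2))


def trj_coords(
    trj: TRJ, trajectory_id: int, all_detections: list[DetectionSet]
) -> list[tuple[int, float, float]]:
    """Resolve a trajectory's (frame, row, col) coordinates from detections.

    ``trajectory_id`` is 0-based.
    """
    if not 0 <= trajectory_id < trj.counter:
        raise IntegrityError(f"no trajectory {trajectory_id} (counter={trj.counter})")
    coords = []
    for iframe, _, pid2 in trj.dat[trajectory_id]:
        if not 1 <= iframe <= len(all_detections):
            raise IntegrityError(f"trajectory {trajectory_id}: no detections for frame {iframe}")
        det = all_detections[iframe - 1]
        if not 1 <= pid2 <= len(det):
            raise IntegrityError(
                f"trajectory {trajectory_id}: vesicle {pid2} missing in frame {iframe}"
            )
        r, c = det.position(pid2)
        coords.append((iframe, r, c))
    return coords


def trj_trim(trj: TRJ) -> TRJ:
    """Shrink capacity to the stored count; contents are untouched. Idempotent."""
    trj.capacity = trj.counter
    return trj


def trace_all(
    all_detections: list[DetectionSet],
    cutoffs: list[float],
    expected: int | None = None,
) -> TRJ:
    """Trace trajectories over a full detection sequence.

    Frame 1 seeds one trajectory per detection (head rows ``[1, 0, k]``);
    each later frame is linked against the previous frame with the
    multi-cutoff search, merges are resolved, and the segments inserted.
    """
    if not all_detections:
        raise ParameterError("need at least one frame of detections")
    nframe = len(all_detections)
    if expected is None:
        # branches inflate the count beyond the vesicle count
        expected = max(4 * max((len(d) for d in all_detections), default=1), 4)
    trj = trj_init(expected, nframe)
    for k in range(1, len(all_detections[0]) + 1):
        trj_new(trj, (1, 0, k))
    for f in range(2, nframe + 1):
        prev, curr = all_detections[f - 2], all_detections[f - 1]
        if len(prev) == 0 or len(curr) == 0:
            from .linking import LinkSet as _LS, Segment as _Seg

            segs = [_Seg(p, 0, "end") for p in range(1, len(prev) + 1)]
            segs += [_Seg(0, c, "begin") for c in range(1, len(curr) + 1)]
            links = _LS(f, tuple(segs))
        else:
            links = multi_cutoff_link(prev, curr, cutoffs, iframe=f)
        trj_tails(trj)  # resolve merges from the previous insertion
        trj_insert(trj, links)
    trj_tails(trj)  # resolve merges created at the final frame
    logger.info("traced %d trajectories over %d frames", trj.counter, nframe)
    return trj_trim(trj)


def trj_to_table(trj: TRJ) -> pd.DataFrame:
    """Serialize to rows (trajectory_id, iframe, pid1, pid2, alive_flag)."""
    rows = []
    for tid in range(trj.counter):
        for iframe, pid1, pid2 in trj.dat[tid]:
            rows.append((tid + 1, iframe, pid1, pid2, int(trj.alive[tid])))
    return pd.DataFrame(rows, columns=["trajectory_id", "iframe", "pid1", "pid2", "alive_flag"])


def trj_from_table(table: pd.DataFrame, nframe: int | None = None) -> TRJ:
    """Rebuild a TRJ from its serialized table."""
    if nframe is None:
        nframe = int(table["iframe"].max()) if len(table) else 1
    trj = trj_init(max(int(table["trajectory_id"].max()), 1) if len(table) else 1, nframe)
    for tid, group in table.groupby("trajectory_id", sort=True):
        group = group.sort_values("iframe")
        trj.dat.append(
            [(int(r.iframe), int(r.pid1), int(r.pid2)) for r in group.itertuples()]
        )
        trj.alive.append(bool(group["alive_flag"].iloc[0]))
        trj.counter += 1
    return trj
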