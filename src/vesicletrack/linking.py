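"""Frame-to-frame vesicle connectivity.

All pairwise distances between detections in two consecutive frames are
stored in a distance matrix; row minima find, for each previous-frame
vesicle, its nearest current-frame neighbor, and column minima the reverse.
A minimum counts only if it is strictly below the cutoff distance. The
resulting segments fall into five categories:

- ``regular``: unique mutual nearest neighbors;
- ``merge``: one current vesicle is the nearest valid neighbor of >= 2
  previous vesicles;
- ``branch``: one previous vesicle is the nearest valid neighbor of >= 2
  current vesicles;
- ``end``: a previous vesicle with no valid neighbor (pid2 = 0);
- ``begin``: a current vesicle with no valid neighbor (pid1 = 0).

Because vesicle speeds vary widely, a single cutoff is a poor compromise: a
small one drops fast vesicles, a large one mixes up slow neighbors. The
multi-cutoff search runs the classification repeatedly with ascending
cutoffs, freezing matches made at smaller cutoffs and removing them from
later levels, so slow vesicles are resolved first at high precision.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .detection import DetectionSet
from .errors import ParameterError

CATEGORIES = ("regular", "merge", "branch", "end", "begin")


@dataclass(frozen=True)
class DistanceMatrix:
    """P x C Euclidean distances; rows = previous frame, columns = current.

    ``row_min_idx[i]`` / ``col_min_idx[j]`` are 0-based argminima with ties
    broken toward the smallest index.
    """

    values: np.ndarray = field(repr=False)
    row_min_idx: np.ndarray = field(repr=False)
    col_min_idx: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class Segment:
    """One connectivity segment; pid1/pid2 are 1-based vesicle indices, 0 = none."""

    pid1: int
    pid2: int
    category: str
    distance: float = float("nan")
    cutoff_level: int = 0


@dataclass(frozen=True)
class LinkSet:
    """All segments connecting one frame pair; ``iframe`` is the current frame."""

    iframe: int
    segments: tuple[Segment, ...]

    def by_category(self, category: str) -> list[Segment]:
        return [s for s in self.segments if s.category == category]


def build_distance_matrix(prev: DetectionSet, curr: DetectionSet) -> DistanceMatrix:
    """All pairwise distances plus row/column argminima."""
    values = cdist(prev.positions, curr.positions)
    return DistanceMatrix(values, values.argmin(axis=1), values.argmin(axis=0))


def _linked_pairs(D: DistanceMatrix, cutoff: float) -> set[tuple[int, int]]:
    """0-based (prev, curr) pairs linked at this cutoff.

    Merge clusters come from row minima that coincide on one column, branch
    clusters from column minima coinciding on one row, and regular links
    from unique mutual minima. The construction is symmetric under
    transposition, which maps merges onto branches.
    """
    P, C = D.values.shape
    rm, cm = D.row_min_idx, D.col_min_idx
    rm_valid = D.values[np.arange(P), rm] < cutoff
    cm_valid = D.values[cm, np.arange(C)] < cutoff

    into_col: dict[int, list[int]] = defaultdict(list)
    for i in range(P):
        if rm_valid[i]:
            into_col[int(rm[i])].append(i)
    from_row: dict[int, list[int]] = defaultdict(list)
    for j in range(C):
        if cm_valid[j]:
            from_row[int(cm[j])].append(j)

    merge_cols = {j for j, rows in into_col.items() if len(rows) >= 2}
    branch_rows = {i for i, cols in from_row.items() if len(cols) >= 2}

    pairs: set[tuple[int, int]] = set()
    for j in merge_cols:
        pairs.update((i, j) for i in into_col[j])
    for i in branch_rows:
        pairs.update((i, j) for j in from_row[i])
    for i in range(P):  # unique mutual nearest neighbors
        if not rm_valid[i]:
            continue
        j = int(rm[i])
        if j in merge_cols or i in branch_rows:
            continue
        if cm_valid[j] and int(cm[j]) == i:
            pairs.add((i, j))
    return pairs


def _categorize(
    pairs: set[tuple[int, int]],
    D: DistanceMatrix,
    level: int,
    prev_ids: np.ndarray,
    curr_ids: np.ndarray,
) -> list[Segment]:
    """Label linked pairs by pid-sharing; merge sharing wins over branch."""
    n_by_col: dict[int, int] = defaultdict(int)
    n_by_row: dict[int, int] = defaultdict(int)
    for i, j in pairs:
        n_by_row[i] += 1
        n_by_col[j] += 1
    segments = []
    for i, j in pairs:
        if n_by_col[j] >= 2:
            cat = "merge"
        elif n_by_row[i] >= 2:
            cat = "branch"
        else:
            cat = "regular"
        segments.append(
            Segment(int(prev_ids[i]), int(curr_ids[j]), cat, float(D.values[i, j]), level)
        )
    return segments


def classify_links(D: DistanceMatrix, cutoff: float, iframe: int = 0) -> LinkSet:
    """Classify one frame pair's connectivity at a single cutoff distance."""
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be > 0, got {cutoff}")
    P, C = D.values.shape
    pairs = _linked_pairs(D, cutoff)
    segments = _categorize(pairs, D, 0, np.arange(1, P + 1), np.arange(1, C + 1))
    linked_prev = {i for i, _ in pairs}
    linked_curr = {j for _, j in pairs}
    segments += [Segment(i + 1, 0, "end") for i in range(P) if i not in linked_prev]
    segments += [Segment(0, j + 1, "begin") for j in range(C) if j not in linked_curr]
    segments.sort(key=lambda s: (s.pid1, s.pid2))
    return LinkSet(iframe, tuple(segments))


def multi_cutoff_link(
    prev: DetectionSet,
    curr: DetectionSet,
    cutoffs: list[float],
    iframe: int = 0,
) -> LinkSet:
    """Link one frame pair with ascending cutoffs, small-first precedence.

    Matches made at a smaller cutoff are frozen: their vesicles are removed
    before the next level runs. Vesicles still unmatched after the last
    level become end/begin segments.
    """
    cutoffs = list(cutoffs)
    if not cutoffs or any(c <= 0 for c in cutoffs):
        raise ParameterError("cutoffs must be a non-empty list of positive distances")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ParameterError(f"cutoffs must be strictly ascending, got {cutoffs}")

    active_prev = np.arange(1, len(prev) + 1)
    active_curr = np.arange(1, len(curr) + 1)
    segments: list[Segment] = []
    for level, cutoff in enumerate(cutoffs):
        if len(active_prev) == 0 or len(active_curr) == 0:
            break
        sub = cdist(prev.positions[active_prev - 1], curr.positions[active_curr - 1])
        D = DistanceMatrix(sub, sub.argmin(axis=1), sub.argmin(axis=0))
        pairs = _linked_pairs(D, cutoff)
        segments += _categorize(pairs, D, level, active_prev, active_curr)
        used_prev = {i for i, _ in pairs}
        used_curr = {j for _, j in pairs}
        active_prev = np.array([p for k, p in enumerate(active_prev) if k not in used_prev])
        active_curr = np.array([c for k, c in enumerate(active_curr) if k not in used_curr])
    segments += [Segment(int(p), 0, "end") for p in active_prev]
    segments += [Segment(0, int(c), "begin") for c in active_curr]
    segments.sort(key=lambda s: (s.pid1, s.pid2))
    return LinkSet(iframe, tuple(segments))


def links_to_table(links: LinkSet) -> pd.DataFrame:
    """Debug export: one row per segment."""
    return pd.DataFrame(
        [
            (links.iframe, s.pid1, s.pid2, s.distance, s.category, s.cutoff_level)
            for s in links.segments
        ],
        columns=["iframe", "pid1", "pid2", "distance", "category", "cutoff_level"],
    )
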