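"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written with plain loops and no shared code with the
package: a per-pixel BFS for connected-component labeling, and an
exhaustive-scan nearest-neighbor classifier for frame-pair linking.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_label(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components by per-pixel breadth-first search.

    Returns an int array: 0 = background, components numbered 1.. in
    row-major order of their first-encountered pixel.
    """
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    h, w = binary.shape
    labels = np.zeros((h, w), dtype=int)
    next_label = 0
    for r in range(h):
        for c in range(w):
            if binary[r, c] == 0 or labels[r, c] != 0:
                continue
            next_label += 1
            queue = deque([(r, c)])
            labels[r, c] = next_label
            while queue:
                cr, cc = queue.popleft()
                for dr, dc in offsets:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and labels[nr, nc] == 0:
                        labels[nr, nc] = next_label
                        queue.append((nr, nc))
    return labels


def brute_classify(prev_pts, curr_pts, cutoff):
    """Exhaustive nearest-neighbor link classification for one frame pair.

    Returns (linked, ends, begins) where linked is a dict
    {(i, j): category} over 0-based indices.
    """
    P, C = len(prev_pts), len(curr_pts)

    def dist(i, j):
        return math.hypot(
            prev_pts[i][0] - curr_pts[j][0], prev_pts[i][1] - curr_pts[j][1]
        )

    nearest_curr = [min(range(C), key=lambda j: (dist(i, j), j)) for i in range(P)]
    nearest_prev = [min(range(P), key=lambda i: (dist(i, j), i)) for j in range(C)]

    def rows_into(j):
        return [i for i in range(P) if nearest_curr[i] == j and dist(i, j) < cutoff]

    def cols_from(i):
        return [j for j in range(C) if nearest_prev[j] == i and dist(i, j) < cutoff]

    linked: set[tuple[int, int]] = set()
    for j in range(C):
        rows = rows_into(j)
        if len(rows) >= 2:
            linked.update((i, j) for i in rows)
    for i in range(P):
        cols = cols_from(i)
        if len(cols) >= 2:
            linked.update((i, j) for j in cols)
    for i in range(P):
        j = nearest_curr[i]
        if (
            dist(i, j) < cutoff
            and nearest_prev[j] == i
            and len(rows_into(j)) == 1
            and len(cols_from(i)) == 1
        ):
            linked.add((i, j))

    categories = {}
    for i, j in linked:
        if sum(1 for ii, jj in linked if jj == j) >= 2:
            categories[(i, j)] = "merge"
        elif sum(1 for ii, jj in linked if ii == i) >= 2:
            categories[(i, j)] = "branch"
        else:
            categories[(i, j)] = "regular"

    ends = [i for i in range(P) if not any(ii == i for ii, _ in linked)]
    begins = [j for j in range(C) if not any(jj == j for _, jj in linked)]
    return categories, ends, begins
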