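import numpy as np
import pytest

from vesicletrack.detection import DetectionParams, detect_sequence
from vesicletrack.errors import (
    ContractViolationError,
    IntegrityError,
    ParameterError,
    SequencingError,
)
from vesicletrack.linking import LinkSet, Segment
from vesicletrack.synth import make_script, render_movie
from vesicletrack.trajectory import (
    trace_all,
    trj_coords,
    trj_from_table,
    trj_init,
    trj_insert,
    trj_new,
    trj_tails,
    trj_to_table,
    trj_trim,
)

from .conftest import detection_set


class TestInit:
    def test_empty_store(self):
        trj = trj_init(100, 10)
        assert trj.counter == 0
        assert trj.nframe == 10
        assert trj.capacity == 100

    def test_single_frame_store(self):
        assert trj_init(1, 1).nframe == 1

    @pytest.mark.parametrize("expected,nframe", [(0, 5), (5, 0), (-1, 1)])
    def test_bad_arguments(self, expected, nframe):
        with pytest.raises(ParameterError):
            trj_init(expected, nframe)

    def test_grows_past_capacity_hint(self):
        trj = trj_init(3, 10)
        for k in range(1, 5):
            trj_new(trj, (1, 0, k))
        assert trj.counter == 4


class TestNew:
    def test_single_head(self):
        trj = trj_init(4, 4)
        trj_new(trj, (1, 0, 3))
        assert trj.counter == 1
        assert trj.dat[0] == [(1, 0, 3)]
        assert trj.alive == [True]

    def test_two_heads_independent(self):
        trj = trj_init(4, 4)
        trj_new(trj, (1, 0, 1))
        trj_new(trj, (1, 0, 2))
        assert trj.counter == 2
        assert trj.dat[0] != trj.dat[1]

    def test_zero_pid2_rejected(self):
        trj = trj_init(4, 4)
        with pytest.raises(ContractViolationError):
            trj_new(trj, (1, 1, 0))


class TestTails:
    def test_distinct_tails_all_returned(self):
        trj = trj_init(4, 4)
        trj_new(trj, (1, 0, 1))
        trj_new(trj, (1, 0, 2))
        assert trj_tails(trj) == [(0, 1, 1), (1, 2, 1)]

    def test_merge_longest_survives(self):
        trj = trj_init(4, 8)
        a = trj_new(trj, (2, 0, 1))
        trj.dat[a] += [(3, 1, 2), (4, 2, 7)]
        b = trj_new(trj, (4, 0, 7))
        tails = trj_tails(trj)
        assert tails == [(a, 7, 4)]
        assert trj.alive[b] is False
        assert trj.alive[a] is True

    def test_length_tie_lowest_id_survives(self):
        trj = trj_init(4, 8)
        a = trj_new(trj, (3, 0, 5))
        trj.dat[a].append((4, 5, 7))
        b = trj_new(trj, (3, 0, 6))
        trj.dat[b].append((4, 6, 7))
        tails = trj_tails(trj)
        assert tails == [(a, 7, 4)]
        assert trj.alive == [True, False]

    def test_tails_unique_after_resolution(self):
        trj = trj_init(8, 4)
        for k in (1, 1, 2, 2, 2):
            trj_new(trj, (2, 0, k))
        tails = trj_tails(trj)
        seen = [(frame, pid) for _, pid, frame in tails]
        assert len(seen) == len(set(seen)) == 2


class TestInsert:
    def test_regular_extension(self):
        trj = trj_init(4, 8)
        tid = trj_new(trj, (3, 0, 2))
        links = LinkSet(4, (Segment(2, 5, "regular", 1.0),))
        trj_insert(trj, links)
        assert trj.dat[tid] == [(3, 0, 2), (4, 2, 5)]

    def test_begin_segment_creates_trajectory(self):
        trj = trj_init(4, 8)
        trj_new(trj, (3, 0, 2))
        links = LinkSet(4, (Segment(2, 5, "regular", 1.0), Segment(0, 9, "begin")))
        trj_insert(trj, links)
        assert trj.counter == 2
        assert trj.dat[1] == [(4, 0, 9)]

    def test_end_segment_kills_trajectory(self):
        trj = trj_init(4, 8)
        tid = trj_new(trj, (3, 0, 2))
        trj_insert(trj, LinkSet(4, (Segment(2, 0, "end"),)))
        assert trj.alive[tid] is False
        assert trj.dat[tid] == [(3, 0, 2)]

    def test_branch_continuation_and_spawn(self):
        trj = trj_init(4, 8)
        parent = trj_new(trj, (3, 0, 1))
        links = LinkSet(
            4, (Segment(1, 3, "branch", 7.0), Segment(1, 2, "branch", 1.5))
        )
        trj_insert(trj, links)
        # parent continues along the nearest branch; the other spawns
        assert trj.dat[parent] == [(3, 0, 1), (4, 1, 2)]
        assert trj.counter == 2
        assert trj.dat[1] == [(4, 1, 3)]
        assert trj.alive == [True, True]

    def test_frame_discontinuity_rejected(self):
        trj = trj_init(4, 8)
        trj_new(trj, (3, 0, 2))
        with pytest.raises(SequencingError):
            trj_insert(trj, LinkSet(6, (Segment(2, 5, "regular", 1.0),)))


class TestCoords:
    def test_single_row_lookup(self):
        trj = trj_init(4, 4)
        trj_new(trj, (1, 0, 2))
        dets = [detection_set(1, [(5.0, 6.0), (10.0, 20.0)])]
        assert trj_coords(trj, 0, dets) == [(1, 10.0, 20.0)]

    def test_length_preserved(self):
        trj = trj_init(4, 5)
        tid = trj_new(trj, (1, 0, 1))
        trj.dat[tid] += [(f, 1, 1) for f in range(2, 6)]
        dets = [detection_set(f, [(float(f), 0.0)]) for f in range(1, 6)]
        coords = trj_coords(trj, tid, dets)
        assert [c[0] for c in coords] == [1, 2, 3, 4, 5]
        assert [c[1] for c in coords] == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_dangling_index(self):
        trj = trj_init(4, 4)
        trj_new(trj, (1, 0, 99))
        dets = [detection_set(1, [(0.0, 0.0)])]
        with pytest.raises(IntegrityError, match="99"):
            trj_coords(trj, 0, dets)


class TestTrim:
    def test_capacity_reduced_content_kept(self):
        trj = trj_init(1000, 4)
        for k in range(1, 8):
            trj_new(trj, (1, 0, k))
        before = [list(rows) for rows in trj.dat]
        trj_trim(trj)
        assert trj.capacity == 7
        assert [list(rows) for rows in trj.dat] == before

    def test_idempotent_and_empty(self):
        trj = trj_init(10, 2)
        trj_trim(trj)
        trj_trim(trj)
        assert trj.capacity == 0 and trj.counter == 0


class TestTraceAll:
    def test_single_frame_seeds(self):
        dets = [detection_set(1, [(0, 0), (10, 10), (20, 20)])]
        trj = trace_all(dets, [5.0])
        assert trj.counter == 3
        assert all(rows == [(1, 0, k + 1)] for k, rows in enumerate(trj.dat))

    def test_two_drifting_points(self):
        dets = [
            detection_set(f, [(1.0 * f, 0.0), (50.0 + 1.0 * f, 0.0)])
            for f in range(1, 11)
        ]
        trj = trace_all(dets, [5.0])
        assert trj.counter == 2
        assert all(len(rows) == 10 for rows in trj.dat)
        assert trj.alive == [True, True]

    def test_frame_continuity_invariant(self, merge_branch_movie):
        _, frames, _ = merge_branch_movie
        dets = detect_sequence(frames, DetectionParams())
        trj = trace_all(dets, [20.0])
        for rows in trj.dat:
            frames_seq = [r[0] for r in rows]
            assert frames_seq == list(range(frames_seq[0], frames_seq[0] + len(rows)))

    def test_conservation_no_detection_orphaned(self, merge_branch_movie):
        _, frames, _ = merge_branch_movie
        dets = detect_sequence(frames, DetectionParams())
        trj = trace_all(dets, [20.0])
        for det in dets:
            for k in range(1, len(det) + 1):
                assert any(
                    (det.frame_index, k) == (r[0], r[2])
                    for rows in trj.dat
                    for r in rows
                )

    def test_empty_middle_frame(self):
        dets = [
            detection_set(1, [(5.0, 5.0)]),
            detection_set(2, np.empty((0, 2))),
            detection_set(3, [(5.0, 5.0)]),
        ]
        trj = trace_all(dets, [5.0])
        assert trj.counter == 2  # the track dies and a new one begins

    def test_merge_branch_duality_on_reversed_movie(self):
        # two merges + one branch forward; reversing frames swaps the counts
        script = make_script(
            4, 8, "oscillate", oscillate_radius=1.0, shape=(260, 260),
            min_spacing=50, merges=[(1, 2, 3), (3, 4, 5)], branches=[(1, 6)], seed=9,
        )
        frames, _ = render_movie(script)
        dets = detect_sequence(frames, DetectionParams())

        def census(detections):
            trj = trace_all(detections, [20.0])
            killed = sum(
                1 for tid in range(trj.counter)
                if not trj.alive[tid] and trj.dat[tid][-1][0] < trj.nframe
            )
            spawned = sum(1 for rows in trj.dat if rows[0][1] != 0)
            return killed, spawned

        rev = [detection_set(i + 1, d.positions) for i, d in enumerate(reversed(dets))]
        fwd_killed, fwd_spawned = census(dets)
        rev_killed, rev_spawned = census(rev)
        assert (fwd_killed, fwd_spawned) == (2, 1)
        assert (rev_killed, rev_spawned) == (fwd_spawned, fwd_killed)

    def test_ground_truth_recovery(self, drift_movie):
        _, frames, truth = drift_movie
        dets = detect_sequence(frames, DetectionParams())
        trj = trace_all(dets, [5.0, 10.0, 20.0])
        assert trj.counter == 10
        assert all(len(rows) == 20 for rows in trj.dat)
        assert all(trj.alive)


class TestSerialization:
    def test_round_trip(self, merge_branch_movie):
        _, frames, _ = merge_branch_movie
        dets = detect_sequence(frames, DetectionParams())
        trj = trace_all(dets, [20.0])
        table = trj_to_table(trj)
        back = trj_from_table(table, nframe=trj.nframe)
        assert back.counter == trj.counter
        assert back.dat == trj.dat
        assert back.alive == trj.alive
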