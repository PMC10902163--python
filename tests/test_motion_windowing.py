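"""Flexible low-motion windowing vs fixed-index partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_candidate_count
from sampenmap import (
    BoldMatrix,
    InsufficientWindowsError,
    MotionTrace,
    WindowConfig,
    concatenate_windows,
    find_candidate_windows,
    fixed_index_windows,
    select_best_windows,
)

CFG = WindowConfig(fd_threshold=0.3, window_length=20, n_windows=20, initial_exclusion=0)


def trace_with_spikes(n=60, spikes=(), baseline=0.1, spike_fd=0.9):
    fd = np.full(n, baseline)
    for s in spikes:
        fd[s] = spike_fd
    return MotionTrace((fd,))


class TestFindCandidateWindows:
    def test_sixty_volumes_with_spikes_at_10_and_55_yield_two_windows(self):
        # high motion at volumes 10 and 55 (1-based): the flexible search
        # re-anchors after the first spike and finds two 20-volume windows
        trace = trace_with_spikes(spikes=(9, 54))
        ws = find_candidate_windows(trace, CFG)
        assert len(ws) == 2
        # windows anchored at the first usable volume after the spike
        assert [(w.start, w.end) for w in ws] == [(10, 30), (30, 50)]

    def test_unobstructed_packing(self):
        ws = find_candidate_windows(trace_with_spikes(), CFG)
        assert [(w.start, w.end) for w in ws] == [(0, 20), (20, 40), (40, 60)]

    def test_fully_contaminated_trace_yields_nothing(self):
        trace = MotionTrace((np.full(60, 0.5),))
        assert len(find_candidate_windows(trace, CFG)) == 0

    def test_threshold_is_strict(self):
        # FD exactly at the threshold is unusable
        trace = MotionTrace((np.full(40, 0.3),))
        assert len(find_candidate_windows(trace, CFG)) == 0

    def test_initial_exclusion_shifts_anchoring(self):
        cfg = WindowConfig(window_length=20, initial_exclusion=10, n_windows=20)
        ws = find_candidate_windows(trace_with_spikes(n=60), cfg)
        assert [(w.start, w.end) for w in ws] == [(10, 30), (30, 50)]

    def test_windows_never_span_runs(self):
        trace = MotionTrace((np.full(30, 0.1), np.full(30, 0.1)))
        ws = find_candidate_windows(trace, CFG)
        assert [(w.run, w.start, w.end) for w in ws] == [(0, 0, 20), (1, 30, 50)]

    def test_exclude_mask_blocks_volumes(self):
        exclude = np.zeros(60, bool)
        exclude[25] = True
        ws = find_candidate_windows(trace_with_spikes(), CFG, exclude=exclude)
        assert [(w.start, w.end) for w in ws] == [(0, 20), (26, 46)]


class TestSelectBestWindows:
    def test_discards_highest_mean_fd(self, rng):
        fd = rng.uniform(0.0, 0.29, size=500)
        trace = MotionTrace((fd,))
        cands = find_candidate_windows(trace, CFG)
        assert len(cands) == 25
        cfg = WindowConfig(window_length=20, n_windows=20, initial_exclusion=0)
        best = select_best_windows(cands, cfg)
        assert len(best) == 20
        kept = set(best.windows)
        dropped_fd = [
            fd_val for w, fd_val in zip(cands.windows, cands.mean_fd) if w not in kept
        ]
        assert len(dropped_fd) == 5
        assert max(best.mean_fd) <= min(dropped_fd)
        assert list(best.windows) == sorted(best.windows, key=lambda w: w.start)

    def test_identity_when_enough_requested(self):
        trace = trace_with_spikes()
        cands = find_candidate_windows(trace, CFG)
        assert select_best_windows(cands, CFG) is cands

    def test_tie_at_cut_keeps_earlier_window(self):
        # four identical-FD windows, request three: the last one is dropped
        trace = MotionTrace((np.full(80, 0.1),))
        cfg = WindowConfig(window_length=20, n_windows=3, initial_exclusion=0)
        cands = find_candidate_windows(trace, cfg)
        best = select_best_windows(cands, cfg)
        assert [(w.start, w.end) for w in best] == [(0, 20), (20, 40), (40, 60)]


class TestFixedIndexWindows:
    def test_spikes_leave_only_middle_block(self):
        ws = fixed_index_windows(trace_with_spikes(spikes=(9, 54)), CFG)
        assert [(w.start, w.end) for w in ws] == [(20, 40)]

    def test_no_spikes_three_blocks(self):
        assert len(fixed_index_windows(trace_with_spikes(), CFG)) == 3

    def test_window_covering_whole_run_with_any_spike(self):
        cfg = WindowConfig(window_length=60, n_windows=1, initial_exclusion=0)
        assert len(fixed_index_windows(trace_with_spikes(spikes=(30,)), cfg)) == 0


class TestConcatenateWindows:
    def _bold(self, n=500):
        data = np.arange(2 * n, dtype=float).reshape(2, n)
        return BoldMatrix(data)

    def test_twenty_windows_of_twenty_gives_419_volumes(self, rng):
        fd = rng.uniform(0.0, 0.29, size=500)
        trace = MotionTrace((fd,))
        best = select_best_windows(find_candidate_windows(trace, CFG), CFG)
        out = concatenate_windows(self._bold(), best)
        assert out.n_volumes == 20 * 20 + 19
        assert int(out.censor_mask.sum()) == 19

    def test_single_window_identity(self):
        trace = MotionTrace((np.full(20, 0.1),))
        ws = find_candidate_windows(trace, CFG)
        out = concatenate_windows(self._bold(20), ws)
        assert np.array_equal(out.data, self._bold(20).data)
        assert not out.censor_mask.any()

    def test_adjoining_windows_still_get_one_separator(self):
        trace = MotionTrace((np.full(41, 0.1),))
        ws = find_candidate_windows(trace, CFG)  # windows [0,20) and [20,40) adjoin
        out = concatenate_windows(self._bold(41), ws)
        assert out.n_volumes == 41
        assert np.flatnonzero(out.censor_mask).tolist() == [20]

    def test_data_preserved_exactly_in_temporal_order(self):
        bold = self._bold(100)
        trace = trace_with_spikes(n=100, spikes=(25,))
        ws = find_candidate_windows(trace, CFG)
        out = concatenate_windows(bold, ws)
        uncensored = out.data[:, ~out.censor_mask]
        expected = np.concatenate(
            [bold.data[:, w.start : w.end] for w in ws], axis=1
        )
        assert np.array_equal(uncensored, expected)

    def test_empty_window_set_is_an_exclusion(self):
        from sampenmap.motion_windowing import WindowSet

        with pytest.raises(InsufficientWindowsError):
            concatenate_windows(self._bold(20), WindowSet((), np.empty(0)))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    fd_scaled=st.lists(st.integers(0, 10), min_size=5, max_size=120),
    length=st.integers(2, 15),
    initial_exclusion=st.integers(0, 5),
)
def test_flexible_search_matches_oracle_and_beats_fixed_indices(
    fd_scaled, length, initial_exclusion
):
    """The greedy flexible search equals a brute-force scan-and-pack, and
    never finds fewer candidates than fixed-index partitioning."""
    fd = np.asarray(fd_scaled, dtype=float) / 20.0  # spans the 0.3 threshold
    cfg = WindowConfig(
        fd_threshold=0.3,
        window_length=length,
        n_windows=5,
        initial_exclusion=initial_exclusion,
    )
    trace = MotionTrace((fd,))
    flexible = find_candidate_windows(trace, cfg)
    fixed = fixed_index_windows(trace, cfg)
    assert len(flexible) == brute_candidate_count([fd], 0.3, length, initial_exclusion)
    assert len(flexible) >= len(fixed)
    for w in flexible:
        assert w.end - w.start == length
        assert (fd[w.start : w.end] < 0.3).all()
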