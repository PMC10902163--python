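"""Low-motion windowing of FD traces.

The flexible window search looks, within each run, for maximal stretches of
consecutive volumes whose framewise displacement is strictly below a
threshold, and greedily packs fixed-length windows into each stretch
starting at its first usable volume.  This finds windows a fixed-index
partition misses: in a 60-volume run with high motion only at volumes 10
and 55 (1-based), fixed 20-volume blocks 1-20 / 21-40 / 41-60 yield one
usable block, while the flexible search yields two windows.

When more candidates are found than requested, the windows with the highest
mean FD are discarded (stable tie-break: the temporally earlier window is
kept).  Selected windows are concatenated with exactly one censored
separator volume between consecutive windows — even when the windows were
adjoining in the source — so every subject's concatenated series has an
identical length and censoring structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .exceptions import InsufficientWindowsError
from .signal_model import BoldMatrix, MotionTrace

__all__ = [
    "WindowConfig",
    "Window",
    "WindowSet",
    "find_candidate_windows",
    "select_best_windows",
    "concatenate_windows",
    "fixed_index_windows",
]

#: Placeholder stored in separator columns of a concatenated matrix. The
#: censor mask, never this value, governs downstream behaviour.
SEPARATOR_SENTINEL = 0.0


@dataclass(frozen=True)
class WindowConfig:
    """Windowing parameters.

    fd_threshold:
        Volumes with FD >= this value (mm) are unusable (usability is the
        strict inequality FD < threshold).
    window_length:
        Window length L in volumes.
    n_windows:
        Number of windows K requested.
    initial_exclusion:
        Volumes dropped from the start of every run before any search.
    """

    fd_threshold: float = 0.3
    window_length: int = 20
    n_windows: int = 20
    initial_exclusion: int = 10

    def __post_init__(self) -> None:
        if not self.fd_threshold > 0:
            raise ValueError("fd_threshold must be > 0")
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.initial_exclusion < 0:
            raise ValueError("initial_exclusion must be >= 0")


class Window(NamedTuple):
    """A half-open [start, end) interval of global volume indices in run `run`."""

    run: int
    start: int
    end: int

    def display(self) -> str:
        """1-based inclusive rendering, e.g. 'run 1: volumes 11-30'."""
        return f"run {self.run + 1}: volumes {self.start + 1}-{self.end}"


@dataclass
class WindowSet:
    """An ordered collection of non-overlapping equal-length windows."""

    windows: tuple[Window, ...]
    mean_fd: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.windows = tuple(Window(int(r), int(a), int(b)) for r, a, b in self.windows)
        self.mean_fd = np.asarray(self.mean_fd, dtype=float)
        if self.mean_fd.shape != (len(self.windows),):
            raise ValueError("mean_fd must have one value per window")
        prev_end = -1
        for w in self.windows:
            if w.end <= w.start:
                raise ValueError(f"empty or inverted window {w}")
            if w.start < prev_end:
                raise ValueError("windows must be sorted and non-overlapping")
            prev_end = w.end

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[Window]:
        return iter(self.windows)


def _iter_usable_segments(usable: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield maximal half-open runs of True in a boolean vector."""
    padded = np.concatenate(([False], usable, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    yield from zip(starts, ends)


def _run_usability(
    trace: MotionTrace, cfg: WindowConfig, exclude: np.ndarray | None
) -> Iterator[tuple[int, int, np.ndarray]]:
    """Per run: (run index, global offset, usability mask within the run)."""
    offset = 0
    total = trace.n_volumes
    if exclude is not None:
        exclude = np.asarray(exclude, dtype=bool)
        if exclude.shape != (total,):
            raise ValueError("exclude mask length must match the trace")
    for run_idx, fd in enumerate(trace.fd):
        usable = fd < cfg.fd_threshold
        usable[: cfg.initial_exclusion] = False
        if exclude is not None:
            usable &= ~exclude[offset : offset + fd.size]
        yield run_idx, offset, usable
        offset += fd.size


def find_candidate_windows(
    trace: MotionTrace, cfg: WindowConfig, exclude: np.ndarray | None = None
) -> WindowSet:
    """Flexible low-motion window search.

    Within each run, after dropping the initial-exclusion volumes, each
    maximal stretch of consecutive usable volumes (FD strictly below the
    threshold, and not flagged in the optional ``exclude`` mask) is greedily
    packed with consecutive windows of length L anchored at the stretch's
    first volume.  Windows never span a run boundary.  Returns all
    candidates with their mean FD; an empty set is a valid return.
    """
    L = cfg.window_length
    fd_all = trace.concatenated
    windows: list[Window] = []
    for run_idx, offset, usable in _run_usability(trace, cfg, exclude):
        for seg_start, seg_end in _iter_usable_segments(usable):
            s = seg_start
            while s + L <= seg_end:
                windows.append(Window(run_idx, offset + s, offset + s + L))
                s += L
    mean_fd = np.array([fd_all[w.start : w.end].mean() for w in windows])
    return WindowSet(tuple(windows), mean_fd)


def select_best_windows(candidates: WindowSet, cfg: WindowConfig) -> WindowSet:
    """Keep the K candidates with the lowest mean FD.

    If there are at most K candidates, all are returned unchanged.
    Otherwise the (count - K) windows with the highest mean FD are
    discarded.  The sort is stable, so among windows tied at the cut the
    temporally earlier one is kept.  The kept windows are returned in
    temporal order.
    """
    k = cfg.n_windows
    if len(candidates) <= k:
        return candidates
    order = np.argsort(candidates.mean_fd, kind="stable")
    keep = np.sort(order[:k])
    return WindowSet(
        tuple(candidates.windows[i] for i in keep), candidates.mean_fd[keep]
    )


def concatenate_windows(bold: BoldMatrix, ws: WindowSet) -> BoldMatrix:
    """Concatenate selected windows with one censored separator between each.

    The output has ``K*L + (K-1)`` volumes; the censor mask is True exactly
    at the K-1 separator positions, whose data columns hold a placeholder
    value that downstream code must never read.  Window data is copied
    verbatim in temporal order.  A separator is inserted between every pair
    of consecutive windows even if they were adjoining in the source, so
    all subjects share one censoring structure.
    """
    if len(ws) == 0:
        raise InsufficientWindowsError(
            "cannot concatenate an empty window set; the subject fails inclusion"
        )
    lengths = {w.end - w.start for w in ws}
    if len(lengths) != 1:
        raise ValueError(f"windows have mixed lengths {sorted(lengths)}")
    L = lengths.pop()
    k = len(ws)
    n_out = k * L + (k - 1)
    data = np.full((bold.n_grayordinates, n_out), SEPARATOR_SENTINEL)
    censor = np.zeros(n_out, dtype=bool)
    pos = 0
    for i, w in enumerate(ws):
        if w.end > bold.n_volumes:
            raise ValueError(f"window {w} exceeds the BOLD matrix ({bold.n_volumes} volumes)")
        data[:, pos : pos + L] = bold.data[:, w.start : w.end]
        pos += L
        if i < k - 1:
            censor[pos] = True
            pos += 1
    return BoldMatrix(data, censor, ((0, n_out),), space=bold.space, tr=bold.tr)


def fixed_index_windows(
    trace: MotionTrace, cfg: WindowConfig, exclude: np.ndarray | None = None
) -> WindowSet:
    """Fixed-index comparator: partition each run (after initial exclusion)
    into consecutive L-length blocks at fixed offsets and keep only the
    blocks whose volumes are all usable."""
    L = cfg.window_length
    fd_all = trace.concatenated
    windows: list[Window] = []
    for run_idx, offset, usable in _run_usability(trace, cfg, exclude):
        s = cfg.initial_exclusion
        while s + L <= usable.size:
            if usable[s : s + L].all():
                windows.append(Window(run_idx, offset + s, offset + s + L))
            s += L
    mean_fd = np.array([fd_all[w.start : w.end].mean() for w in windows])
    return WindowSet(tuple(windows), mean_fd)
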