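"""Core domain types and a synthetic fixture generator.

The central in-memory containers are :class:`BoldMatrix` (grayordinates x
volumes with a per-volume censor mask and run boundaries) and
:class:`MotionTrace` (per-volume framewise displacement, one vector per
run). :class:`SyntheticSpec` parameterizes a generator that emulates
AR-structured BOLD signals with motion-spike contamination, so every stage
of the pipeline can be exercised without any imaging data.

Volume indexing is 0-based, half-open ``[start, end)`` everywhere in code;
user-facing reports convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "BoldMatrix",
    "MotionTrace",
    "SyntheticSpec",
    "generate_bold",
    "generate_repeated_entropy",
    "ar_companion_spectral_radius",
]

#: Amplitude of the additive artifact injected at a spiked volume, in units
#: of (noise_sd * spike_fd[mm]).  Motion corrupts signal coherently across
#: grayordinates; the magnitude scales with the framewise displacement of
#: the spike.
ARTIFACT_GAIN = 4.0

#: Population mean of the pseudo-entropy fixture used for reliability tests.
ENTROPY_FIXTURE_MEAN = 1.0

#: Samples discarded at the start of each simulated AR run so the process
#: reaches its stationary distribution.
_AR_BURN_IN = 200


@dataclass
class BoldMatrix:
    """A grayordinate x time BOLD matrix.

    Parameters
    ----------
    data:
        Array of shape (G, N), BOLD amplitude in arbitrary units.
    censor_mask:
        Boolean array of length N; True marks a censored volume that must be
        ignored by template matching and model fitting.  Censored columns may
        hold a placeholder value; the mask, not the value, is authoritative.
    run_boundaries:
        Ordered half-open (start, end) volume intervals, one per run,
        partitioning [0, N).
    space:
        One of ``"dense"``, ``"parcellated"``, ``"plain"``.
    tr:
        Seconds per volume, if known.
    """

    data: np.ndarray
    censor_mask: np.ndarray | None = None
    run_boundaries: tuple[tuple[int, int], ...] | None = None
    space: str = "plain"
    tr: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D grayordinate x time matrix")
        g, n = self.data.shape
        if g < 1 or n < 1:
            raise ValueError("data must have at least one grayordinate and one volume")
        if self.censor_mask is None:
            self.censor_mask = np.zeros(n, dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape != (n,):
            raise ValueError("censor_mask length must equal the number of volumes")
        if self.run_boundaries is None:
            self.run_boundaries = ((0, n),)
        self.run_boundaries = tuple((int(a), int(b)) for a, b in self.run_boundaries)
        pos = 0
        for a, b in self.run_boundaries:
            if a != pos or b <= a:
                raise ValueError(
                    f"run_boundaries must partition [0, {n}) with no gaps or "
                    f"overlaps; got {self.run_boundaries}"
                )
            pos = b
        if pos != n:
            raise ValueError(
                f"run_boundaries cover [0, {pos}) but the matrix has {n} volumes"
            )
        if self.space not in ("dense", "parcellated", "plain"):
            raise ValueError(f"unknown space {self.space!r}")
        if not np.isfinite(self.data[:, ~self.censor_mask]).all():
            raise ValueError("non-finite values in uncensored columns")

    @property
    def n_grayordinates(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)

    def uncensored_segments(self) -> list[tuple[int, int]]:
        """Maximal contiguous uncensored intervals that do not cross a run
        boundary, as half-open (start, end) pairs."""
        segments: list[tuple[int, int]] = []
        for a, b in self.run_boundaries:
            start = None
            for i in range(a, b):
                if not self.censor_mask[i]:
                    if start is None:
                        start = i
                else:
                    if start is not None:
                        segments.append((start, i))
                        start = None
            if start is not None:
                segments.append((start, b))
        return segments


@dataclass
class MotionTrace:
    """Per-volume framewise displacement (FD, mm), one vector per run."""

    fd: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        self.fd = tuple(np.asarray(v, dtype=float).ravel() for v in self.fd)
        if not self.fd:
            raise ValueError("MotionTrace needs at least one run")
        for i, v in enumerate(self.fd):
            if v.size == 0:
                raise ValueError(f"run {i + 1} has an empty FD vector")
            if not np.isfinite(v).all() or (v < 0).any():
                raise ValueError(f"run {i + 1} has negative or non-finite FD values")

    @property
    def run_lengths(self) -> tuple[int, ...]:
        return tuple(v.size for v in self.fd)

    @property
    def n_volumes(self) -> int:
        return int(sum(self.run_lengths))

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.fd)

    def check_paired(self, bold: BoldMatrix) -> None:
        """Raise unless this trace aligns volume-for-volume with *bold*."""
        if self.run_lengths != tuple(b - a for a, b in bold.run_boundaries):
            raise ValueError(
                f"FD run lengths {self.run_lengths} do not match BOLD run "
                f"boundaries {bold.run_boundaries}"
            )


def ar_companion_spectral_radius(coefficients: np.ndarray) -> float:
    """Spectral radius of the AR companion matrix; < 1 means stationary."""
    phi = np.atleast_1d(np.asarray(coefficients, dtype=float))
    p = phi.size
    if p == 0:
        return 0.0
    companion = np.zeros((p, p))
    companion[0, :] = phi
    if p > 1:
        companion[1:, :-1] = np.eye(p - 1)
    return float(np.abs(np.linalg.eigvals(companion)).max())


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic BOLD + motion fixture generator.

    Defaults emulate a two-run resting-state acquisition at TR 0.8 s with
    AR(2)-structured signals, a constant low-motion FD floor and sporadic
    high-motion spikes whose additive amplitude artifact corrupts the BOLD
    data at the spiked volumes.
    """

    n_subjects: int = 1
    n_grayordinates: int = 8
    n_volumes_per_run: int = 375
    n_runs: int = 2
    ar_coefficients: tuple[tuple[float, ...], ...] = ((0.5, -0.3),)
    noise_sd: float = 1.0
    spike_rate: float = 5.0
    spike_fd: float = 1.0
    baseline_fd: float = 0.1
    between_subject_sd: float = 1.0
    within_subject_sd: float = 1.0
    tr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_grayordinates, self.n_runs) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_volumes_per_run < 1:
            raise ValueError("n_volumes_per_run must be >= 1")
        self.ar_coefficients = tuple(
            tuple(float(c) for c in group) for group in self.ar_coefficients
        )
        if not self.ar_coefficients:
            raise ValueError("at least one AR coefficient group is required")
        for gi, group in enumerate(self.ar_coefficients):
            rho = ar_companion_spectral_radius(np.asarray(group))
            if rho >= 1.0:
                raise ValueError(
                    f"AR coefficient group {gi} {group} is non-stationary "
                    f"(companion spectral radius {rho:.3f} >= 1)"
                )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.baseline_fd < 0 or not self.spike_fd > self.baseline_fd:
            raise ValueError("need spike_fd > baseline_fd >= 0")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("variance-component SDs must be >= 0")


def _simulate_ar(phi: np.ndarray, n: int, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Simulate a stationary AR(p) series of length n (after burn-in)."""
    eps = rng.normal(0.0, noise_sd, size=n + _AR_BURN_IN)
    if phi.size == 0:
        return eps[_AR_BURN_IN:]
    a = np.concatenate(([1.0], -phi))
    series = lfilter([1.0], a, eps)
    return series[_AR_BURN_IN:]


def generate_bold(spec: SyntheticSpec) -> tuple[BoldMatrix, MotionTrace]:
    """Generate one subject's multi-run BOLD matrix and paired FD trace.

    Each grayordinate follows the AR process of its coefficient group
    (groups are assigned cyclically over grayordinates).  Per run, the
    number of high-motion events is Poisson(``spike_rate``); spiked volumes
    get FD ``spike_fd`` and all grayordinates receive a coherent additive
    amplitude offset of magnitude ``ARTIFACT_GAIN * noise_sd * spike_fd``
    with a random sign per event, so motion corrupts the signal the way the
    windowing procedure is designed to guard against.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    g, n_run, n_runs = spec.n_grayordinates, spec.n_volumes_per_run, spec.n_runs
    n = n_run * n_runs
    data = np.empty((g, n))
    fd_runs: list[np.ndarray] = []
    spike_cols: list[np.ndarray] = []
    for r in range(n_runs):
        sl = slice(r * n_run, (r + 1) * n_run)
        for gi in range(g):
            phi = np.asarray(spec.ar_coefficients[gi % len(spec.ar_coefficients)])
            data[gi, sl] = _simulate_ar(phi, n_run, spec.noise_sd, rng)
        fd = np.full(n_run, spec.baseline_fd)
        n_spikes = min(int(rng.poisson(spec.spike_rate)), n_run)
        pos = rng.choice(n_run, size=n_spikes, replace=False) if n_spikes else np.empty(0, int)
        fd[pos] = spec.spike_fd
        fd_runs.append(fd)
        spike_cols.append(np.sort(pos) + r * n_run)
    # coherent artifact: one sign per motion event, applied to every row
    for col_group in spike_cols:
        for col in col_group:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[:, col] += sign * ARTIFACT_GAIN * spec.noise_sd * spec.spike_fd
    boundaries = tuple((r * n_run, (r + 1) * n_run) for r in range(n_runs))
    bold = BoldMatrix(data, run_boundaries=boundaries, space="plain", tr=spec.tr)
    return bold, MotionTrace(tuple(fd_runs))


def generate_repeated_entropy(spec: SyntheticSpec) -> np.ndarray:
    """Draw pseudo-entropy repeated measurements from the two-level model
    ``mu_ij = mu + alpha_i + e_ij``.

    Returns an array of shape (n_grayordinates, n_subjects, 2) with
    ``alpha_i ~ N(0, between_subject_sd**2)`` per subject per grayordinate
    and ``e_ij ~ N(0, within_subject_sd**2)`` per measurement.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    g, s = spec.n_grayordinates, spec.n_subjects
    alpha = rng.normal(0.0, spec.between_subject_sd, size=(g, s, 1))
    e = rng.normal(0.0, spec.within_subject_sd, size=(g, s, 2))
    return ENTROPY_FIXTURE_MEAN + alpha + e
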