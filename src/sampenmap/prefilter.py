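"""Optional prefiltering: interpolate high-motion volumes, then bandpass.

Bandpass filtering a series that still contains motion spikes smears the
spike into neighbouring low-motion volumes (the filter's impulse response
is long compared to a spike).  Replacing high-motion volumes by linear
interpolation between their nearest clean neighbours *before* filtering
prevents that propagation; the interpolated volumes themselves are marked
censored so entropy calculation never reads fabricated data.

The filter is a zero-phase (forward-backward) Butterworth bandpass, order 2
per pass, applied per run after demeaning and symmetric zero-padding; the
mean is restored afterwards.  Filtering never crosses a run boundary.

This stage is off by default in the pipeline; upstream preprocessing often
performs an equivalent step already.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt, sosfilt

from .signal_model import BoldMatrix, MotionTrace

__all__ = ["FilterConfig", "interpolate_high_motion", "bandpass", "design_bandpass"]


@dataclass(frozen=True)
class FilterConfig:
    """Bandpass and interpolation settings.

    low_cut / high_cut:
        Passband edges in Hz; must satisfy 0 < low < high < Nyquist.
    sampling_interval:
        Seconds per volume (TR).
    pad_volumes:
        Zeros appended to each end before filtering; None derives one
        impulse-response length from the designed filter.
    interpolate_high_motion:
        Whether the interpolation stage runs before the bandpass.
    fd_threshold_for_interp:
        Volumes with FD >= this (mm) are interpolated.
    """

    low_cut: float = 0.009
    high_cut: float = 0.25
    sampling_interval: float = 0.8
    pad_volumes: int | None = None
    interpolate_high_motion: bool = False
    fd_threshold_for_interp: float = 0.2

    def __post_init__(self) -> None:
        nyquist = 0.5 / self.sampling_interval
        if not (0.0 < self.low_cut < self.high_cut < nyquist):
            raise ValueError(
                f"cutoffs must satisfy 0 < {self.low_cut} < {self.high_cut} < "
                f"Nyquist ({nyquist:.4g} Hz at TR {self.sampling_interval}s)"
            )
        if self.pad_volumes is not None and self.pad_volumes < 0:
            raise ValueError("pad_volumes must be >= 0")
        if not self.fd_threshold_for_interp > 0:
            raise ValueError("fd_threshold_for_interp must be > 0")


def design_bandpass(cfg: FilterConfig) -> np.ndarray:
    """Second-order-sections of the order-2 Butterworth bandpass."""
    fs = 1.0 / cfg.sampling_interval
    return butter(2, [cfg.low_cut, cfg.high_cut], btype="bandpass", fs=fs, output="sos")


def _impulse_response_length(sos: np.ndarray, cap: int = 4096) -> int:
    """Samples until the filter impulse response decays below 1e-3 of its peak."""
    impulse = np.zeros(cap)
    impulse[0] = 1.0
    h = sosfilt(sos, impulse)
    peak = np.abs(h).max()
    above = np.flatnonzero(np.abs(h) > 1e-3 * peak)
    return int(above[-1]) + 1 if above.size else 1


def interpolate_high_motion(
    bold: BoldMatrix, trace: MotionTrace, cfg: FilterConfig
) -> BoldMatrix:
    """Replace high-motion volumes by linear interpolation within each run.

    Volumes with FD >= ``fd_threshold_for_interp`` are rebuilt by linear
    interpolation between the nearest sub-threshold neighbours of the same
    run; contaminated volumes at a run's edges take the nearest clean
    value.  The returned matrix marks every interpolated volume censored,
    so windowing and entropy calculation can never include it.
    """
    trace.check_paired(bold)
    data = bold.data.copy()
    censor = bold.censor_mask.copy()
    offset = 0
    for run_idx, fd in enumerate(trace.fd):
        n = fd.size
        bad = fd >= cfg.fd_threshold_for_interp
        if bad.any():
            good = np.flatnonzero(~bad)
            if good.size < 2:
                raise ValueError(
                    f"run {run_idx + 1} has {good.size} sub-threshold volumes; "
                    "at least 2 are needed to interpolate"
                )
            bad_idx = np.flatnonzero(bad)
            for gi in range(data.shape[0]):
                row = data[gi, offset : offset + n]
                row[bad_idx] = np.interp(bad_idx, good, row[good])
            censor[offset + bad_idx] = True
        offset += n
    return BoldMatrix(data, censor, bold.run_boundaries, bold.space, bold.tr)


def bandpass(bold: BoldMatrix, cfg: FilterConfig) -> BoldMatrix:
    """Zero-phase bandpass per run, per grayordinate.

    Each run is demeaned, zero-padded by ``pad_volumes`` on both ends,
    filtered forward-backward, trimmed, and the mean restored.
    """
    sos = design_bandpass(cfg)
    pad = cfg.pad_volumes if cfg.pad_volumes is not None else _impulse_response_length(sos)
    out = bold.data.copy()
    for a, b in bold.run_boundaries:
        x = bold.data[:, a:b]
        if b - a < 8:
            raise ValueError(f"run [{a}, {b}) is too short to filter")
        mu = x.mean(axis=1, keepdims=True)
        padded = np.pad(x - mu, ((0, 0), (pad, pad)))
        filtered = sosfiltfilt(sos, padded, axis=1, padtype=None)
        out[:, a:b] = (filtered[:, pad : pad + (b - a)] if pad else filtered) + mu
    return BoldMatrix(out, bold.censor_mask.copy(), bold.run_boundaries, bold.space, bold.tr)
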