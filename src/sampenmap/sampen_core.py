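"""Censoring-aware sample entropy (SampEn) with match-count diagnostics.

SampEn compares length-m templates of a time series under the Chebyshev
(maximum coordinate-wise) distance: two templates match when every
coordinate pair differs by at most the tolerance.  With ``Cm`` the number of
ordered template pairs matching over m points and ``Cm1`` the number also
matching at the (m+1)-th point, SampEn is ``-ln(Cm1/Cm)`` — the negative
log of the conditional probability that sequences matching for m points
also match at m+1.  Self-matches are never counted.  When either count is
zero, SampEn is not mathematically defined and a sentinel (NaN) is
returned.

Censoring support follows the screening-condition approach for missing
values in physiological time series: templates are enumerated only at start
positions whose m+1 constituent volumes are all uncensored, so censored
volumes (window separators, high-motion volumes) are transparently ignored
without distorting the remaining data.

Both template lengths are enumerated from the common set of start positions
valid for length m+1 (the Richman-Moorman convention, which guarantees
``Cm1 <= Cm``).  Alongside the match counts, the overlap counts ``K_B`` and
``K_A`` (matching ordered pairs whose template index ranges share a time
index, at lengths m and m+1 respectively) are recorded for the variance
estimator used by parameter optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import (
    DegenerateSeriesError,
    UndefinedCountsError,
    UndefinedSampEnWarning,
)
from .signal_model import BoldMatrix

__all__ = [
    "SampEnParams",
    "MatchCounts",
    "SampEnResult",
    "effective_tolerance",
    "count_matches",
    "sampen",
    "sampen_map",
]

_ROW_BLOCK = 512  # pairwise-distance block size; bounds memory at ~block*T floats


@dataclass(frozen=True)
class SampEnParams:
    """Template length m, tolerance factor r, and how r is interpreted.

    In ``relative_to_sd`` mode (the field standard) the match threshold is
    ``r`` times the standard deviation of the analyzed (uncensored) series,
    computed per series; in ``absolute`` mode ``r`` is the threshold itself,
    in amplitude units.
    """

    m: int = 2
    r: float = 0.3
    tolerance_mode: str = "relative_to_sd"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r > 0:
            raise ValueError("r must be > 0")
        if self.tolerance_mode not in ("relative_to_sd", "absolute"):
            raise ValueError(f"unknown tolerance_mode {self.tolerance_mode!r}")


@dataclass(frozen=True)
class MatchCounts:
    """Ordered-pair match counts at template lengths m and m+1.

    ``cm``/``cm1`` count ordered pairs (i, j), i != j (each unordered pair
    twice); ``k_b``/``k_a`` count the subsets of those pairs whose template
    index ranges overlap in time, needed by the CP variance estimator;
    ``n_templates`` is the number of valid template start positions.
    """

    cm: int
    cm1: int
    k_b: int
    k_a: int
    n_templates: int

    def __post_init__(self) -> None:
        if not (0 <= self.cm1 <= self.cm):
            raise ValueError("need 0 <= Cm1 <= Cm")
        if min(self.k_a, self.k_b, self.n_templates) < 0:
            raise ValueError("counts must be >= 0")
        if self.k_a > self.cm1 or self.k_b > self.cm:
            raise ValueError("overlap counts cannot exceed match counts")

    @property
    def cp(self) -> float:
        """Conditional probability CP = Cm1 / Cm."""
        if self.cm == 0:
            return float("nan")
        return self.cm1 / self.cm


@dataclass
class SampEnResult:
    """Per-grayordinate entropy map with diagnostics.

    ``entropy`` holds NaN (the undefined sentinel) for rows where SampEn is
    not defined; ``counts`` holds the per-row :class:`MatchCounts` or None
    for degenerate rows; ``n_effective`` is the number of uncensored
    volumes analyzed.
    """

    entropy: np.ndarray
    counts: list[MatchCounts | None]
    params: SampEnParams
    n_effective: int


def effective_tolerance(
    x: np.ndarray, censor: np.ndarray | None, p: SampEnParams
) -> float:
    """Amplitude threshold for accepting a match.

    In relative mode this is r times the sample standard deviation of the
    uncensored points of *x* (the series actually analyzed — motion-inflated
    variance from excluded volumes must not leak into the tolerance); in
    absolute mode it is r unchanged.
    """
    if p.tolerance_mode == "absolute":
        return float(p.r)
    x = np.asarray(x, dtype=float)
    kept = x if censor is None else x[~np.asarray(censor, dtype=bool)]
    if kept.size < 2:
        raise DegenerateSeriesError(
            f"need >= 2 uncensored points to estimate SD (got {kept.size})"
        )
    sd = float(kept.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSeriesError("zero-variance series: tolerance undefined")
    return float(p.r) * sd


def _valid_template_starts(censor: np.ndarray | None, n: int, m: int) -> np.ndarray:
    """Start positions whose m+1 constituent volumes are all uncensored."""
    if n < m + 1:
        return np.empty(0, dtype=int)
    if censor is None:
        return np.arange(n - m)
    censor = np.asarray(censor, dtype=bool)
    bad = sliding_window_view(censor, m + 1).any(axis=1)
    return np.flatnonzero(~bad)


def count_matches(
    x: np.ndarray,
    censor: np.ndarray | None,
    p: SampEnParams,
    tol: float,
) -> MatchCounts:
    """Enumerate ordered template matches of *x* at lengths m and m+1.

    Templates start at every position i whose volumes i..i+m are all
    uncensored.  An ordered pair (i, j), i != j, contributes to ``Cm`` when
    the Chebyshev distance of the first m coordinates is <= *tol*, and
    additionally to ``Cm1`` when the (m+1)-th coordinates also differ by
    <= *tol*.  ``K_B``/``K_A`` count the contributing pairs whose template
    index ranges overlap.
    """
    x = np.asarray(x, dtype=float)
    m = p.m
    starts = _valid_template_starts(censor, x.size, m)
    if starts.size == 0:
        raise UndefinedCountsError(
            f"no valid template positions for m={m} "
            f"(series length {x.size}, censored "
            f"{0 if censor is None else int(np.sum(censor))})"
        )
    X = sliding_window_view(x, m + 1)[starts]  # (T, m+1)
    T = X.shape[0]
    cm = cm1 = k_b = k_a = 0
    for i0 in range(0, T, _ROW_BLOCK):
        i1 = min(i0 + _ROW_BLOCK, T)
        Xi = X[i0:i1]
        dist_m = np.abs(Xi[:, 0, None] - X[None, :, 0])
        for k in range(1, m):
            np.maximum(dist_m, np.abs(Xi[:, k, None] - X[None, :, k]), out=dist_m)
        b = dist_m <= tol
        b[np.arange(i1 - i0), np.arange(i0, i1)] = False  # no self-matches
        a = b & (np.abs(Xi[:, m, None] - X[None, :, m]) <= tol)
        sep = np.abs(starts[i0:i1, None] - starts[None, :])
        cm += int(b.sum())
        cm1 += int(a.sum())
        k_b += int((b & (sep <= m - 1)).sum())
        k_a += int((a & (sep <= m)).sum())
    return MatchCounts(cm, cm1, k_b, k_a, T)


def sampen(
    x: np.ndarray,
    censor: np.ndarray | None = None,
    p: SampEnParams = SampEnParams(),
) -> float:
    """Sample entropy of a single series: ``-ln(Cm1/Cm)``.

    Returns NaN (with an :class:`UndefinedSampEnWarning`) when no matches
    exist at length m or m+1, in which case SampEn is not mathematically
    defined.  Raises :class:`DegenerateSeriesError` for zero-variance input
    in relative-tolerance mode.
    """
    tol = effective_tolerance(x, censor, p)
    counts = count_matches(x, censor, p, tol)
    return _entropy_from_counts(counts)


def _entropy_from_counts(counts: MatchCounts) -> float:
    if counts.cm == 0 or counts.cm1 == 0:
        warnings.warn(
            "SampEn is not mathematically defined for this series "
            f"(Cm={counts.cm}, Cm1={counts.cm1}); returning the undefined sentinel",
            UndefinedSampEnWarning,
            stacklevel=3,
        )
        return float("nan")
    return float(np.log(counts.cm) - np.log(counts.cm1))


def sampen_map(bold: BoldMatrix, p: SampEnParams = SampEnParams()) -> SampEnResult:
    """Apply :func:`sampen` independently to every grayordinate row.

    Each row uses its own effective tolerance.  Rows with undefined entropy
    (degenerate variance, no valid templates, or no matches) carry the NaN
    sentinel; the pipeline never fails on a single bad row.
    """
    g = bold.n_grayordinates
    entropy = np.full(g, np.nan)
    counts: list[MatchCounts | None] = [None] * g
    censor = bold.censor_mask
    for gi in range(g):
        try:
            tol = effective_tolerance(bold.data[gi], censor, p)
            c = count_matches(bold.data[gi], censor, p, tol)
        except (DegenerateSeriesError, UndefinedCountsError):
            continue
        counts[gi] = c
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedSampEnWarning)
            entropy[gi] = _entropy_from_counts(c)
    n_effective = int(np.sum(~censor))
    return SampEnResult(entropy, counts, p, n_effective)
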