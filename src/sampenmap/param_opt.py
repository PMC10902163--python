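"""Data-driven selection of the SampEn parameters m and r.

Two stages, intended to be run in order:

* :func:`select_m` fits autoregressive models of increasing order to every
  series and takes the AIC-minimizing order, aggregated across series and
  subjects, as the suggested template length m.  The rationale: the AR
  order is the number of past volumes that carry predictive information,
  which is exactly what the template length should capture.

* :func:`search_mr_grid` evaluates, for candidate (m, r) pairs, an error
  criterion based on the variance of the conditional-probability estimator
  CP = Cm1/Cm: the maximum of the relative error of the CP estimate
  (sigma_CP / CP) and of the SampEn estimate (sigma_CP / (-CP ln CP)).
  Good tolerances keep the number of matches large (small sigma_CP) while
  keeping CP away from 1 (where -ln CP vanishes and SampEn becomes
  unstable).  The criterion is aggregated by median across grayordinates
  within subject; the across-subject distribution per cell is exposed.

sigma_CP**2 accounts for the correlation between overlapping template
pairs:  ``CP(1-CP)/Cm + (K_A - K_B*CP**2) / Cm**2``, where K_A and K_B
count matching ordered pairs with overlapping index ranges at template
lengths m+1 and m.  It is floored at zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSeriesError, UndefinedCountsError
from .sampen_core import MatchCounts, SampEnParams, count_matches, effective_tolerance
from .signal_model import BoldMatrix

__all__ = [
    "ARFit",
    "ARFitSummary",
    "ErrorCriterionGrid",
    "fit_ar_orders",
    "select_m",
    "cp_variance",
    "error_criterion",
    "error_criterion_from_counts",
    "search_mr_grid",
    "default_r_grid",
    "default_m_grid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ARFit:
    """AIC trace over candidate AR orders for one contiguous segment."""

    order: int
    aic_by_order: np.ndarray

    def __post_init__(self) -> None:
        if int(np.nanargmin(self.aic_by_order)) != self.order:
            raise ValueError("order must minimize aic_by_order")


@dataclass(frozen=True)
class ARFitSummary:
    """Aggregate of per-segment AR order selections across an ensemble."""

    suggested_m: int
    order_counts: dict[int, int]
    n_segments: int
    n_skipped: int


def fit_ar_orders(segment: np.ndarray, max_order: int) -> ARFit:
    """Fit AR(0..max_order) to one contiguous series and select by AIC.

    All orders are fit by conditional maximum likelihood (least squares
    with an intercept) on the common sample obtained by holding back
    ``max_order`` initial values, so AIC values are comparable across
    orders.  AIC = -2 loglik + 2 (order + 2), counting the intercept and
    the innovation variance.
    """
    from statsmodels.tsa.ar_model import AutoReg

    y = np.asarray(segment, dtype=float)
    if y.size < max_order + 2:
        raise ValueError(
            f"segment of {y.size} points is too short for max_order={max_order}"
        )
    aic = np.full(max_order + 1, np.nan)
    held = y[max_order:]
    nobs = held.size
    sigma2 = float(np.mean((held - held.mean()) ** 2))
    if sigma2 <= 0:
        raise DegenerateSeriesError("zero-variance segment: AR fit undefined")
    ll0 = -0.5 * nobs * (math.log(2 * math.pi * sigma2) + 1.0)
    aic[0] = -2.0 * ll0 + 2.0 * 2
    for order in range(1, max_order + 1):
        res = AutoReg(y, lags=order, trend="c", hold_back=max_order).fit()
        aic[order] = -2.0 * float(res.llf) + 2.0 * (order + 2)
    return ARFit(int(np.nanargmin(aic)), aic)


def _segment_cap(length: int, max_order: int) -> int:
    # keep at least two thirds of the segment as regression sample
    return min(max_order, length // 3)


def select_m(
    ensemble: BoldMatrix | list[BoldMatrix], max_order: int = 10
) -> ARFitSummary:
    """Suggest the template length m from AR order selection.

    Every contiguous uncensored segment of every grayordinate series (of
    every subject) is fit separately — AR likelihoods assume contiguity, so
    fitting never crosses a censored separator or run boundary.  The
    searched order range is capped per segment at a third of its length so
    short windows cannot support more parameters than data.  Segments too
    short to fit are skipped and counted.  The suggestion is the modal
    AIC-selected order, ties broken toward the smaller order, clamped to
    >= 1.
    """
    bolds = [ensemble] if isinstance(ensemble, BoldMatrix) else list(ensemble)
    counts: Counter[int] = Counter()
    n_segments = 0
    n_skipped = 0
    for bold in bolds:
        segments = bold.uncensored_segments()
        for a, b in segments:
            local_max = _segment_cap(b - a, max_order)
            if local_max < 1 or (b - a) < local_max + 2:
                n_skipped += bold.n_grayordinates
                continue
            for gi in range(bold.n_grayordinates):
                try:
                    fit = fit_ar_orders(bold.data[gi, a:b], local_max)
                except DegenerateSeriesError:
                    n_skipped += 1
                    continue
                counts[fit.order] += 1
                n_segments += 1
    if n_skipped:
        logger.info("select_m skipped %d segment fits (too short or degenerate)", n_skipped)
    if not counts:
        raise ValueError("no segment was long enough to fit an AR model")
    top = max(counts.values())
    modal = min(order for order, c in counts.items() if c == top)
    return ARFitSummary(max(1, modal), dict(counts), n_segments, n_skipped)


def cp_variance(c: MatchCounts) -> float:
    """Variance of the CP = Cm1/Cm estimator, correcting for overlapping
    template pairs; floored at 0."""
    if c.cm == 0:
        raise UndefinedCountsError("Cm = 0: CP and its variance are undefined")
    cp = c.cm1 / c.cm
    var = cp * (1.0 - cp) / c.cm + (c.k_a - c.k_b * cp * cp) / (c.cm * c.cm)
    return max(var, 0.0)


def error_criterion_from_counts(c: MatchCounts) -> float:
    """max(sigma_CP/CP, sigma_CP/(-CP ln CP)) from precomputed counts.

    Returns +inf when CP is 0 or 1 (no matches to condition on, or
    -ln CP = 0), so that argmin semantics stay total: a tolerance at which
    every m-match extends is useless for estimating SampEn, and the
    criterion says so by sorting it last.
    """
    if c.cm == 0 or c.cm1 == 0:
        return float("inf")
    cp = c.cm1 / c.cm
    if cp >= 1.0:
        return float("inf")
    sigma = math.sqrt(cp_variance(c))
    return max(sigma / cp, sigma / (-cp * math.log(cp)))


def error_criterion(
    x: np.ndarray, censor: np.ndarray | None, p: SampEnParams
) -> float:
    """Error criterion of one series at parameters *p*.

    NaN flags an undefined cell (degenerate series or no valid templates);
    +inf flags CP in {0, 1}.
    """
    try:
        tol = effective_tolerance(x, censor, p)
        counts = count_matches(x, censor, p, tol)
    except (DegenerateSeriesError, UndefinedCountsError):
        return float("nan")
    return error_criterion_from_counts(counts)


def default_r_grid() -> np.ndarray:
    """Candidate tolerance factors 0.10, 0.15, ..., 0.60."""
    return np.round(np.arange(0.10, 0.601, 0.05), 2)


def default_m_grid(suggested_m: int) -> list[int]:
    """suggested m +/- 1, clamped to >= 1."""
    return sorted({max(1, suggested_m - 1), suggested_m, suggested_m + 1})


@dataclass
class ErrorCriterionGrid:
    """Per-subject median error criterion over an (m, r) grid.

    ``per_subject`` has shape (n_subjects, n_m, n_r): the median across
    grayordinates of the criterion, per subject.  NaN marks cells where no
    grayordinate produced a defined criterion.  ``per_region`` optionally
    splits the same aggregation by region mask.
    """

    m_values: list[int]
    r_values: np.ndarray
    per_subject: np.ndarray
    per_region: dict[str, np.ndarray] | None = None

    def aggregate(self) -> np.ndarray:
        """Median across subjects per cell (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(self.per_subject, axis=0)

    def argmin(self) -> tuple[int, float]:
        """(m, r) of the cell minimizing the across-subject median;
        all-undefined cells are excluded."""
        agg = self.aggregate()
        finite = np.isfinite(agg)
        if not finite.any():
            raise ValueError("every grid cell is undefined")
        masked = np.where(finite, agg, np.inf)
        i, j = np.unravel_index(int(np.argmin(masked)), agg.shape)
        return self.m_values[i], float(self.r_values[j])


def _subject_grid(
    bold: BoldMatrix,
    m_values: list[int],
    r_values: np.ndarray,
    region_masks: dict[str, np.ndarray] | None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    g = bold.n_grayordinates
    crit = np.full((g, len(m_values), len(r_values)), np.nan)
    for gi in range(g):
        for mi, m in enumerate(m_values):
            for ri, r in enumerate(r_values):
                crit[gi, mi, ri] = error_criterion(
                    bold.data[gi], bold.censor_mask, SampEnParams(m=m, r=float(r))
                )

    def _median(rows: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(rows, axis=0)

    regions = {}
    if region_masks:
        regions = {name: _median(crit[np.asarray(mask, bool)]) for name, mask in region_masks.items()}
    return _median(crit), regions


def search_mr_grid(
    ensemble: BoldMatrix | list[BoldMatrix],
    m_candidates: list[int],
    r_candidates: np.ndarray | list[float],
    region_masks: dict[str, np.ndarray] | None = None,
    n_workers: int = 1,
) -> ErrorCriterionGrid:
    """Evaluate the error criterion over an (m, r) grid for an ensemble.

    The criterion is computed per grayordinate series per cell, reduced to
    a median across grayordinates within each subject, and the per-subject
    medians are stacked.  Worker count is an opaque parallelism knob:
    results are bit-identical for any ``n_workers``.
    """
    bolds = [ensemble] if isinstance(ensemble, BoldMatrix) else list(ensemble)
    if not bolds:
        raise ValueError("empty ensemble")
    m_values = [int(m) for m in m_candidates]
    r_values = np.asarray(r_candidates, dtype=float)
    if not m_values or r_values.size == 0:
        raise ValueError("candidate lists must be non-empty")

    if n_workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_workers)(
            delayed(_subject_grid)(b, m_values, r_values, region_masks) for b in bolds
        )
    else:
        results = [_subject_grid(b, m_values, r_values, region_masks) for b in bolds]

    per_subject = np.stack([res[0] for res in results])
    per_region = None
    if region_masks:
        per_region = {
            name: np.stack([res[1][name] for res in results]) for name in region_masks
        }
    return ErrorCriterionGrid(m_values, r_values, per_subject, per_region)
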