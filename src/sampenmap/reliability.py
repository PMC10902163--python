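"""Test-retest reliability of entropy maps via intraclass correlation.

The model is the one-way random-effects ANOVA ``y_ij = mu + alpha_i +
e_ij`` with subject intercepts ``alpha_i ~ N(0, sigma2_alpha)`` and noise
``e_ij ~ N(0, sigma2_e)``.  The intraclass correlation is the share of
total variance attributable to stable between-subject differences,
``ICC(1,1) = sigma2_alpha / (sigma2_alpha + sigma2_e)``, estimated per
grayordinate from the repeated entropy measurements by restricted maximum
likelihood.  Negative variance solutions are truncated at zero (ICC 0);
a degenerate 0/0 case returns the NaN sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ICCResult", "icc_oneway", "icc_map"]

_SUMMARY_KEYS = ("min", "max", "median", "q1", "q3")


@dataclass
class ICCResult:
    """Per-grayordinate variance components and ICC.

    ``summary`` maps a region name to the (min, max, median, Q1, Q3) of the
    defined ICC values inside that region's mask.
    """

    icc: np.ndarray
    sigma2_alpha: np.ndarray
    sigma2_e: np.ndarray
    n_subjects: np.ndarray
    summary: dict[str, dict[str, float]] | None = None


def _variance_components_reml(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """REML estimates (sigma2_alpha, sigma2_e) of the one-way random model."""
    from statsmodels.regression.mixed_linear_model import MixedLM
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    exog = np.ones((values.size, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MixedLM(values, exog, groups=groups)
        res = model.fit(reml=True)
    return float(np.asarray(res.cov_re)[0, 0]), float(res.scale)


def _moment_components(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA moment estimator (fallback when REML fails)."""
    labels, inverse = np.unique(groups, return_inverse=True)
    k = labels.size
    n = values.size
    means = np.bincount(inverse, weights=values) / np.bincount(inverse)
    ssw = float(np.sum((values - means[inverse]) ** 2))
    grand = values.mean()
    counts = np.bincount(inverse)
    ssb = float(np.sum(counts * (means - grand) ** 2))
    msw = ssw / max(n - k, 1)
    msb = ssb / max(k - 1, 1)
    n0 = (n - np.sum(counts**2) / n) / max(k - 1, 1)
    s2a = max((msb - msw) / n0, 0.0)
    return s2a, msw


def icc_oneway(measurements: np.ndarray) -> tuple[float, float, float, int]:
    """ICC(1,1) from a subjects x repeats matrix (NaN = missing).

    Subjects with no finite measurement are dropped; at least two subjects
    contributing at least two measurements in total between them are
    required.  Returns ``(icc, sigma2_alpha, sigma2_e, n_subjects_used)``;
    the ICC is NaN when total variance is zero (0/0).
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise ValueError("measurements must be a 2-D subjects x repeats matrix")
    finite = np.isfinite(m)
    keep = finite.any(axis=1)
    m, finite = m[keep], finite[keep]
    n_subj = m.shape[0]
    if n_subj < 2 or int(finite.sum()) < n_subj + 1:
        raise ValueError("need >= 2 subjects and repeated measurements to estimate ICC")

    subj, rep = np.nonzero(finite)
    values = m[subj, rep]
    # pooled within-subject variance; exact-degenerate cases bypass REML
    counts = np.bincount(subj, minlength=n_subj)
    means = np.bincount(subj, weights=values, minlength=n_subj) / counts
    ssw = float(np.sum((values - means[subj]) ** 2))
    if ssw == 0.0:
        s2a = float(np.var(means, ddof=1))
        if s2a == 0.0:
            return float("nan"), 0.0, 0.0, n_subj
        return 1.0, s2a, 0.0, n_subj

    try:
        s2a, s2e = _variance_components_reml(values, subj)
        if not (np.isfinite(s2a) and np.isfinite(s2e)):
            raise ValueError
    except Exception:
        s2a, s2e = _moment_components(values, subj)
    s2a = max(s2a, 0.0)
    total = s2a + s2e
    icc = s2a / total if total > 0 else float("nan")
    return float(icc), float(s2a), float(s2e), n_subj


def _summarize(values: np.ndarray) -> dict[str, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {key: float("nan") for key in _SUMMARY_KEYS}
    stats = (v.min(), v.max(), np.median(v), np.percentile(v, 25), np.percentile(v, 75))
    return dict(zip(_SUMMARY_KEYS, (float(s) for s in stats)))


def icc_map(
    measurements_a: np.ndarray,
    measurements_b: np.ndarray,
    region_masks: dict[str, np.ndarray] | None = None,
) -> ICCResult:
    """Grayordinate-wise ICC between two repeated entropy maps.

    Inputs are (n_subjects, G) arrays of entropy values — e.g. the early
    and late scan-session measurements per subject — aligned on both axes.
    Per grayordinate, subjects carrying the undefined-entropy sentinel
    (NaN) in either measurement are skipped; a grayordinate with fewer
    than two usable subjects gets the NaN sentinel.  Summary statistics
    (min, max, median, Q1, Q3) are reported for the whole map and for each
    optional region mask.
    """
    a = np.asarray(measurements_a, dtype=float)
    b = np.asarray(measurements_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(
            f"measurement maps must share a subjects x grayordinates shape; "
            f"got {a.shape} vs {b.shape}"
        )
    n_subj, g = a.shape
    icc = np.full(g, np.nan)
    s2a = np.full(g, np.nan)
    s2e = np.full(g, np.nan)
    n_used = np.zeros(g, dtype=int)
    for gi in range(g):
        pair = np.column_stack([a[:, gi], b[:, gi]])
        usable = np.isfinite(pair).all(axis=1)
        if int(usable.sum()) < 2:
            continue
        try:
            icc[gi], s2a[gi], s2e[gi], n_used[gi] = icc_oneway(pair[usable])
        except ValueError:
            continue
    summary = {"all": _summarize(icc)}
    if region_masks:
        for name, mask in region_masks.items():
            summary[name] = _summarize(icc[np.asarray(mask, dtype=bool)])
    return ICCResult(icc, s2a, s2e, n_used, summary)
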