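"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive (pure-Python loops, direct formulas) and share
no code with the package; where a counting convention is ambiguous, the
oracle here is the normative definition.
"""

from __future__ import annotations

import math

import numpy as np


def brute_sampen_counts(x, censor, m, tol):
    """All-ordered-pairs template enumeration.

    Templates of length m and m+1 both start at every position i whose
    volumes i..i+m are uncensored.  Returns (cm, cm1, k_b, k_a,
    n_templates) with overlap counts defined on original time indices.
    """
    x = list(map(float, x))
    n = len(x)
    if censor is None:
        censor = [False] * n
    starts = [
        i for i in range(n - m) if not any(censor[i : i + m + 1])
    ]
    cm = cm1 = k_b = k_a = 0
    for i in starts:
        for j in starts:
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= tol:
                cm += 1
                if abs(i - j) <= m - 1:
                    k_b += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    cm1 += 1
                    if abs(i - j) <= m:
                        k_a += 1
    return cm, cm1, k_b, k_a, len(starts)


def brute_sampen(x, censor, m, tol):
    """-ln(Cm1/Cm) from the brute-force counts; NaN when undefined."""
    cm, cm1, *_ = brute_sampen_counts(x, censor, m, tol)
    if cm == 0 or cm1 == 0:
        return float("nan")
    return -math.log(cm1 / cm)


def split_window_counts(windows, m, tol):
    """Counts when templates are enumerated inside each window separately
    (no template may straddle a window join) but pairs may span windows.

    ``windows`` is a list of 1-D arrays.  Equivalent to censoring exactly
    the separator volumes of a concatenated series.
    """
    templates = []
    for w_idx, w in enumerate(windows):
        w = list(map(float, w))
        offset = sum(len(v) + 1 for v in windows[:w_idx])  # +1 separator
        for i in range(len(w) - m):
            templates.append((offset + i, w[i : i + m + 1]))
    cm = cm1 = k_b = k_a = 0
    for pi, (si, ti) in enumerate(templates):
        for pj, (sj, tj) in enumerate(templates):
            if pi == pj:
                continue
            if max(abs(a - b) for a, b in zip(ti[:m], tj[:m])) <= tol:
                cm += 1
                if abs(si - sj) <= m - 1:
                    k_b += 1
                if abs(ti[m] - tj[m]) <= tol:
                    cm1 += 1
                    if abs(si - sj) <= m:
                        k_a += 1
    return cm, cm1, k_b, k_a, len(templates)


def brute_candidate_count(fd_runs, threshold, length, initial_exclusion):
    """Scan every start index for a sub-threshold run of the window length
    and greedily pack, independently per run."""
    total = 0
    for fd in fd_runs:
        usable = [v < threshold for v in fd]
        for i in range(min(initial_exclusion, len(fd))):
            usable[i] = False
        i = 0
        while i + length <= len(fd):
            if all(usable[i : i + length]):
                total += 1
                i += length
            else:
                i += 1
    return total


def anova_icc(measurements):
    """Closed-form balanced one-way ANOVA moment estimator of ICC(1,1)."""
    m = np.asarray(measurements, dtype=float)
    n, k = m.shape
    means = m.mean(axis=1)
    grand = m.mean()
    msb = k * float(((means - grand) ** 2).sum()) / (n - 1)
    msw = float(((m - means[:, None]) ** 2).sum()) / (n * (k - 1))
    s2a = max((msb - msw) / k, 0.0)
    total = s2a + msw
    return s2a / total if total > 0 else float("nan")
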