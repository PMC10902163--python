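"""Censoring-aware SampEn against brute-force enumeration and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_sampen_counts
from sampenmap import (
    BoldMatrix,
    DegenerateSeriesError,
    MatchCounts,
    SampEnParams,
    UndefinedCountsError,
    UndefinedSampEnWarning,
    count_matches,
    effective_tolerance,
    sampen,
    sampen_map,
)
from conftest import random_series

ABS = "absolute"


def assert_counts_match_oracle(x, censor, m, tol):
    p = SampEnParams(m=m, r=tol, tolerance_mode=ABS)
    c = count_matches(x, censor, p, tol)
    cm, cm1, k_b, k_a, n_t = brute_sampen_counts(x, censor, m, tol)
    assert (c.cm, c.cm1, c.k_b, c.k_a, c.n_templates) == (cm, cm1, k_b, k_a, n_t)


class TestEffectiveTolerance:
    def test_relative_mode_scales_sd(self):
        x = np.array([0.0, 2.0] * 10)
        p = SampEnParams(m=2, r=0.3)
        sd = np.std(x, ddof=1)
        assert effective_tolerance(x, None, p) == pytest.approx(0.3 * sd)

    def test_censored_points_excluded_from_sd(self, rng):
        x = rng.normal(size=40)
        censor = np.zeros(40, bool)
        censor[::2] = True
        p = SampEnParams(m=2, r=0.25)
        expected = 0.25 * np.std(x[~censor], ddof=1)
        assert effective_tolerance(x, censor, p) == pytest.approx(expected)

    def test_constant_series_raises(self):
        with pytest.raises(DegenerateSeriesError):
            effective_tolerance(np.ones(30), None, SampEnParams())

    def test_absolute_mode_passthrough(self):
        assert effective_tolerance(np.ones(3), None, SampEnParams(r=0.7, tolerance_mode=ABS)) == 0.7


class TestCountMatches:
    def test_periodic_pattern_equals_exhaustive_enumeration(self):
        x = np.array([1.0, 3.0] * 6)  # length 12
        assert_counts_match_oracle(x, None, m=2, tol=0.5)

    def test_template_match_that_extends_increments_both_counts(self):
        # template at points 1-2 recurs at 11-12 and the third points also
        # match; A (Cm1) and B (Cm) each gain one ordered pair per direction
        x = 100.0 * np.arange(13.0)  # filler gaps far beyond the tolerance
        x[[0, 1, 2]] = [1.0, 2.0, 3.0]
        x[[10, 11, 12]] = [1.1, 2.1, 3.1]
        c = count_matches(x, None, SampEnParams(m=2, r=0.3, tolerance_mode=ABS), 0.3)
        assert (c.cm, c.cm1) == (2, 2)  # that single unordered pair, both directions
        assert_counts_match_oracle(x, None, m=2, tol=0.3)

    def test_monotone_series_with_tiny_tolerance_has_no_matches(self):
        x = np.arange(15, dtype=float)
        c = count_matches(x, None, SampEnParams(m=2, r=0.4, tolerance_mode=ABS), 0.4)
        assert (c.cm, c.cm1) == (0, 0)

    def test_no_valid_templates_raises(self):
        censor = np.ones(10, bool)
        censor[[2, 5]] = False
        with pytest.raises(UndefinedCountsError):
            count_matches(np.arange(10.0), censor, SampEnParams(m=2), 1.0)

    def test_blocked_path_matches_direct_path(self, rng):
        # a series long enough to span several row blocks
        from sampenmap import sampen_core

        x = rng.normal(size=1200)
        p = SampEnParams(m=2, r=0.2, tolerance_mode=ABS)
        c_big = count_matches(x, None, p, 0.2)
        old = sampen_core._ROW_BLOCK
        try:
            sampen_core._ROW_BLOCK = 97
            c_small = count_matches(x, None, p, 0.2)
        finally:
            sampen_core._ROW_BLOCK = old
        assert c_big == c_small

    def test_invariants_on_counts(self):
        with pytest.raises(ValueError):
            MatchCounts(cm=1, cm1=2, k_b=0, k_a=0, n_templates=5)


@settings(max_examples=120, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), m=st.integers(1, 3), censored=st.booleans())
def test_counts_equal_brute_force_on_random_series(seed, m, censored):
    rng = np.random.default_rng(seed)
    x, censor = random_series(rng, censored=censored)
    tol = float(rng.uniform(0.05, 1.5))
    try:
        assert_counts_match_oracle(x, censor if censored else None, m, tol)
    except UndefinedCountsError:
        cm, *_rest, n_t = brute_sampen_counts(x, censor if censored else None, m, tol)
        assert n_t == 0


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), m=st.integers(1, 3))
def test_match_sets_nest_as_r_grows(seed, m):
    """Increasing the tolerance never decreases Cm or Cm1."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=25)
    prev = None
    for tol in (0.1, 0.3, 0.6, 1.2):
        c = count_matches(x, None, SampEnParams(m=m, r=tol, tolerance_mode=ABS), tol)
        if prev is not None:
            assert c.cm >= prev.cm and c.cm1 >= prev.cm1
        prev = c


class TestSampen:
    def test_periodic_series_has_zero_entropy(self):
        x = np.array([1.0, 3.0] * 6)
        p = SampEnParams(m=2, r=0.5, tolerance_mode=ABS)
        assert sampen(x, None, p) == 0.0

    def test_nonnegative_whenever_defined(self, rng):
        for _ in range(30):
            x = rng.normal(size=40)
            v = sampen(x, None, SampEnParams(m=1, r=0.5, tolerance_mode=ABS))
            assert np.isnan(v) or v >= 0.0

    def test_undefined_emits_sentinel_and_warning(self):
        x = np.arange(15, dtype=float)
        with pytest.warns(UndefinedSampEnWarning, match="not mathematically defined"):
            v = sampen(x, None, SampEnParams(m=2, r=0.01, tolerance_mode=ABS))
        assert np.isnan(v)

    def test_all_false_mask_equals_no_mask(self, rng):
        x = rng.normal(size=60)
        p = SampEnParams(m=2, r=0.3)
        assert sampen(x, np.zeros(60, bool), p) == sampen(x, None, p)

    def test_iid_gaussian_closed_form_small(self, rng):
        from scipy.stats import norm

        x = rng.normal(size=3000)
        v = sampen(x, None, SampEnParams(m=2, r=0.2, tolerance_mode=ABS))
        expected = -np.log(2 * norm.cdf(0.2 / np.sqrt(2)) - 1)
        assert v == pytest.approx(expected, abs=0.08)


class TestSampenMap:
    def test_periodic_row_less_complex_than_noise_row(self, rng):
        periodic = np.tile([0.0, 1.0], 100)
        noise = rng.normal(size=200)
        bold = BoldMatrix(np.vstack([periodic, noise]))
        res = sampen_map(bold, SampEnParams(m=2, r=0.3))
        assert res.entropy[0] < res.entropy[1]

    def test_single_row_reduces_to_sampen(self, rng):
        x = rng.normal(size=80)
        bold = BoldMatrix(x[None, :])
        p = SampEnParams(m=2, r=0.3)
        res = sampen_map(bold, p)
        assert res.entropy[0] == sampen(x, None, p)
        assert res.n_effective == 80

    def test_row_permutation_equivariance(self, rng):
        data = rng.normal(size=(5, 70))
        perm = np.array([3, 0, 4, 1, 2])
        p = SampEnParams(m=1, r=0.4)
        res = sampen_map(BoldMatrix(data), p)
        res_perm = sampen_map(BoldMatrix(data[perm]), p)
        assert np.array_equal(res_perm.entropy, res.entropy[perm])

    def test_degenerate_row_gets_sentinel_not_failure(self, rng):
        data = np.vstack([np.ones(50), rng.normal(size=50)])
        res = sampen_map(BoldMatrix(data), SampEnParams(m=2, r=0.3))
        assert np.isnan(res.entropy[0]) and np.isfinite(res.entropy[1])
        assert res.counts[0] is None and res.counts[1] is not None
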