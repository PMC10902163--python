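# Methods

This note documents the models and procedures implemented in `sampenmap`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish.

## Sample entropy

For a series `x` of length `N`, template length `m` and tolerance `tol`,
templates of length `m` and `m+1` are both enumerated from the common set
of start positions `i` such that volumes `i..i+m` are all uncensored (the
Richman–Moorman boundary convention, which guarantees `Cm1 <= Cm` and hence
`SampEn >= 0`).  An ordered pair `(i, j)`, `i != j`, is an *m*-match when
the Chebyshev (maximum coordinate-wise) distance of the first `m`
coordinates is `<= tol` (inclusive), and an *(m+1)*-match when the last
coordinates also agree within `tol`.  Matches are counted over ordered
pairs (each unordered pair twice); SampEn depends only on the ratio
`Cm1/Cm`, so this choice is immaterial but is fixed so that the brute-force
test oracle and the implementation count identically.

**Censoring.**  A censored volume (window separator, high-motion or
interpolated volume) invalidates every template that contains it; nothing
else changes.  This is the screening-condition approach for missing data in
physiological series: the retained data are never modified, and a property
test verifies that counts on a concatenated-with-separator series equal an
oracle that enumerates templates inside each window separately while still
pairing templates across windows.

**Tolerance.**  In the standard relative mode, `tol = r * SD` where the SD
(sample standard deviation, `ddof=1`) is computed per grayordinate from the
uncensored points of the series actually analyzed — i.e. *after*
windowing, not from the full pre-windowing series.  The motion-inflated SD
of the full series is precisely the distortion the windowing procedure
exists to remove, so it must not leak into the tolerance.  A zero-variance
series has no meaningful tolerance and raises a per-series error, which
`sampen_map` converts to the undefined sentinel for that row.

**Undefined values.**  When `Cm` or `Cm1` is zero, SampEn is not
mathematically defined; the result is NaN (with a structured warning),
written to output maps as a missing value, never as 0.

**Complexity.**  Counting is O(N²·m) with blocked vectorization (block
size 512 rows), which handles N = 5000 series in well under a second and
keeps memory at ~`block × N` floats.

## Low-motion windowing

Inputs: FD threshold (default 0.3 mm; usability is the *strict* inequality
`FD < threshold`), window length L (default 20 volumes), requested window
count K (default 20), and an initial exclusion (default 10 volumes) dropped
from the start of every run.  Within each run, every maximal stretch of
consecutive usable volumes is greedily packed with L-length windows
anchored at the stretch's first usable volume; remainders shorter than L
are discarded.  Windows never cross a run boundary (an FD value is not
even defined at a run's first volume, and signal continuity across runs is
not assumable).  If more than K candidates exist, the windows with the
highest mean FD are dropped; the sort is stable, so among ties the
temporally earlier window survives — determinism was the priority, the
choice is otherwise arbitrary.

Selected windows are concatenated in temporal order with exactly one
censored separator volume between consecutive windows, *including*
adjoining ones, so every subject's concatenated series has identical length
`K·L + (K-1)` and censoring structure.  Separator columns carry a
placeholder value (0.0); the censor mask, never the value, governs
downstream behaviour.  Subjects with fewer than K candidates are excluded
with a structured error — comparable window counts across subjects is the
point of the procedure, so partial results are not produced.

Indexing is 0-based half-open internally; all user-facing reports
(provenance records, window displays) are 1-based inclusive.

## Parameter selection

**Template length m.**  Each contiguous uncensored segment of each
grayordinate series is fit with AR(0..p_max) by conditional maximum
likelihood (least squares with an intercept), holding back `p_max` initial
values so every order is scored on the same sample;
`AIC = -2 loglik + 2 (order + 2)`, counting intercept and innovation
variance.  Fitting never crosses a censored separator or run boundary (AR
likelihoods assume contiguity).  The searched order is additionally capped
at a third of the segment length so a 20-volume window cannot support a
10-parameter model; segments too short to fit are skipped and counted.
The suggestion is the modal selected order across segments, series and
subjects, ties broken toward the smaller order (more templates, cheaper
matching), clamped to >= 1 (white-noise data select order 0, but SampEn
needs `m >= 1`).

**Tolerance r.**  For candidate `(m, r)` cells the error criterion is
`max(σ_CP/CP, σ_CP/(-CP·ln CP))` — the larger of the relative errors of
the CP and SampEn estimates — with

```
σ²_CP = CP(1-CP)/Cm + (K_A - K_B·CP²) / Cm²
```

floored at zero.  `K_B` and `K_A` count the matching ordered pairs whose
two template index ranges share a time index (at lengths m and m+1
respectively); they capture the first-order effect of overlapping-template
correlation on the estimator variance.  The brute-force enumeration in the
test suite is the normative definition of these counts.  The criterion is
`+inf` when CP is 0 or 1 (at CP = 1, `-ln CP = 0` and SampEn's relative
error diverges — tolerances at which *every* m-match extends are useless),
and NaN for degenerate series; infinities sort last, so argmin semantics
stay total.  Aggregation is median across grayordinates within subject,
then the across-subject distribution per cell; the default grids are
`m ∈ {suggested-1, suggested, suggested+1} ∩ [1, ∞)` and
`r ∈ {0.10, 0.15, …, 0.60}`.  Parallelism over subjects (joblib) never
changes results.

The criterion has an interior minimum in `r` only when the signal is
smooth enough for CP to approach 1 within the grid: for strongly
autocorrelated AR(2) fixtures (companion roots 0.9 and 0.8, emulating the
smoothness of bandpassed BOLD) the minimum sits strictly inside
[0.10, 0.60], whereas for rough signals the criterion decreases
monotonically over that range.  The tool recommends one global `(m, r)`
pair; the per-region grids are exposed but region-specific application is
left to the user.

## Prefiltering

Optional and off by default (upstream preprocessing pipelines usually
filter already).  Volumes with `FD >=` an interpolation threshold (default
0.2 mm) are replaced by linear interpolation between the nearest clean
neighbours within the run (edge volumes take the nearest clean value) and
are marked censored, so windows and entropy can never include fabricated
data.  Linear interpolation is the minimal choice; since interpolated
volumes are excluded from analysis anyway, the interpolation method only
affects what leaks through the filter.  The bandpass is a zero-phase
(forward-backward) Butterworth, order 2 per pass, default band
0.009–0.25 Hz at TR 0.8 s, applied per run per grayordinate after
demeaning and symmetric zero-padding (default pad: one impulse-response
length, computed from the designed filter as the last sample above 1e-3 of
the peak response); the mean is restored afterwards.  Filtering never
crosses run boundaries.  Property tests verify ~unit passband gain at
0.05 Hz, >= 90% stopband attenuation at 0.4 Hz, and that
interpolate-then-filter output is closer (RMSE) to the spike-free ground
truth than filter-only output at volumes >= 10 TRs from a spike.

## Reliability

`ICC(1,1) = σ²α/(σ²α + σ²e)` from the one-way random-intercept model,
estimated per grayordinate by REML (statsmodels MixedLM).  On balanced
data the REML solution coincides with the truncated one-way ANOVA moment
estimator, which the test suite keeps as an independent oracle; the moment
estimator also serves as a fallback if REML fails to converge.  Negative
variance solutions truncate at zero (ICC 0); a zero-total-variance 0/0
case returns the NaN sentinel; exact zero within-subject variance
(duplicated measurements) is detected analytically and returns ICC 1
without invoking an optimizer at a boundary.  Per grayordinate, subjects
with an undefined-entropy sentinel in either measurement are skipped
(pairwise exclusion); fewer than two usable subjects yields the sentinel.
Region summaries report min, max, median, Q1, Q3 of the defined values.

## Synthetic data

The generator emulates what the pipeline needs to see, not real
hemodynamics.  Per grayordinate it simulates a stationary AR process
(default AR(2) with coefficients (0.5, -0.3); non-stationary coefficient
groups are rejected by a companion-matrix spectral-radius check) with
Gaussian innovations (default SD 1.0), independently per run with a
200-sample burn-in.  Defaults mirror a two-run acquisition of 375 volumes
at TR 0.8 s.  FD sits at a constant baseline (0.1 mm) except at spiked
volumes: the number of high-motion events per run is Poisson (default mean
5), spiked volumes get FD = `spike_fd` (default 1.0 mm) and every
grayordinate receives a coherent additive amplitude offset of
`4 · noise_sd · spike_fd` with a random sign per event — a minimal
mechanism by which motion corrupts signal, sufficient to reproduce the
full-vs-windowed bias contrast.  The ICC fixture draws from the two-level
model directly (default σα = σe = 1, grand mean 1.0).

Because the fixtures contain no physiological noise spectra, spatial
smoothness, or realistic artifact shapes, passing tests establish the
*algorithmic* properties (exact counting, censoring correctness, recovery
of known generating parameters, bias removal under the stated artifact
model) — not performance on any real dataset.

## Problem sizes and tolerances in the test suite

Oracle equivalence uses 1000 randomized series of length <= 30 (exact
equality).  The iid Gaussian closed-form check uses N = 5000 at
`r = 0.2` (absolute tolerance mode against unit-variance noise) within 3
Monte-Carlo standard errors estimated from 6 replicate draws.  AR-order
recovery uses 50 ensembles of six AR(2) series of N = 400; ICC recovery
uses 20 draws of 500 subjects x 2 repeats (mean within 0.05 of the true
0.5).  The motion-bias cohort has 200 subjects with spike rates graded
0 to 12 events/run; the expected contrast is a full-mode entropy-motion
correlation <= -0.5 and a windowed-mode correlation within +/- 0.1 of
zero.  These sizes keep the whole suite around a minute on one CPU.

## Known limitations

* Window length/count defaults (20 x 20) trade entropy precision against
  subject retention and are not optimized per dataset.
* `σ²_CP` uses pair-level overlap counts as the correlation correction;
  it is a first-order approximation and is validated against the test
  oracle's enumeration, not against an exact estimator variance.
* One global `(m, r)` is recommended; individual- or region-specific
  parameters are unexplored territory exposed through the grid output.
* FD is assumed precomputed; DVARS or other outlier criteria are not
  supported.
* NIfTI volumes and GIFTI surfaces are out of scope; CIFTI-2 and TSV are
  the only dialects.
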