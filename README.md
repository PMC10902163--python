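# sampenmap

Motion-robust **sample entropy (SampEn) mapping** for resting-state fMRI.

Sample entropy measures the unpredictability of a signal: with `Cm` the
number of template pairs of length *m* that match within a tolerance (under
the Chebyshev distance, excluding self-matches) and `Cm1` the number that
still match when extended to *m* + 1 points,

```
SampEn = -ln(Cm1 / Cm)
```

Low SampEn means a regular, predictable signal; high SampEn means a complex
one.  Applied per grayordinate (cortical surface vertex or subcortical
voxel) of a BOLD dense time series, SampEn yields a whole-brain complexity
map — but two practical problems get in the way:

1. **Head motion.**  Motion events distort the series shape *and* inflate
   its standard deviation, hence the match tolerance `r × SD`, biasing
   SampEn downward for high-motion subjects.  Conventional scrubbing
   censors different numbers of volumes per subject, which itself biases
   SampEn.
2. **Parameter choice.**  The template length *m* and tolerance factor *r*
   should be derived from the data at hand, not copied from prior
   literature.

`sampenmap` addresses both:

* **Flexible low-motion windowing** — search each run for stretches of
  consecutive volumes with framewise displacement (FD) strictly below a
  threshold, greedily pack fixed-length windows into them (no fixed
  indices), keep the K windows with the lowest mean FD, and concatenate
  them with one censored separator volume between windows.  Every subject
  then contributes the same number of volumes and censored points.
* **Censoring-aware SampEn** — template matching simply skips templates
  that contain a censored volume, so separators and high-motion volumes
  are ignored without altering the retained data.
* **Parameter selection** — `select_m` fits autoregressive models
  (order chosen by AIC) to suggest *m*; `search_mr_grid` scans candidate
  (*m*, *r*) pairs with an error criterion based on the variance of the
  conditional probability CP = Cm1/Cm, minimizing the maximum relative
  error of the CP and SampEn estimates.
* **Prefiltering (optional)** — linear interpolation of high-motion volumes
  followed by a zero-phase Butterworth bandpass, preventing motion spikes
  from leaking into clean volumes; interpolated volumes are censored and
  never analyzed.
* **Reliability** — grayordinate-wise intraclass correlation
  `ICC(1,1) = σ²α / (σ²α + σ²e)` from the one-way random-effects model
  `y_ij = μ + α_i + e_ij`, estimated by REML, for test–retest comparisons
  of repeated entropy maps.
* **I/O** — CIFTI-2 `.dtseries.nii` / `.ptseries.nii` in, `.dscalar.nii` /
  `.pscalar.nii` out (via nibabel), plus a plain TSV dialect and YAML/JSON
  run manifests so everything is testable without imaging data.

## Worked example

A synthetic two-run subject (375 volumes/run, AR(2) BOLD signals, ~8
high-motion spikes per run that corrupt the signal at the spiked volumes):

```python
import numpy as np
from sampenmap import (SyntheticSpec, generate_bold, WindowConfig, SampEnParams,
                       windowed_entropy, full_entropy, mean_fd)

spec = SyntheticSpec(n_grayordinates=4, n_volumes_per_run=375, n_runs=2,
                     spike_rate=8.0, seed=42)
bold, trace = generate_bold(spec)
wcfg = WindowConfig(fd_threshold=0.3, window_length=20, n_windows=20,
                    initial_exclusion=10)
params = SampEnParams(m=2, r=0.3)

windowed, windows = windowed_entropy(bold, trace, wcfg, params)
full = full_entropy(bold, trace, wcfg, params)

print(f"mean FD (post-exclusion): {mean_fd(trace, wcfg.initial_exclusion):.3f} mm")
print(f"windows selected: {len(windows)}; first: {windows.windows[0].display()}")
print("windowed SampEn per grayordinate:", np.round(windowed.entropy, 3))
print("full-series SampEn per grayordinate:", np.round(full.entropy, 3))
```

Output:

```
mean FD (post-exclusion): 0.117 mm
windows selected: 20; first: run 1: volumes 44-63
windowed SampEn per grayordinate: [1.615 1.634 1.619 1.697]
full-series SampEn per grayordinate: [1.596 1.562 1.603 1.574]
```

The windowed estimates are computed from 20 windows x 20 low-motion
volumes (419 volumes including the 19 censored separators); the
full-series estimates use every volume after the initial exclusion and sit
systematically lower — the motion artifacts inflate the tolerance and make
the signal look more "predictable" than it is.  Across a cohort with graded
motion this becomes a strong negative correlation between full-mode SampEn
and mean FD, which the windowed mode removes (see the acceptance script).

A command-line interface mirrors the library
(`sampenmap entropy | select-params | icc | simulate | motion-check`):

```sh
sampenmap simulate --out sub01 --seed 7
sampenmap entropy --input sub01/manifest.yaml --m 2 --r 0.3 \
    --output sub01_entropy.tsv --provenance sub01_prov.json
```

Subjects with fewer usable windows than requested exit with status 3
("excluded"), distinct from failures.

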