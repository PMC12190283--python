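# Methods

Modelling assumptions, parameter defaults and numerical choices, in the
order the pipeline runs.

## 1. Synthetic cohort (`eegmfe.cohort`)

The generator produces the *statistical structure* a two-group, two-site
EEG complexity study assumes — it makes no claim of physiological realism.

**Dynamics.** Healthy subjects (HS) are per-channel stationary AR(1)
processes with lag-1 coefficient 0.7 (band-limited noise). Patients (AD)
add a unit-weight slow AR(1) component with coefficient 0.95. A channel-
shared component (weight 0.5) with the same group dynamics induces
inter-channel correlation, plus white sensor noise (SD 0.2). Every channel
is standardized to unit SD before gains are applied, so *all* amplitude
structure comes from the gain model.

*Why these coefficients.* The design goal is the canonical complexity
signature: the HS entropy-versus-scale curve rises and then falls, the AD
curve keeps rising, and the groups separate at long scales (17–20) with the
AD group higher. A much slower component (e.g. AR coefficient 0.99 or a
random walk) fails to produce this: after coarse-graining it is too
predictable, and its extra scale-1 variance inflates the tolerance
`r = 0.2 × SD`, pushing AD *below* HS at every scale — the opposite of the
intended structure. The 0.7/0.95 pair was calibrated once, before any
evaluation code existed, and frozen; at these defaults the gain-free
long-scale group separation is Cohen's d ≈ 5 at scale 20.

**Gains (the confound).** Each recording is multiplied by
`dataset_gain × subject_gain × channel_gain`: dataset (site) gains default
to A = 1.0 and B = 3.0, with 35/52 of each group drawn from site A;
subject gains are log-normal with σ = 0.5; channel gains default to 1.
Gains are drawn from a dedicated child RNG stream, independent of the
dynamics stream, and are applied identically regardless of group label —
amplitude is a *pure* confound, carrying no diagnostic information.

**Reproducibility.** Subject `i` of group `g` derives its RNG from
`SeedSequence([seed, g, i])`, so enlarging the cohort or reordering the
generation loop never changes an existing subject's data.

**Scope and limits.** No 1/f spectrum, no oscillatory peaks, no artifacts,
no non-stationarity, only two sites and a multiplicative (not additive or
frequency-dependent) gain model. These are deliberate: the object under
study is the amplitude sensitivity of the entropy statistic, and every
omitted ingredient would confound that question rather than sharpen it.

## 2. Preprocessing (`eegmfe.preprocess`)

* Polyphase resampling to 200 Hz via an exact rational ratio (denominator
  ≤ 1000, logged if approximated), Kaiser anti-aliasing FIR with cutoff at
  0.9× and transition width 0.2× the limiting Nyquist frequency, 60 dB
  stopband.
* Causal Hamming windowed-sinc band-pass 0.5–45 Hz whose order equals the
  sample count of a 3 s window (601 taps at 200 Hz); the first 3 s of
  output are discarded so the filter transient never reaches the features.
  With this fixed order the transition band (≈1.1 Hz) straddles DC, so the
  DC gain is ≈2%, not zero; tests assert the exact frequency-response
  value rather than an arbitrary bound.
* 51 s recordings become 48 s after the trim → 16 non-overlapping 3 s
  epochs of 600 samples. Epoching is separate from filtering because the
  amplitude transforms are fitted on the *continuous* filtered recording.
* An `artifact_hook` slot accepts any `Recording -> Recording` cleaner;
  default is the identity (synthetic data contain no artifacts).

## 3. Amplitude transforms (`eegmfe.transforms`)

Min-max parameters are robust: `x_min`/`x_max` are the *medians* of
per-3 s-window minima/maxima (per channel for `single_norm`; pooled over
all channels for `global_norm`), mapped affinely to [−5, +5] without
clipping, so individual extreme windows cannot dominate the fit.
Standardization uses sample SD (ddof = 1). All four maps are
positive-slope affine per channel and therefore preserve inter-channel
Pearson correlations exactly; the global variants additionally preserve
between-channel amplitude ratios and are invariant to any per-subject
multiplicative gain.

Numerical note: the min-max map computes the ratio
`(x − x_min)/(x_max − x_min)` *before* scaling, so a sample exactly equal
to the fitted maximum maps to exactly +5.0 in IEEE arithmetic.

## 4. Entropy (`eegmfe.entropy`)

Fuzzy entropy with embedding `m = 2`, fuzziness exponent `n = 2`,
Chebyshev distance between *mean-subtracted* templates, `N − m` templates
in both dimensions, membership `exp(−dⁿ/r)`. This membership form is the
crux: because `d` scales with the signal while `r` is fixed from the
scale-1 SD, a gain change moves the entropy value (the confound the study
targets). The alternative form `exp(−(d/r)ⁿ)` (gain-invariant when `r`
tracks the SD) is available via `MFEParams(membership=...)` for contrast.

Tolerance convention: `r = 0.2 × SD(scale-1 series)`, reused at every
scale (`r_convention="fixed_from_scale1"`, the default; `"per_scale"` is
available). A practical consequence: scale-`τ` entropy does not depend on
any other scale's series, so classification features (mean over scales
17–20) can be computed with `MFEParams(scales=(17, 18, 19, 20))` alone —
identical values at a fraction of the cost.

The O(N²) template-pair kernel is a numba `@njit` function computing both
`φ^m` and `φ^{m+1}` in one symmetric pass; correctness is pinned to a
deliberately naive pure-Python double-loop oracle (1e-10) and to frozen
cross-check values computed with an independent reference implementation.

## 5. Classification (`eegmfe.classify`)

* Subject-level split stratified by (group, dataset); epochs of one
  subject never cross the train/test boundary. Default test fraction
  30/104.
* Model selection is leave-one-subject-out over an explicit,
  declaration-ordered hyperparameter grid (SVM-RBF, random forest, KNN).
  Z-scoring moments are computed on the retained subjects of each fold
  only. The selection score is validation accuracy pooled over held-out
  *observations*; ties break to the earliest grid point. The loop is
  explicit rather than `GridSearchCV` because sklearn's parameter grid
  sorts keys and would silently change the tie-break order.
* Reported metrics: per-subject accuracy; their mean with expanded
  uncertainty `k·SD/√N` (coverage factor k = 2, ≈95%); Matthews
  correlation coefficient pooled over all test observations (0 when a
  confusion marginal is empty). The disease group is the positive class.
* One split plan is shared across all conditions and classifiers so
  per-condition accuracies are paired subject-by-subject.

## 6. Statistics (`eegmfe.stats`)

* Subjects, not epochs, are the unit of analysis: each subject's epochs
  are averaged before any test.
* Welch t-tests per (channel, scale) cell, Benjamini–Hochberg FDR over
  the whole 19 × 20 grid, Cohen's d with pooled (N−1) variance; cells
  constant in both groups yield NaN and are excluded from correction.
* Mixed ANOVA: two between factors (group, dataset) and one within factor
  (scale) on channel-averaged entropy, computed in its two error strata
  with type-III (drop-term) sums of squares — between effects on subject
  means, within effects with subject dummies absorbing between-subject
  variation — and Greenhouse–Geisser correction of all Scale-involving
  p-values (ε from the pooled within-cell covariance). Implemented
  directly on design matrices because no installed package handles two
  between factors; validated against pingouin on single-between designs.
* Paired one-tailed t-test for "condition beats reference" on per-subject
  accuracies, with explicit handling of degenerate zero-variance
  differences (p = 0, 0.5 or 1 by sign).
* Correlation preservation: subject-averaged inter-channel Pearson
  matrices per condition; affine transforms must reproduce the reference
  matrix to numerical precision.

## 7. I/O (`eegmfe.io`)

Default on-disk format is a TSV matrix (channels × samples) with a JSON
sidecar (rate, channel names, labels) — lossless and diff-able. A minimal
16-bit EDF writer (1 s records, symmetric physical range rounded to its
8-character header rendering so digital→physical scaling is exactly
invertible) is included; EDF reading goes through MNE's parser, so every
round-trip doubles as an independent check of the writer. Cohorts are
directories with a `manifest.csv`.

## 8. Problem sizes

Defaults mirror a realistic study scale chosen for this package: 52
subjects/group, 19-channel 10–20 montage, 51 s at 200 Hz → 1664
observations, 74/30 subject split → 1184/480 observations. Desk-scale
runs (the `analysis/` scripts with `--subjects-per-group 10..40` and
`--reduced-grid`) complete in seconds to a few minutes on one CPU.

## 9. Limitations

* The generator's AR-based dynamics are a minimal surrogate; effect sizes
  (d ≈ 5 at long scales, gain-free) are far larger than clinical EEG, so
  absolute accuracies here do not transfer — only the *contrast between
  amplitude conditions* is the object of study.
* The mixed ANOVA assumes complete panels (every subject at every scale)
  and ≥2 subjects per (group, dataset) cell, and uses a single pooled
  Greenhouse–Geisser ε.
* The EDF writer covers the subset of the format this pipeline needs
  (identical rates across channels, integer-second records); it is not a
  general-purpose EDF library.
* Single-threaded by design; the numba kernel is the only optimization.
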