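# Methods

This note records the models, conventions and design decisions behind
`redstartcalls`, in the order the pipeline runs them.

## Synthetic call model

A call is a frequency-modulated sinusoid: the instantaneous frequency
contour f(t) is piecewise-linear between a variant template's breakpoints
(relative time ∈ [0, 1] × frequency in Hz), smoothed by convolution with a
raised-cosine kernel whose half-width is the template's
`inflection_sharpness` (a fraction of call duration), with a sinusoidal
frequency modulation (default depth up to 450 Hz, rate ≈ 1 kHz, per
template) ramped in over the final `tail_fraction` of the call.  The
waveform is `sin(2π ∫f dt)` under a Tukey (α = 0.25) amplitude envelope,
padded with 5 ms of silence on both ends, plus white Gaussian noise at a
configurable SNR (default 20 dB); the peak amplitude is kept ≤ 1.

Five templates (A, G, M, S, V) encode the qualitative contour shapes of
redstart-type flight calls: A is the typical fall–inflect–rise "tick
mark" with a modulated tail; G has an acute convex then shallow obtuse
inflection; M alternates convex–concave–convex; S has an obtuse concave
middle inflection and ends lower than it starts; V has an acute concave
inflection with the minimum at mid-call.  The breakpoint tables are
versioned calibration constants of this package — the source material for
such shapes is qualitative, so the templates are assumptions, not
measurements.

**Latent population structure.**  Each bird carries additive offsets on
duration, frequency, tail-modulation depth and rate, drawn from centered
normals with between-bird SDs (defaults 6 ms, 280 Hz, 90 Hz, 130 Hz) that
exceed the corresponding within-bird SDs (3 ms, 70 Hz, 30 Hz, 40 Hz) —
this is what makes calls individually recognisable.  Sex enters three
ways: mean duration 72 ms (M) vs 66 ms (F) (all durations clipped to
38–95 ms), a +400 Hz female frequency offset (females' calls sit higher
and narrower in frequency), and per-sex variant propensities taken from
the observed sex-by-variant call proportions (males: A .571, M .086,
S .014, V .329; females: A .318, G .064, S .255, V .364).  Age affects
nothing, by design.  Sex and age are assigned at the exact rounded quota
of the configured ratios (so the default 36-bird population is 14 M / 22 F
and 25 HY / 11 AHY), in seeded random order.  Variant identity is drawn
per call from the bird's propensity (treated as behavioural rather than
fixed anatomy; the alternative — one variant per bird — is a config away
via a degenerate propensity).

The within/between-bird variance ratios and sex effect sizes are not
field-measured quantities; they are calibrated once so that the full
pipeline at the 36-bird design recovers a clear sex effect and no age
effect, and they are documented here as calibration assumptions.

**What the generator does not emulate:** syrinx physiology, atmospheric
propagation and reverberation, heterospecific or overlapping calls,
recording-chain colour, and non-Gaussian ambient noise.  Passing tests on
synthetic data therefore demonstrate the correctness and calibration of
the *analysis*, not properties of any real population.

## Spectrograms and features

Spectrograms use a 256-point FFT with 256-sample Hann windows advancing 38
samples; trailing samples that do not fill a window are dropped, the body
is never zero-padded, and no window-gain correction is applied (downstream
measurements are relative, so absolute calibration is irrelevant).
Padding is converted to samples by nearest-sample rounding, half away from
zero (5 ms @ 44.1 kHz → 221 samples).

The 95-entry feature registry (`redstartcalls.features.DEFAULT_SPEC`) is
the normative definition of every measurement; the families are described
in the module docstring.  Conventions worth recording:

- Percentile locations interpolate linearly within bins of the cumulative
  energy, so a rectangular envelope of length T has 90% duration 0.9·T
  exactly (up to one hop).
- Contour spread is the inter-quartile range of the per-frame peak
  frequency over the 90%-energy time span; inflection count is the number
  of sign changes of the 3-frame-smoothed first difference.
- Correlation-envelope "median" is the area-median lag of the non-negative
  normalized autocorrelation (chosen over the first half-max crossing for
  robustness to ripple); "halfwidth" is the interpolated first crossing of
  r = ½.
- Three features (`total_energy`, `mean_power`, `peak_power`) scale with
  the square of waveform amplitude and are flagged `scale_dependent`; all
  others are amplitude-invariant.
- Deliberate near-duplicates exist in the registry (e.g. `t_center` vs
  `t_pct_50`), mirroring how overlapping measurement suites behave; the
  pruning stage removes them.
- No background-noise floor is subtracted (clips are short and
  SNR-controlled); a spectral-floor option exists but is off by default.

**Pruning** visits feature pairs in descending |Pearson r|; for each pair
at or above the threshold (default 0.95) whose members both survive, the
member with the larger mean |r| to the other surviving features is
removed (ties break toward the later registry column).  Constant columns
are removed first.  The removal report makes the surviving count
auditable; on synthetic populations ~50 features survive (synthetic calls
are more mutually correlated than field data, where a comparable suite
retains ~84).

**Subset consistency** compares a per-bird subsample against the
*complement* of the full table (comparing against the full table itself
would double-count shared rows and be badly conservative), feature-wise by
Welch t with a Fisher omnibus (−2Σlog p ~ χ²₂ₖ) across features, flagging
individual features at the Bonferroni level.

## Random-forest similarity

Unsupervised proximity uses the synthetic-contrast construction: a
contrast class of equal size is drawn by sampling each feature
independently from its empirical marginal, a forest (default 4999 trees,
√p features per split, unlimited depth, bootstrap) separates real from
contrast, and proximity is counted over **all** trees for each pair of
real calls (an OOB-restricted variant is switchable).  The forest learner
is scikit-learn's `RandomForestClassifier`; the contrast construction,
proximity extraction and all aggregation are implemented here.

The within/between comparison uses Welch's t by default and also reports
the pooled-variance test: on 36 + 36 per-bird means the pooled df is 70
while Welch's df is ≈ 69, and published analyses of this design differ on
which was used, so both are carried.  The per-bird "between" mean shares
matrix entries across birds, so the two samples are not strictly
independent; simulation under an exchangeable null shows the Welch test's
size is ≈ 0.05 at this design (36 × 5), which the test suite checks.

## PERMANOVA

Single-factor: the direct sums-of-squares formulas (see the module
docstring), which reduce exactly to classical one-way ANOVA F for
univariate Euclidean data.  Multi-factor: Gower-centered inner-product
matrix G = −½·J·A·J and sequential (Type I) sums of squares via hat
matrices of the growing design, in the order the factors are listed;
interactions are products of dummy blocks; aliased terms (0 df) raise.
p-values use the (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) estimator, so the
smallest attainable p at 999 permutations is 0.001.

**Nesting.**  "Individual nested" is implemented as a permutation scheme,
not a model term: factors constant within every bird (sex, age) are tested
by reassigning bird-level labels across whole birds, holding call-level
factors fixed; call-level factors (variant, and interactions involving
them) use free permutation of calls.  Free permutation of a bird-level
factor in the presence of within-bird correlation is anti-conservative —
the test suite demonstrates the inflation and the block scheme's nominal
size.  The alternative (free permutation throughout) remains available via
`permute_blocks=False`.

**Distances.**  Default Euclidean on z-scored features: the classical
ecological default dissimilarity (Bray–Curtis) is undefined for
negative-valued acoustic measurements, and the features mix units (ms, Hz,
bits), so z-scoring is required for exchangeability across features.  The
metric and standardization are recorded in every result; Manhattan and
Bray–Curtis (on non-negative data) are available.  Published pseudo-F
values from comparable real-data analyses depend on an unstated metric
choice, so small discrepancies are expected and no exact real-data F is
targeted.

## Ordination

PCoA eigendecomposes G; coordinates are eigenvectors scaled by √λ; axes
with λ ≤ 0 are excluded from coordinates but reported (1 − RF-proximity is
generally non-Euclidean).  NMDS minimizes Kruskal stress-1 via
scikit-learn's non-metric MDS (monotone regression, precomputed
dissimilarities, normalized stress), taking the best of 20 seeded restarts
by default.  Confidence ellipses are **standard-error-of-the-mean**
ellipses: group score covariance divided by n, scaled by χ²₂(level) —
centroid uncertainty, not data spread.  The similarity heatmap orders
calls by bird with separator lines between individuals, darker = more
similar.

## Problem sizes and seeds

The acceptance script runs the full design: 36 birds × 5 calls, 95 → ~50
features, 999 permutations, 4999 trees, 10 NMDS restarts.  Replicated
checks in the test suite use the same study design with lighter machinery
chosen to keep statistical power at ordinary desk runtimes: 300-tree
forests and 199 permutations for the 100-replicate pattern-recovery check,
100-tree forests for the 200-replicate null calibration, and n = 20
datasets for the 1000-replicate PERMANOVA size check.  Every stochastic
step (population sampling, call noise, subsampling, contrast sampling,
permutations, restarts) draws from a seed tree rooted at a single integer,
so identical seeds reproduce identical numbers, including WAV bytes.

## Known limitations

- The feature registry is this package's own fixed definition of an
  Acoustat/robust-measurement-style suite; it is not a bit-for-bit
  reimplementation of any proprietary tool.
- Synthetic variants are more separable than field variants (template
  shapes are exact up to smoothing and noise), so variant-factor effect
  sizes on synthetic data run high.
- The sequential-SS PERMANOVA attributes shared variance to earlier terms;
  results are order-dependent by construction, and the order is recorded.
- Proximities counted over all trees (rather than OOB-only) are slightly
  optimistic for duplicated calls; the OOB variant exists but relies on
  scikit-learn internals.
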