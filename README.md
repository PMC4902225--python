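# redstartcalls

Do the nocturnal flight calls of a migrating songbird carry information
about who is calling?  `redstartcalls` is a Python package for testing
whether short (tens of milliseconds) frequency-modulated flight calls
encode **individual identity** and **sex**, built around the analysis
design used for American Redstart (*Setophaga ruticilla*) calls: spectrogram
energy-distribution measurements, unsupervised random-forest call
similarity, permutational MANOVA, and ordination.  Because raw field
recordings of this kind are rarely public, the package includes a
first-class synthetic-call generator with known latent structure, so the
entire analysis chain is testable end to end.

It is aimed at bioacousticians and quantitative ecologists who want a
reproducible, scriptable version of this workflow — or a calibrated test
bed for their own similarity statistics.

## The analysis

1. **Calls.** Mono 44.1 kHz WAV clips of single calls (optionally clipped
   out of longer recordings via Raven-style selection tables, with 5 ms of
   padding).  The generator emulates five qualitative contour variants
   (A, G, M, S, V), per-bird parameter offsets larger than within-bird
   variation, a 72 vs 66 ms male/female duration difference, per-sex
   variant propensities, call frequencies within 3.5–10.3 kHz, and no age
   effect.
2. **Features.** Each call's power spectrogram (256-point FFT, 256-sample
   Hann window, 38-sample hop) is reduced to 95 named measurements of the
   marginal energy distributions e(t) = Σ_f P(t,f), s(f) = Σ_t P(t,f) and
   m(f) = Σ_t √P(t,f): cumulative-energy percentiles and the derived
   durations/bandwidths (e.g. 90% duration = t₉₅ − t₅), concentrations,
   half-maximum modewidths, Shannon entropies, peak-frequency contour
   statistics, and correlation-envelope summaries.  Features with Pearson
   |r| ≥ 0.95 are pruned; five calls per bird (birds with ≥ 5 calls) enter
   the analysis.
3. **Similarity.** An unsupervised random forest (real calls vs a
   marginal-resampled synthetic contrast, 4999 trees) yields proximities
   prox(i,j) = fraction of trees routing calls *i* and *j* to the same
   terminal node — a similarity matrix in [0, 1].
4. **Statistics.** PERMANOVA pseudo-F
   `F = [SS_among/(a−1)] / [SS_within/(n−a)]` with permutation p-values
   (999 permutations); in the multi-factor design, individual identity is
   the exchangeable unit, so bird-level factors (sex, age) are tested by
   permuting whole birds.  Per bird, the mean of the C(5,2) = 10
   within-bird proximities is compared against the mean of the
   5·5·35 = 875 between-bird entries with a two-sample t-test.
   PCoA and NMDS render the distance structure in 2-D with 99% centroid
   confidence ellipses.

## Worked example

```python
from redstartcalls.pipeline import run_pipeline

summary = run_pipeline(
    {"stats": {"n_trees": 300, "n_perm": 199}, "report": {"ordination": False}},
    seed=7,
)
print(summary["n_calls"], summary["n_features_pruned"])
print({k: round(v["p"], 3) for k, v in summary["permanova"]["terms"].items()
       if v["p"] is not None})
print(round(summary["similarity"]["t_welch"], 2))
```

prints

```
180 53
{'sex': 0.005, 'age': 0.795, 'variant': 0.005, 'sex:variant': 0.09}
6.97
```

i.e. a default 36-bird × 5-call synthetic population yields 180 analysis
calls and 53 surviving features; the nested PERMANOVA finds calls from the
two sexes significantly different (p = 0.005 at 199 permutations) and no
age effect (p = 0.80), and calls from the same bird are far more similar
to each other than to other birds' calls (Welch t = 6.97 on the 36 + 36
per-bird means, p ≈ 10⁻⁸) — the qualitative signature of individual and
sex information in the calls.

The same stages are scriptable from the shell:

```bash
redstartcalls simulate --out data/ --seed 1
redstartcalls features --clips data/ --manifest data/manifest.csv --out feats.csv
redstartcalls prune --in feats.csv --out pruned.csv
redstartcalls run-all --out run1/ --seed 1
```

## Layout

- `redstartcalls.synth` — variant templates, bird profiles, population
  generator (`PopulationConfig`, `generate_dataset`).
- `redstartcalls.audio` — WAV I/O, selection tables, clip extraction,
  spectrograms.
- `redstartcalls.features` — the 95-measurement registry, pruning,
  subsampling, subset-consistency check.
- `redstartcalls.similarity` — `ProximityForest` → similarity matrix,
  within/between t-test, supervised importances.
- `redstartcalls.permanova` — `Permanova` model / `PermanovaResults`
  (single-factor, sequential multi-term, nested permutation).
- `redstartcalls.ordination` — PCoA, NMDS, ellipses, plots.
- `redstartcalls.pipeline` — `run_pipeline` and the report bundle.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical conventions.
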