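# nmrfinger

Urine ¹H NMR metabolic fingerprinting for predicting and monitoring
response to anti-TNF therapy in inflammatory arthritis — and, more
generally, for any two-group urine NMR study that needs spectral binning,
supervised multivariate classification, feature selection and
permutation-tested regression in one reproducible pipeline.

The package is aimed at metabolomics analysts who have 1-D ¹H spectra
(JCAMP-DX or two-column ppm/intensity text) plus a clinical metadata table
and want the complete chain:

1. **Preprocessing** — TMSP calibration (reference peak shifted to 0.0
   ppm), truncation to 0.8–10.0 ppm, integration into 0.005-ppm bins
   (1840 bins), per-sample baseline-offset subtraction, normalization to
   unit total spectral area (removing urine dilution), and the
   generalized log transform g(x) = ln(x + √(x² + λ)).
2. **PLS-DA** — a NIPALS partial least-squares engine fitting latent
   variables that maximize covariance between bins and the ±1-coded
   class, with Venetian-blinds cross-validated sensitivity/specificity,
   ranked weighting peaks, and VIP scores
   (VIP_j = √(p·Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a), so mean VIP² = 1).
3. **Genetic-algorithm bin selection** — GALGO-style searches evolving
   small bin subsets scored by K-fold cross-validated nearest-centroid
   accuracy; bins ranked by selection frequency across searches and
   presented by PCA.
4. **PLS regression** — greedy forward selection of bins against a
   continuous outcome (e.g. the change in DAS28, or CRP /
   albumin-to-creatinine ratio for confounder checks), with a
   selection-inclusive permutation test: the null distribution reruns the
   *entire* pipeline, forward selection included, on outcome-permuted
   data, so selection bias cannot manufacture significance
   (p = (1 + #{r²_null ≥ r²_obs}) / (1 + B)).
5. **Annotation** — tolerance-based chemical-shift lookup of
   discriminating bins against a packaged urine metabolite library, and a
   consensus table of metabolites found by several methods.

Because clinical urine spectra are rarely shareable, the package also
ships a first-class synthetic cohort generator: Lorentzian resonances at
the library shifts with realistic relative abundances, group-dependent
log-fold concentration effects, log-normal urine dilution, baseline
offset and additive noise — with a full ground-truth record, so every
pipeline stage is testable against known truth.

## Worked example

```python
from nmrfinger import (CohortConfig, response_effect_map, simulate_cohort,
                       preprocess_spectra, cross_validate_plsda, fit_pls,
                       top_weighted_peaks, match_bins, default_library)
from nmrfinger.plsda import encode_labels

# 9 non-responders vs 7 responders; the 4-metabolite response signature
# (histamine, glutamine, xanthurenic acid up; ethanolamine down) planted
# at 1.0 log-fold
cfg = CohortConfig(group_sizes=(9, 7),
                   effect_map=response_effect_map(1.0), seed=1)
cohort = simulate_cohort(cfg)
matrix = preprocess_spectra(cohort.spectra)
print(f"feature matrix: {matrix.n_samples} samples x {matrix.n_bins} bins")

cv = cross_validate_plsda(matrix, cohort.labels, k=7, positive_class=0)
print(f"PLS-DA 7-fold CV: sensitivity={cv.sensitivity:.3f} "
      f"specificity={cv.specificity:.3f}")

coded, _ = encode_labels(cohort.labels, 0)
model = fit_pls(matrix, coded, 2)
for ann in match_bins(top_weighted_peaks(model, 5), default_library(), 0.01):
    names = ", ".join(ann.metabolite_names()) or "(unassigned)"
    print(f"  {ann.bin_center:.3f} ppm  {ann.direction:>4s}  {names}")
```

prints

```
feature matrix: 16 samples x 1840 bins
PLS-DA 7-fold CV: sensitivity=1.000 specificity=1.000
  8.008 ppm  down  histamine
  8.012 ppm  down  histamine
  3.278 ppm  down  histamine
  7.998 ppm  down  histamine
  3.743 ppm    up  ethanolamine
```

The cross-validation classifies every sample correctly, and the largest
LV1 weightings fall on histamine and ethanolamine resonances. Directions
are reported relative to the positive class (here the non-responders):
histamine is *lower* and ethanolamine *higher* in non-responders, i.e.
histamine up- and ethanolamine down-regulated in responders — matching
the planted signature.

The same analyses run from the shell: `nmrfinger simulate`, `nmrfinger
preprocess`, `nmrfinger plsda`, `nmrfinger gaselect`, `nmrfinger plsreg`,
`nmrfinger annotate`, and `nmrfinger run` for a full study into a report
directory (see `nmrfinger --help`).

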