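# Methods

This note documents the models, parameter choices and numerical decisions
behind `nmrfinger`, and what the synthetic-data experiments do and do not
demonstrate about real urine NMR data.

## Preprocessing model

A raw spectrum is a strictly monotone ppm axis with intensities. The
analysis-ready matrix is produced in a fixed order, enforced through
stage flags (running a stage after a later one raises):

calibrate → truncate → bin → baseline-correct → normalize → glog → center.

- **Calibration**: the ppm axis is shifted so the maximum within ±0.05
  ppm of the reference position (0.0 ppm, TMSP) lands exactly on the
  reference. In a flat window the leftmost maximum is used — an arbitrary
  but deterministic tie-break.
- **Truncation** to 0.8–10.0 ppm discards the reference and water-edge
  regions. No solvent/urea exclusion windows are applied by default; an
  `exclude` option zeroes configurable ppm regions before normalization.
- **Binning**: half-open 0.005-ppm bins anchored at 0.8 (the last bin is
  closed at 10.0), giving exactly (10.0 − 0.8)/0.005 = 1840 bins. Bin
  values are the trapezoidal integral of the piecewise-linear spectrum
  over the bin, computed from the cumulative integral so the bin values
  telescope exactly to the whole-interval integral. Coverage up to one
  sampling step short of either edge is tolerated (calibration shifts
  the grid off exact multiples). A spectrum sampled coarser than the bin
  width is rejected with the empty bins named.
- **Baseline offset**: the per-sample 1st percentile of bin values is
  subtracted (quantile configurable); residual negatives are clipped to
  zero. The choice of a low quantile as "the offset" is a pragmatic
  reading of constant-offset correction; it is exact when at least 1% of
  bins contain no signal.
- **Normalization** divides each row by its total, so every spectrum has
  unit area. This removes the per-sample urine dilution factor exactly
  (the generator's dilution is a single multiplicative factor, which is
  what total-area normalization assumes).
- **Generalized log**: g(x) = ln(x + √(x² + λ)) with default λ = 1e-8 on
  unit-area data. g(0) = ½ ln λ; for x ≫ √λ, g → ln(2x). λ is exposed in
  configuration and recorded in output sidecars/provenance; 1e-8 places
  the log/linear transition (√λ = 1e-4) below typical occupied-bin values
  (~5e-4), so occupied bins behave logarithmically while near-empty bins
  are not blown up arbitrarily.
- **Centering** subtracts per-column means and stores them; inside any
  cross-validation loop centering statistics are computed on training
  rows only and applied to held-out rows (verified by a perturbation
  test: rescaling a held-out sample by 1e9 does not move predictions of
  other samples in the same fold).

Ordering note: baseline-correction-before-normalization is one of two
defensible orders and is fixed here (and recorded in the stage flags);
the two differ only through the clipping of residual negatives.

## PLS engine

`fit_pls` implements NIPALS PLS1. For component a: w = Xᵀy/‖Xᵀy‖,
t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X ← X − tpᵀ. Weight vectors are
unit-norm, score vectors mutually orthogonal; with as many components as
predictors the fit equals ordinary least squares (tested against the
normal equations, and against scikit-learn's PLSRegression as an
independent implementation). Components are truncated (with a warning)
when the residual carries no covariance with y. Per-component explained
X-variance is (tᵀt)(pᵀp)/‖X₀‖².

PLS-DA codes the two classes ±1 and classifies by the sign of the
predicted response (threshold 0). The coding and threshold are symmetric,
so class orientation only determines which class "sensitivity" refers
to; the positive class defaults to the non-responder group in the
response design and is always recorded in the report.

**Venetian blinds CV**: sample i (input order) goes to fold (i //
block_size) mod k, deterministic, with k = 7 and block_size = 1 by
default. The deterministic interleave is chosen over randomized blocks
for exact reproducibility. Fold models are centered and fitted on
training rows only.

**VIP**: VIP_j = √(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a) with SS_a =
q_a² t_aᵀt_a. The mean squared VIP over bins is identically 1, which the
suite asserts for every fitted model.

**Weighting ranking** uses |LV1 weighting| by default (the component the
standard weighting plot annotates); a multi-component row-norm variant is
available. Sign conventions: positive weighting = elevated in the
positive class.

## Genetic-algorithm bin selection

Chromosomes are sets of `chromosome_length` = 5 distinct bin indices.
Fitness is pooled held-out accuracy of a nearest-centroid classifier
under seeded stratified K-fold (K = 5); stratification guarantees both
classes in every training fold, and K may not exceed the smaller class.
Each of `n_searches` = 100 independent searches runs tournament selection
(size 2) with single-point crossover on the sorted index lists (repaired
to keep genes distinct), per-gene mutation (rate 0.02) to a uniformly
random unused bin, and one elite survivor, stopping at `fitness_goal` =
0.90 or `max_generations` = 200. The best chromosome of each search is a
"solution"; bins are ranked by the number of solutions containing them,
ties broken by mean fitness of the containing solutions, then bin index.
Defaults follow common GALGO practice and are all configurable. A
KNN(k = 3) fitness classifier is available as an option. Selected bins
are presented by PCA (scores + variance fractions) and evaluated by
repeated stratified K-fold nearest-centroid classification (pooled
confusion, mean sensitivity/specificity).

## PLS regression and permutation testing

Forward selection greedily adds the bin maximizing cross-validated r²
(leave-one-out for cohorts ≤ 40 samples, else 7-fold interleaved),
stopping at the budget (default 90 bins) or when CV r² stops improving;
ties go to the lower bin index. The reported r² = 1 − SS_res/SS_tot is
the training goodness-of-fit of the PLS fit on the selected bins
(2 components, truncated to the selected-set rank with a warning).

The permutation test reruns the **whole pipeline — selection included —**
on outcome-permuted data for each of B permutations (default 100), and
reports p = (1 + #{r²_null ≥ r²_obs})/(1 + B), which can never be zero
(minimum 1/(B+1)). A `freeze_selection` variant keeps the observed bin
set in the null; it is demonstrably anti-conservative on null data
(asserted in the suite) and is provided for comparison only. Permuting
the outcome vector (rows of X intact) is the default reading of
"randomizing" the bin–outcome link; a row-permutation variant of X is
exposed and equivalent under exchangeability. The same operation serves
confounder checks (CRP, albumin-to-creatinine ratio) via the
`outcome_name` field. The batched cross-validation core vectorizes
NIPALS across folds (grouped by equal fold size) so the
selection-inclusive null stays tractable.

## Annotation

Bins are matched to the packaged metabolite library within a tolerance
(default 0.01 ppm = two bin widths); all matches within tolerance are
reported, sorted by distance — shift overlap (e.g. 7.15 ppm for both
histamine and xanthurenic acid) is preserved, not resolved. The consensus
table counts, per metabolite, the methods whose annotated top bins
include it; direction (up/down in the positive class) is taken from the
PLS-DA signs, the other two rankings being unsigned.

The library stores the discriminating urine metabolites of the anti-TNF
response setting with their reported resonances pooled across methods;
for the treatment-change metabolites (hippuric acid, lactic acid,
choline, urea, creatine, methylamine) no resonances were reported
alongside, so standard urine shifts (HMDB-consistent: hippurate
3.97/7.55/7.64/7.84, lactate 1.33/4.11, choline 3.20, urea 5.78,
creatine 3.03/3.93, methylamine 2.61) were adopted. Shifts are stored
verbatim (including a 4-decimal 6.8225 entry); matching is always
tolerance-based, so bin-center vs peak-maximum ambiguity is immaterial
at the default tolerance.

## Synthetic cohort generator

Each metabolite contributes a Lorentzian of half-width-at-half-maximum
`linewidth` (default 0.002 ppm ≈ 2 Hz at 500 MHz, a realistic urine line
width) at each of its library shifts, with equal per-shift amplitude
proportional to concentration. The acquisition grid spans −0.2 to 10.2
ppm at `points_per_ppm` = 1000 (five points per 0.005-ppm bin — enough
to integrate a 2-Hz line; one point per bin demonstrably is not). A
uniform baseline offset (range 0.05) and additive Gaussian noise (sd
0.01) are added; the TMSP reference is rendered at fixed concentration
(it is spiked, not diluted).

Per-sample metabolite log-concentrations are Normal(ln(base) + effect ·
group, 0.25); base abundances follow typical relative urinary levels
(urea 15, creatinine 10, citrate/hippurate 4, trace metabolites
0.1–0.6). Realistic abundances matter: with flat abundances, a planted
fold-change in a few metabolites moves the *total* spectral area enough
that unit-area normalization injects an opposing, perfectly
group-correlated "closure" artifact into every bin, which makes any
random bin subset discriminative. With abundance-dominated totals the
normalization constant is stable and planted effects stay local to
their resonances — the regime real total-area normalization operates in.
Each sample's concentrations are finally multiplied by a log-normal
dilution factor (log-sd 0.3), which normalization removes.

The continuous outcome emulates the change in DAS28: group means −0.5
(non-responders) and −3.0 (responders), noise sd 0.8. The generator
records group-mean log concentrations, per-sample rendered
concentrations, dilution factors and per-sample render seeds, so every
spectrum can be reproduced bit-exactly from the truth record.

Two planted signatures are provided: the 4-metabolite response signature
(histamine, glutamine, xanthurenic acid up; ethanolamine down) and the
drug-contrast signature (hippurate/citrate/lactate up under infliximab;
choline/phenylacetate/urea/creatine/methylamine up under etanercept). The
default "moderate" planted effect is 1.0 log-fold (≈ 2.7×), against a
within-group biological log-sd of 0.25.

What the generator does **not** emulate: J-coupling multiplets,
pH-dependent shift drift, peak overlap from the hundreds of minor urine
compounds, field inhomogeneity, or water-suppression artifacts. Passing
tests therefore demonstrate the *statistical machinery* — leakage-free
cross-validation, calibrated permutation inference, frequency-based GA
ranking, tolerance annotation — under a controlled spectral model, not
robustness to every artifact of real spectra.

## Experiment and test problem sizes

- Planted-signature recovery runs at the study's own scale: 16 baseline
  samples (9 non-responders vs 7 responders), full 1840-bin matrices,
  GA with 100 searches capped at 60 generations (the goal criterion
  makes longer runs redundant on separable cohorts), over 20 generator
  seeds.
- Chance-level controls use one 200-sample cohort with 50 label
  permutations for PLS-DA CV accuracy and random-chromosome GA fitness.
- Permutation-test calibration uses 200 null datasets (16 × 10, 2-bin
  budget, 50 permutations each); power uses 20 datasets of n = 36 with a
  strong planted linear signal and 100 permutations. Dataset dimensions
  are kept small because the selection-inclusive null refits the entire
  forward-selection pipeline per permutation; calibration is a property
  of the procedure, not of the matrix size.
- The acceptance script's regression experiment uses 0.05-ppm bins and a
  5-bin selection budget for the same reason; all its other experiments
  run the default 0.005-ppm binning.

## Known limitations

- PLS-DA assumes exactly two classes; multi-class designs are out of
  scope.
- The forward-selection CV r² can be negative early on noise outcomes;
  selection then stops immediately, which is intended but means the
  "selected bins" list can be a single bin on null data.
- The GA's frequency ranking inherits GALGO's greediness: strongly
  correlated neighboring bins of one metabolite can crowd the top of the
  ranking when one resonance region dominates the class difference.
- The JCAMP-DX reader covers uncompressed AFFN `(X++(Y..Y))` and
  `(XY..XY)` tables only (no DIF/DUP/SQZ packed forms).
- Paired (subject-aware) fold assignment for the longitudinal design is
  available via the Venetian-blinds block option but is off by default;
  the default treats baseline and 12-week samples as independent, as the
  two-class machinery does.
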