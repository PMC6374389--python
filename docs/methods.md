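# Methods

`sleepmet` analyses plasma metabolite concentrations from a two-factor
animal design — treatment {SHAM, ROT} × procedure {CT, SR, REB}, six groups —
through five stages: panel QC filtering, OPLS-DA chemometrics, per-metabolite
group statistics, stepwise biomarker modelling, and a ¹H NMR spectral branch.
A synthetic cohort generator reproduces the statistical structure the
analysis assumes, so every stage is exercised end to end without animal
data. This note records the models, the defaults and why, the numerical
choices, and what the tests do and do not demonstrate.

## Panel model and QC filtering

A targeted panel is a manifest of 183 metabolites in five compound classes
(40 acylcarnitines, 21 amino acids, 19 biogenic amines, 89
glycerophospholipids, 14 sphingolipids) with per-metabolite LOD, LLOQ and
ULOQ bounds in µM. The packaged manifest is a constructed stand-in with
p180-style names, not a vendor list; its bounds are tied to plasma baselines
(LOD = baseline/50, LLOQ = baseline/20, ULOQ = 20×baseline) so that typical
readings sit far from the limits. Concentrations are stored in µM with
explicit missingness (never imputed zeros); every cell carries a status flag
derived from the bounds, so QC decisions do not depend on upstream export
conventions.

A metabolite is excluded when any of five rules fires, with strict
inequalities throughout: >25% of study-sample cells below LOD, below LLOQ,
or above ULOQ; mean blank signal above the LOD ("blank out of range",
operationalized here since assay documentation leaves it vendor-defined);
or CV > 30% over QC level-2 replicates (CV = 100·sd(n−1)/mean). The 25%
fraction is computed over study samples only. Exactly 25% or exactly 30%
is retained; both thresholds are configurable. Rules needing QC or blank
rows are skipped with a warning when those rows are absent. Downstream
tests use per-metabolite pairwise deletion of missing cells.

## Chemometrics

Scaling is column-wise: `center`, `uv` (unit variance) or `pareto` (divide
by √sd). Unit variance is the default for targeted LC/MS concentrations;
Pareto for spectral matrices, where it tempers the dominance of tall peaks.

PCA is computed by SVD of the scaled matrix. Hotelling T² per sample is
Σ t_a²/λ_a over the retained components, with the F-limit
A(n−1)(n+1)/(n(n−A))·F(α; A, n−A).

OPLS-DA uses the orthogonal-filtering formulation for a single 0/1 response
(centered before fitting): the predictive weight is w ∝ Xᵀy (unit norm);
each orthogonal component takes p = Xᵀt/(tᵀt), w_o ∝ p − (wᵀp)w,
t_o = X w_o, and deflates X by t_o p_oᵀ; the predictive component is
extracted from the fully deflated matrix. The sign convention makes positive
p(corr) — the Pearson correlation between the predictive score and a scaled
variable — mean "higher in the second-listed (y = 1) group". Component
counts are reported as "1 + n_orth".

Q²Y = 1 − PRESS/SS with held-out predictions from 7-fold cross-validation;
fold membership is deterministic and interleaved by sample order (fold =
index mod folds), chosen for bit-reproducibility. Orthogonal components are
added greedily while Q² improves by more than 0.01 — commercial packages do
not disclose their stopping rule, so this one is declared rather than
inferred, with both the threshold and the cap configurable.

CV-ANOVA compares the cross-validated residual variation against total y
variation: F = ((SS − PRESS)/d1)/(PRESS/d2) with d1 = 1 + n_orth latent
components and d2 = n − 1 − d1. The degrees-of-freedom bookkeeping of the
published CV-ANOVA convention is approximated (the commercial internals are
proprietary), so these p-values are compared against a significance level,
never digit-for-digit; a simulation in the test suite checks the null
rejection rate at α = 0.05 stays in [0.01, 0.10].

The permutation test refits the full procedure — including orthogonal
component selection — for every permuted labelling and reports
p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1). One subtlety, found while
calibrating: with deterministic interleaved folds, a systematically
alternating observed labelling is atypically well balanced across folds and
biases p downward; under a true null the observed labelling must be treated
as one random draw among its permutations, which restores exact uniformity.

## Group statistics

Ratio tables are arithmetic group mean over control-group (SHAM-CT) mean of
raw concentrations (ratio-of-means; per-animal ratios would weight animals
differently). ANOVA runs on natural-log concentrations by default, matching
the multiplicative structure of the ratios (configurable to raw). The
two-factor model uses Type-II sums of squares — robust to the mild imbalance
that sample exclusions create — plus additive-model coefficient t-tests for
the ROT-vs-SHAM, SR-vs-CT and REB-vs-CT contrasts. BH-FDR is applied across
metabolites separately per test family (one-way, each factor, each
contrast). For cohorts without missing cells all metabolites share one
design matrix, so the fits are vectorized (nested residual-sum-of-squares
comparisons); the suite asserts equality with per-metabolite
statsmodels/scipy fits to 1e−10. Note that BH q-values are not a fixed point
of the procedure (reapplying BH to q-values can change them); the meaningful
invariants are q ≥ p, q ≤ 1, and rank monotonicity.

Ward clustering (Euclidean, Lance–Williams update via scipy) orders the
heat map; leaves are traversed smaller-cluster-first for a deterministic
order. Missing cells are mean-imputed per metabolite for clustering only.
The correlation screen computes Pearson r (binary covariates via 0/1
coding) over all metabolite and covariate pairs, reports |r| > 0.4, and
attaches BH-adjusted correlation-test p-values over the screened family.

## Biomarker modelling

Candidates for a contrast (default: pooled SR vs pooled CT) must pass three
screens: q < 0.05 for the matching contrast family; a direction-agnostic
permutation AUC test (statistic max(AUC, 1−AUC), since markers fall as well
as rise; add-one p-value over 10,000 permutations by default) at P < 0.05;
and |mean ratio − 1| > 5% on raw concentrations. The non-CV AUC screen uses
raw values; model fitting uses natural logs.

Logistic models are fit by IRLS. Perfect separation — inevitable at n ≈ 23
with strong markers — triggers a fallback to a tiny ridge penalty
(λ = 1e−6) and sets a provenance flag. LOOCV probabilities warm-start each
leave-one-out fit from the full-data coefficients. The panel grows greedily
by the candidate with the highest LOOCV AUC, accepted only on strict
improvement ("no further improvement" stops the search); ties break by
lower q-value then lexicographic id, making the result invariant to
candidate input order. The final model is refit on all samples; ROC is the
all-thresholds staircase whose trapezoid area equals the Mann–Whitney AUC,
and confusion metrics use the strict p > 0.5 rule.

## ¹H NMR branch

Spectra are (ppm, intensity) pairs on a strictly decreasing axis, with
append-only provenance. Order: reference → excise → digitize →
outlier-remove. Referencing finds the β-glucose anomeric doublet in a
5.0–5.5 ppm window (two resolved peaks within 0.02 ppm; centre = their
mean) and shifts the axis so the centre sits at δ 5.223; a spectrum without
a peak above median + 5·MAD is an error. The water region defaults to
4.5–5.1 ppm — bounds are conventional, configurable, and must not cover the
reference. Digitization linearly interpolates every spectrum onto a common
full-resolution grid (the generator's 16,384-point 10.0 → −0.5 ppm axis by
default); bucketing is deliberately not the default since fixed-width
binning discards resolution the interpolation preserves.

Outlier removal Pareto-scales the digitized matrix and flags samples by
Hotelling T² at the 99% limit (95% would over-flag at these sample sizes)
on a fixed 4-component overview PCA, iterating flag → remove → refit until
clean. The iteration matters: k similar outliers inflate the variance of
their own score direction, capping each one's T² near (n−1)/k however
extreme they are, so a single pass can mask a group of outliers. Flagged
spectra are annotated with the band (glucose 5.18–5.27 vs lactate
1.315–1.345 ppm) contributing most scaled deviation.

## Synthetic cohort generator

The generator defines the study conditions the tests assume:

- **Group sizes** — default 11/group (the study analysed 10–12).
- **Effects** — multiplicative group-mean ratios vs SHAM-CT. The ten
  metabolites with significant six-group differences use the published
  ratios exactly (e.g. isoleucine 1.00/1.22/1.12/1.35, kynurenine
  1.00/0.79/1.15/0.72 for SHAM-CT/SHAM-SR/ROT-CT/ROT-SR); metabolites
  reported only by direction of change get ±15%; everything else 1.00; the
  rebound groups are 1.00 throughout (the SR and ROT effects were lost
  after recovery sleep).
- **Noise** — log-normal with log-sd 0.15 per metabolite. Dispersions are
  not published; 0.15 makes the published ratios FDR-detectable at
  n ≈ 11/group, which is the regime the analysis targets.
- **Correlations** — realized on the log scale within group (so group
  effects cannot inflate r): LEU×ILE 0.90, VAL×ILE 0.94, VAL×LEU 0.89,
  PHE×MET 0.73, TRP×MET 0.64, activity×MET 0.41. Unspecified pairs are
  completed to a PSD matrix by alternating projections between the PSD cone
  and the set fixing the specified entries — this keeps the specified
  correlations exact, which plain eigenvalue clipping does not (it perturbs
  them by up to 0.07 here). Activity×sleep (−0.57) is realized through the
  group structure: sleep_condition is 1 for SR and 0 for CT/REB, and the SR
  activity deficit is calibrated so the pooled point-biserial correlation
  hits the target (activity: mean 5400 s, within-group sd 900 s).
- **QC and blanks** — three QC levels at 0.5×/1×/2× baseline with
  configurable CV (default 10%), blanks drawn below the LOD. LOD censoring,
  when on, removes sub-LOD readings; flags always reflect the bounds.
- **Violation fixture** — a deterministic cohort in which 50 designated
  metabolites (30 acylcarnitines, 7 biogenic amines, 13
  glycerophospholipids) each violate exactly one rule, with the allocation
  recorded in a ledger, so the retained set has composition 10/21/12/76/14.
- **Spectra** — Lorentzian lines for the glucose anomeric doublet and ring
  protons, lactate doublet/quartet, BCAA methyls, broad lipoprotein
  envelopes and residual water; additive noise (sd 0.002), per-spectrum
  amplitude variability (log-sd 0.08) and optional axis mis-calibration.
  The default outlier plan plants three high-glucose spectra at distinct
  factors (3.0/4.5/6.0) and one high-lactate (5.0) — distinct magnitudes,
  as distinct hyperglycaemic animals would show, which also keeps the
  planted set recoverable by T² (see the masking note above).

What passing tests show — and don't: the generator produces exactly the
correlation and effect structure the analysis assumes, with no unmodelled
biology, batch structure, drift, or heavy-tailed noise. Recovery results on
it are therefore upper bounds on real-data behaviour. In particular the
synthetic SR signal is cleaner than animal plasma, so stepwise panels reach
held-out AUCs near 1.0 at n = 11/group, above the ~0.85 a real cohort
yields; the tests assert recovery frequencies and floors, not real-data
effect sizes.

## Degenerate inputs and numerical conventions

Zero-variance columns: centered only when scaling (warning), p(corr) = 0
(warning). Constant responses: ANOVA p = 1. Aliased or non-factorial
designs: additive model, interaction NaN. A training fold losing a class is
an error (fold CV) or skips the candidate (LOOCV). Probabilities exactly at
the classification threshold are negative (strict >). Permutation p-values
use the add-one rule, so p ≥ 1/(n_perm+1). Report JSON is schema-versioned,
floats rounded to 10 digits, keys sorted — two runs with one seed are
byte-identical. All RNG flows from explicit seeds through
`numpy.random.default_rng`.

Problem sizes in the test suite are chosen to finish in minutes: null
calibrations use 1000 repeats × 999 permutations (single-marker AUC) and
200 × 199 (OPLS Q²), recovery properties use 40–100 seeded cohorts at
11/group, and convergence checks use one 1000/group cohort.

## Known limitations

- CV-ANOVA degrees of freedom are an approximation to an undisclosed
  convention; use its p-values only against a threshold.
- The manifest is a constructed stand-in; real p180 exports need their own
  manifest CSV (bounds in µM).
- No imputation, batch or drift correction (the emulated design is a single
  plate); no multi-class OPLS-DA; no peak fitting or metabolite
  identification in the NMR branch; phase/baseline correction is assumed
  done upstream (the generator emits phase-corrected, baseline-flat
  spectra).
- The biomarker search is greedy; it will not find panels whose members are
  only jointly informative through suppression effects, and at these sample
  sizes the LOOCV AUC ceiling stops growth early when a single marker is
  strong.
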