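# Methods

## Outcome definition

The MSKP severity index aggregates visual-analogue pain intensities (0–10)
over four body regions (neck, shoulders, middle back, lower back).  Each
region is banded — 0 for no pain, 1 for intensities 1–3, 2 for 4–7, 3 above
7 — and the index is the sum of the four bands (0–12).  Positivity is
index ≥ 4; since one region contributes at most 3, a positive case needs
meaningful pain in at least two regions.  The no-pain band (0 → 0) is forced
by the semantics of "absence of pain"; the three non-zero bands are the
published convention.

## Instruments

* **TDM / mobile dependency** — plain sum of 22 Likert items (0–4), total
  0–88.
* **SDSC sleep factors** — six factor scores carried as continuous values on
  their factor scales (0–4, 0–3, 0–3.2, 0–3, 0–4, 0–4).  The scales follow
  the published effect-table ranges; the alternative days-per-week reading
  of the instrument description is not used because the reported per-SD
  coefficients (e.g. 0.039 at SD 1.04 for factor 5) only make sense on the
  continuous factor scale.
* **IPAQ** — five activity levels cut on weekly MET-minutes at
  600 / 1500 / 3000 / 4500.  The level labels are published; the cutpoints
  are not, so they are package defaults (configurable) chosen to match the
  conventional low/moderate/high IPAQ bands with two extra extremes.
* **Complete-case rule** — a record missing any scored item is dropped and
  listed in the exclusion report.

## Synthetic cohort generator

The generator is the package's study population: it emulates the surveyed
sample so the pipeline can be exercised and its operating characteristics
measured.

* **Marginals** follow the published sample description: 53.8% girls, age
  discretised from N(13.9, 2.0²) on 10–18, TDM total from a rounded
  truncated normal (25.1, SD 16, 0–88), IPAQ category proportions
  15/38/35/10/2% enforced exactly through a piecewise-uniform MET-minutes
  marginal, per-region pain-report rates 28.7/21.6/30.2/15.9%.  Sleep
  factors and the daily-habit items use right-skewed scaled Beta marginals;
  their shape parameters are invented.
* **Correlation structure** is a Gaussian copula: per block (6 sleep
  factors; 12 activities + MET-minutes; 8 chores; 4 screen-use variables) an
  equicorrelated latent normal is pushed through each marginal's inverse
  CDF.  The latent correlation is set to 2·sin(π·ρ_S/6) so a requested
  Spearman ρ_S is realised for continuous marginals.  Defaults: sleep 0.32,
  activity 0.25, chores 0.22, screen 0.35.  Girls receive small latent
  shifts (more sleep problems and chores, less sport except dance) matching
  the survey's qualitative description; magnitudes are invented.
* **One-hot realism**: age group, school grade, transport and IPAQ are drawn
  as single categoricals and encoded afterwards, producing the structural
  negative within-group correlations of one-hot data.  School grade tracks
  age with a ±2 jitter (grade repetition / early entry).
* **Outcome model**: logistic over the encoded features.  The default
  effect table mirrors the published one in sign and importance ranking,
  with designed per-SD log-odds between 0.42 and 0.58 (football −0.52).
  The published shrunken coefficients themselves (max ORs 1.02–1.18) are
  mutually inconsistent with the reported discrimination (AUC ≈ 0.8): a
  model with all per-SD effects below 0.17 cannot discriminate at that
  level, so the generator scales the effects to reproduce the reported AUC
  while keeping the qualitative structure.  Two features
  (`activity_weightlifting`, `age_group_16_18`) carry small additional
  boosts so that every true effect is reliably resolvable at the survey's
  sample size despite block correlation and proxy competition; exact
  max-OR-ranking parity with the published table is deliberately not
  attempted because binary features cannot reach large maximum ORs.
  Defaults were frozen after Monte-Carlo design checks (mean CV AUC in the
  published range, reliable selection of every true effect, ≥80% of
  zero-effect features dropped) and are not tuned thereafter.
* **Intercept calibration**: Monte-Carlo root finding (Brent) on the
  simulated prevalence curve at n = 100 000 with a fixed internal seed;
  target prevalence 22.6%.  The frozen default intercept is −8.9542.
* **Pain synthesis**: outcome labels are drawn first from the logistic
  model; region intensities are then sampled from the *exact* conditional
  distribution over all 11⁴ intensity combinations (enumerated once, split
  by index ≥ 4), so re-scoring a generated cohort reproduces the drawn
  labels identically.
* **What the generator does not emulate**: item-level psychometrics of the
  instruments (only totals and factor scores matter downstream), missing
  data mechanisms, seasonal or school-level clustering, and any causal
  structure between predictors and pain.  Passing tests therefore
  demonstrate the pipeline's statistical machinery under the emulated
  structure, not epidemiological conclusions about real adolescents.

## Feature selection

* **Screen** (first step): average-linkage clustering on 1 − |Spearman ρ|,
  tree cut at 1 − threshold (default |ρ| = 0.5, configurable).  The
  published analysis screened manually from the dendrogram; an automatic
  deterministic rule is required here, so within each cluster the kept
  representative is the feature with the largest |ρ| with the outcome (ties
  broken alphabetically) — a documented departure.  The reference level of
  every one-hot group is always dropped first, and same-group one-hot
  siblings are never merged into one cluster: their negative correlation is
  structural complementarity, not redundancy, and letting them merge would
  discard a category indicator based on a noise-level representative
  contest.
* **Lasso selection** (second step): penalty λ scales the L1 term against
  the total log-likelihood (`C = 1/λ` in scikit-learn's convention); the
  published λ = 10 is the default for the selection stage, and a log-spaced
  grid 10⁻²…10² (including 10) is searched by mean test-fold AUC wherever a
  grid is requested — the definitive-model stage always grid-searches.
  Retention rule: median of the 60 fold coefficients nonzero
  (|median| > 10⁻⁸).

## Definitive-model workflow

Stratified 60/20/20 split (train / risk definition / risk evaluation), all
parts preserving the sample prevalence to within one respondent.
Standardization statistics, ensemble fitting and penalty choice use the
training part only; tertile cutpoints use the risk-definition part only;
the evaluation part is untouched until the final band comparison, and the
workflow object records which rows entered each stage and asserts the
separation structurally.  (The standalone screen/select analysis scripts
mirror the published two-step selection on the full sample; the definitive
workflow re-fits everything leak-free downstream of the chosen feature
list.)

Band cutpoints sit at the order statistics immediately above the empirical
tertile boundaries (`sorted[⌈n/3⌉]`, `sorted[⌈2n/3⌉]`) with left-closed,
right-open intervals: this makes tertile balance exact up to ties
(|band − n/3| ≤ 1) and assigns a score equal to a cutpoint to the upper
band, matching the published "below c₁ / between c₁ and c₂ / above c₂"
wording.  An empty band reports its prevalence as undefined, never 0.

## Effect statistics

OR per SD = exp(β_std); maximum OR = exp(β_std · range/SD) with the range
and SD observed on the training rows (the same rows that defined the
standardization).  Confidence intervals for the maximum OR use the normal
approximation on the log-OR scale with the across-fold mean and SD of the
60 per-fold values, at per-feature level 1 − (0.10/k) for k features
(Bonferroni, family level 90%); an empirical-quantile variant is available
via config.  The across-fold spread mixes sampling and fold-assignment
variability and is wide for weak effects, so only strong effects' CIs
reliably exclude 1 at the survey's sample size — the tests freeze exactly
that measured behaviour.  Prevalence uses the Wilson score interval, which
reproduces the published 22.6% [19.7%, 25.9%] from 154/680 at one-decimal
rounding (a Wald interval does not).

## Numerical choices

* L1 fits use scikit-learn's saga solver with `C = 1/λ`, tolerance scaled
  by min(1, 1/λ) so the unpenalised intercept converges even at extreme
  penalties, and a fixed solver seed for exact determinism; λ = 0 routes to
  unpenalised lbfgs.  If every slope is exactly zero the intercept is set
  to its closed form logit(prevalence).
* AUC is the rank statistic (ties count ½); grid ties on mean AUC go to the
  larger penalty.
* Constant columns standardize to 0 and are flagged, never divided by zero;
  their correlations are defined as 0.
* Problem sizes in the test suite: calibration checks at n = 50 000–100 000,
  effect recovery at n = 20 000, selection operating characteristics over
  20 seeded cohorts of n = 680, band behaviour over 50 seeded workflow
  replicates — sizes chosen to make Monte-Carlo noise small relative to the
  asserted margins.

## Known limitations

* The synthetic defaults are one plausible realisation of the survey's
  structure; conclusions about selection frequencies and band ordering are
  specific to those defaults.
* The screen's representative rule is deterministic but greedy; with
  strongly clustered proxies it can keep a proxy over the causal feature
  when their outcome correlations are within noise of each other.
* No probability recalibration is applied to ensemble scores, and no causal
  interpretation is attached to any effect estimate.
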