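# Methods

This note documents the models implemented in `npxrisk`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Study design and estimand

The package targets a nested case-control design: within each prospective
cohort, every future cancer case (diagnosed within a bounded lead time `L`
of blood draw, 3 years by default) is matched 1:1 to a control on cohort,
sex, age (±1 year), and smoking status in four categories (current <15 or
≥15 cigarettes/day; former, quit <10 or ≥10 years ago). Protein abundances
are relative, log2-scale (NPX-like) values. The estimand for each protein
is the odds ratio of imminent diagnosis per standard deviation of the
within-cohort-standardized protein, OR_sd = exp(β), from the 1:1
conditional logistic model.

## Synthetic-study generator (`npxrisk.simulate`)

The generator is the package's data-generating stand-in for restricted
cohort data; its mechanism is chosen so the estimand is known exactly.

**Mechanism.** For each matched pair, the two members' standardized latent
protein values are drawn from a bivariate normal with within-pair
correlation ρ per protein (default 0.2, mimicking the residual similarity
matching induces). With pair lead time L ~ Uniform(0, 3) years, the case
label is assigned within the pair with probability

    P(member 1 is the case) = exp(η₁) / (exp(η₁) + exp(η₂)),
    ηᵢ = Σⱼ βⱼ(L) x_{ij},   βⱼ(L) = β₀ⱼ + β_lead,ⱼ · L,

optionally shifted additively by histology- or smoking-category-specific
modifiers. This retrospective conditional-likelihood assignment makes the
1:1 conditional logistic model hold *exactly* with the planted
coefficients, so estimator bias and CI coverage can be audited against a
known truth without simulating a full source cohort under
incidence-density sampling. The trade-off: the generator does not produce
absolute risks or a cohort time axis, only the matched contrast.

**Planted-effect scale.** Planted β₀ values used in tests and the
acceptance script span log(0.74) to log(2.43), the magnitude range a
well-powered pre-diagnostic protein study reports for replicable markers,
with lead-time decay β_lead < 0 for markers that strengthen toward
diagnosis.

**Measurement structure.** Raw values are μⱼ + σⱼ·x with per-assay means
in [5, 10] and scales in [0.5, 1.5] (NPX-like magnitudes); each assay's LOD
is placed at a configurable pooled quantile (default 5%) and values below
it are flagged; a configurable fraction of proteins (default 10%) is
duplicated on a second panel as a noisy copy (noise SD 20% of the assay
scale); cohorts measure only their configured panels, so panel-restricted
proteins are missing in some cohorts, reproducing the
full-library-in-two-cohorts / subset-elsewhere structure.

**Covariates.** Smoking intensity, duration, and cessation are drawn per
member within the pair's shared category; proteins can load on a
standardized smoking composite (`smoking_assoc`) to create cross-sectional
smoking associations. The baseline risk score is a noisy monotone function
of smoking intensity/duration/cessation — a stand-in for a
questionnaire-based risk model, not a reimplementation of one. Histology
and stage-group marginals approximate a late-stage-dominated case series
(adeno 34%, squamous 20%, large-cell 4%, small-cell 16%, other 26%; stages
1–4 at 12/11/30/47%, 54% missing stage). Post-diagnosis survival is
exponential with cohort×sex-specific baseline scale and a planted log
hazard ratio per SD (`gamma_surv`); censoring is exponential.

**What the generator does not emulate.** Plate and batch effects, bridging
normalization, assay cross-reactivity, informative missingness, matching on
blood-draw date, and protein–protein biological covariance beyond the
planted partial-correlation structures used in network tests. Passing
tests therefore demonstrate correctness of the estimators and algorithms
under a faithful design, not robustness to every artifact of real assay
data.

## Preprocessing (`npxrisk.preprocess`)

Order of operations: LOD substitution → duplicate resolution →
within-cohort standardization (QC percentages are computed from the raw
below-LOD mask). Below-LOD values are replaced by LOD/√2, the conventional
substitution for left-censored assay values; the mask is retained so QC can
flag proteins with ≥20% of pooled values below LOD. A non-positive LOD is
substituted as the rule states, with a warning, since the rule is
degenerate there. Duplicate assays are resolved by lowest missingness
first, highest variance on ties — missingness dominates usability, and
variance (computed on LOD-substituted values over the cohorts where all
duplicates were measured, so the comparison is head-to-head) breaks ties in
favour of the assay with more dynamic range. Standardization uses all
samples per cohort (cases and controls) with the ddof=1 SD; a zero-variance
protein-cohort cell is set to missing and logged rather than producing
infinities.

## Matched models (`npxrisk.models`)

Only 1:1 sets are supported; the conditional likelihood is implemented
directly on within-set differences (no general m:n machinery). Newton
iterations use the analytic score and observed information, stop at
max-norm score < 1e-8 or 50 iterations, and halve steps on a likelihood
decrease. Covariate columns whose within-set differences are identically
zero cancel in the conditional likelihood and are dropped from the fit
(reported with zero coefficient and infinite SE). A covariate whose nonzero
differences all share one sign has a monotone likelihood and no finite
maximizer; this raises an error naming the covariate. Estimates diverging
past |β| = 30 are treated the same way. Wald p-values use the normal
reference, matching the CI formula exp(β ± 1.96·se).

A vectorized single-covariate path fits every protein of a matrix at once
(per-protein scalar Newton with NaN-masked differences, steps clipped to
±4); it is exact — the unit tests assert agreement with the multivariate
path to 1e-8 — and is what makes 100-iteration × 300-protein resampling
runs take seconds.

Smoking-adjusted models enter cigarettes/day, years smoked, and years
since cessation as continuous covariates standardized within cohort (the
untransformed-continuous choice; categorized alternatives are a caller-side
transformation). Cross-sectional smoking models are OLS of the
standardized protein on one smoking metric with adjustment for cohort
indicators, age, sex, and smoking status, among controls only or cases+
controls with a case-status indicator; years-since-cessation models are fit
among former smokers.

## Multiplicity (`npxrisk.multiplicity`)

ENT is the smallest k whose leading k eigenvalues of the protein
correlation matrix explain ≥95% of total variance. Correlation (not
covariance) PCA is used — on a cohort-standardized matrix the two agree up
to missingness. Missing entries are mean-imputed solely for the
eigendecomposition (zero on a standardized matrix), keeping one complete
matrix rather than pairwise-complete correlation estimates that need not be
positive semi-definite. ENT is computed once per selection run on the full
standardized matrix of the protein set in play: the per-iteration
alternative changes the threshold negligibly while making runs slower and
the threshold unstable.

## Selection (`npxrisk.selection`)

Matched sets — never individuals — are split 70/30 within each non-forced
cohort (banker's rounding of the discovery count; forced cohorts go wholly
to discovery). Defaults: 500 iterations, discovery fraction 0.7, selection
frequency 0.5, sign concordance required (a "replicated" association should
replicate in direction; the flag is toggleable to measure its impact), and
a protein enters an iteration only when ≥25 complete sets fall on each
side. Selection requires joint pass frequency ≥ the selection frequency
*and* at least one passing iteration — the extra clause only matters at a
selection frequency of zero, where it makes the boundary case reduce to the
single-iteration pass set instead of selecting everything vacuously. The
run is a pure function of the data and the config seed, and the iteration
log records each split's cohort composition so forced-cohort and
set-integrity invariants can be audited after the fact.

The single-split variant fixes discovery to designated cohorts and uses
BH-FDR < 0.05 in discovery with p < 0.05 in replication — FDR rather than
ENT because a fixed discovery subset has less power than the resampled 70%
splits.

## Strata and discrimination (`npxrisk.strata`)

Sets are stratified by the case's attribute (histology, stage group,
lead-time category <1 / 1–2 / 2–3 years) or the pair's shared attribute
(cohort, smoking status). Heterogeneity uses Cochran's Q on the stratum log
ORs with inverse-variance weights (χ², k−1 df); lead-time trend uses
inverse-variance-weighted linear regression of the stratum log OR on the
category score with the fixed-effect slope SE — the standard
meta-analytic contrasts for stratum-specific estimates.

The AUC is the Mann–Whitney concordance with ties counted ½. The AUC gain
from one protein is computed by refitting an unconditional logistic model
of case status on (baseline score, protein) and scoring its linear
predictor — the minimal combiner, fit near-unpenalized (ridge C=1e6) so
complete separation yields a finite coefficient and AUC → 1 rather than an
error. Both AUCs are in-sample and conditional on the matched design:
matching on strong risk factors removes their discrimination, so baseline
AUCs near 0.5 are expected and the *gain* is the quantity of interest; no
cross-validation is applied, so gains for null proteins carry a small
positive optimism that shrinks as 1/n.

## Networks (`npxrisk.network`)

Proteins are residualized by per-protein OLS on age, sex, cohort, and
smoking status; conditioning on the *other proteins* happens inside the
precision matrix itself, which is the point of a graphical model. Networks
are estimated separately in cases and controls by stability selection over
the graphical LASSO: 100 half-sample subsamples (without replacement), an
edge's stability is the fraction of subsamples with a nonzero precision
entry (|Ω_ij| > 1e-8), stable edges need frequency ≥0.9, and the penalty is
chosen by the StARS criterion — scan the grid from sparse to dense and keep
the densest penalty whose monotonized mean edge instability 2f(1−f) stays
≤0.05. All parameters are configurable; the defaults are the standard
stability-selection choices.

## Clinical course (`npxrisk.clinical`)

Stage at blood draw is back-calculated deterministically: starting at the
diagnosed stage, subtract that stage's mean sojourn time from the lead
time; while the remainder is positive, step one stage down and subtract
that stage's sojourn time; the stage where the remainder first becomes
non-positive is the estimate, and lead times exceeding the whole
preclinical window return stage 1. A deterministic expected-path walk was
chosen over a stochastic dwell-time model because only mean sojourn times
(by stage × sex × histology) are taken as input; the walk is monotone in
lead time by construction. The packaged default sojourn table is
**synthetic** — plausible magnitudes with the qualitative pattern of
published natural-history models (shorter dwell at higher stage, fastest
for small-cell) — and real estimates should be supplied as a four-column
TSV (stage, sex, histology, years) when available.

Post-diagnosis survival uses Cox partial likelihood (lifelines; Efron tie
handling) on time from diagnosis to death from any cause, with the baseline
hazard stratified by cohort × sex, adjustment for age, and a protein ×
lead-time interaction; centring the interaction at L = 0 makes the protein
main effect its log hazard ratio at diagnosis. Stage is deliberately not
adjusted for.

## Pipeline and provenance (`npxrisk.pipeline`, `npxrisk.cli`)

All I/O is tab-separated UTF-8 text with `NA` for missing. A run is
configured by a `RunConfig` (optionally from YAML), validates inputs first
(set completeness, matching constraints, LOD availability, panel
consistency — violations are machine-readable), executes stages in a fixed
order with per-stage timings, and writes a manifest carrying the seed and a
config hash. One global seed derives per-stage seeds by stable SHA-256
hashing of the stage name, so toggling one stage never shifts another
stage's randomness. Descriptive stages (stratification, discrimination,
networks, survival) run on the selected proteins, topped up to a
configurable minimum with the strongest overall associations when selection
is sparse.

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks run at sizes where the checked property is decisive yet
the whole suite stays fast: 700-set studies for parameter recovery and CI
coverage (500 replicates), 300 proteins × 400 sets × 100 iterations × 10
seeds for selection validity, 8 proteins × 300 samples × 50 resamples for
network recovery, 1,000 cases for the back-calculation oracle, and 2,000
cases × 60 replicates for Cox calibration. These sizes are the package's
own choices for decisive-but-fast simulations; the algorithms themselves
scale to full study dimensions (the 500-iteration default on ~1,200
proteins and ~730 sets runs in minutes thanks to the vectorized matched
estimator).

## Known limitations

- 1:1 matching only; m:n conditional likelihood and exact/Firth inference
  are out of scope (monotone likelihoods raise rather than penalize).
- The ΔAUC combiner is in-sample; small positive optimism for null
  proteins is documented rather than cross-validated away.
- Network edge detection thresholds the glasso precision at 1e-8; true
  near-zero partial correlations below estimator resolution are
  indistinguishable from zero.
- The generator's case-assignment mechanism yields matched contrasts only;
  absolute-risk quantities are outside the design.
- The bundled sojourn table is a labelled synthetic stand-in, and stage
  back-calculation ignores dwell-time dispersion.
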