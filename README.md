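# npxrisk

Discovery of blood protein markers of imminent cancer diagnosis from
matched case-control proteomics studies.

`npxrisk` implements the full analysis pipeline for a multi-cohort nested
case-control design in which each future cancer case is matched 1:1 to a
control on cohort, age, sex, and detailed smoking status, and relative
protein abundances are measured on a log2 (NPX-like) scale across panels
whose availability differs by cohort. Because the cohort data such designs
use are access-restricted, the package ships a first-class synthetic-study
generator with planted effects, so every stage is testable and every
reported number is reproducible from code.

## What the pipeline computes

**Matched association model.** For matched set *s* with case covariates
*x*<sub>case,s</sub> and control covariates *x*<sub>ctrl,s</sub>, the 1:1
conditional likelihood is

&nbsp;&nbsp;&nbsp;&nbsp;L(β) = ∏<sub>s</sub> e<sup>β′x<sub>case,s</sub></sup> / (e<sup>β′x<sub>case,s</sub></sup> + e<sup>β′x<sub>ctrl,s</sub></sup>) = ∏<sub>s</sub> σ(β′d<sub>s</sub>),

with d<sub>s</sub> = x<sub>case,s</sub> − x<sub>ctrl,s</sub> and σ the
logistic function. The package maximizes this by Newton iterations with the
analytic gradient and Hessian; standard errors come from the observed
information and 95% confidence intervals are e<sup>β ± 1.96·se</sup>.
Because proteins are standardized within cohort, e<sup>β</sup> is the odds
ratio per standard deviation (OR<sub>sd</sub>).

**Preprocessing.** Values below an assay's limit of detection are replaced
by LOD/√2; proteins measured on two panels are resolved to the assay with
the lowest missingness (highest variance on ties); each protein is then
standardized to mean 0, SD 1 within each cohort, and proteins with ≥20% of
values below LOD are flagged.

**Multiplicity.** The effective number of tests (ENT) is the number of
principal components of the protein correlation matrix needed to explain
95% of variance; 0.05/ENT is the discovery threshold. BH-FDR is available
for the single-split sensitivity analysis.

**Selection.** A resampling discovery–replication algorithm: in each of
*n* iterations (500 by default) the matched sets are split 70/30 by cohort
(designated cohorts can be forced wholly into discovery); a protein passes
an iteration if p < 0.05/ENT in discovery and p < 0.05 in replication with
concordant coefficient signs, and is selected if it passes at least 50% of
iterations. A single fixed-split variant (FDR < 0.05 discovery, p < 0.05
replication) serves as the sensitivity comparator.

**Description of selected markers.** Stratum-specific ORs (histology,
stage, smoking status, cohort, lead time) with Cochran's Q heterogeneity
and inverse-variance-weighted lead-time trend tests; AUC gain over a
baseline risk score from a two-variable logistic combiner; residualized
Pearson correlations and graphical-LASSO stability networks (StARS penalty
selection, half-sample resampling) separately in cases and controls;
deterministic sojourn-time back-calculation of stage at blood draw; and
stratified Cox models of post-diagnosis survival with a protein × lead-time
interaction so the protein coefficient is its effect at diagnosis.

## Worked example

```python
import numpy as np
from npxrisk.simulate import SimConfig, CohortSpec, TruthTable, generate_study
from npxrisk.preprocess import preprocess_study
from npxrisk.models import fit_clogit
from npxrisk.selection import ResamplingConfig, resample_select

proteins = [f"P{i+1:04d}" for i in range(60)]
truth = TruthTable.with_effects(
    proteins, beta0={"P0001": np.log(2.4), "P0002": np.log(0.74)}
)
cfg = SimConfig(
    cohorts=[CohortSpec("EPIC", 180, ("panel1", "panel2")),
             CohortSpec("NSHDS", 60, ("panel1", "panel2")),
             CohortSpec("HUNT", 160, ("panel1",)),
             CohortSpec("CPS2", 120, ("panel1",))],
    n_proteins=60, truth=truth, seed=42,
)
study = generate_study(cfg)
pre = preprocess_study(study.matrix, study.lod_mask, study.annotations, study.subjects)

res = fit_clogit(pre.matrix, study.subjects, "P0001")
print(f"P0001: OR_sd = {res.or_sd:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
      f"p = {res.p:.2e}, n_sets = {res.n_sets}")

sel = resample_select(
    pre.matrix, study.subjects,
    config=ResamplingConfig(n_iter=100, forced_discovery_cohorts=("EPIC", "NSHDS"), seed=0),
)
print(f"ENT = {sel.ent.ent}, discovery threshold = {sel.ent.threshold:.2e}")
print(f"selected: {sel.selected}")
```

Output:

```
P0001: OR_sd = 2.55 (95% CI 2.09-3.10), p = 1.37e-20, n_sets = 520
ENT = 55, discovery threshold = 9.09e-04
selected: ['P0001']
```

The strong planted marker (true OR<sub>sd</sub> 2.4) is estimated at 2.55
with a covering confidence interval and passes the joint
discovery–replication criterion in 100% of iterations; all 520 matched sets
are usable because P0001 sits on a panel measured in every cohort (proteins
on cohort-restricted panels are fit on complete sets only). The weaker
inverse marker (true OR 0.74) is not selected at this sample size — the
joint criterion is deliberately conservative. ENT = 55 for 60
near-independent proteins reflects their weak correlation structure.

A command-line interface wraps the same stages
(`npxrisk simulate | preprocess | validate | select | run-all`); `npxrisk
run-all --out results/ --seed 1` runs a small end-to-end demo and writes
every stage's table plus a provenance manifest.

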