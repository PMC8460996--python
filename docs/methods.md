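# Methods

This note documents the statistical model behind `scdmort`, the assumptions
it rests on, the tunable parameters, the synthetic-data generator used to
validate it, and the numerical and design choices made where the design was
genuinely open.

## Setting and notation

A stratified two-stage household survey genotypes living children aged 6–59
months at the HBB locus (alleles A, S, C; genotypes AA, AS, AC, SS, SC, CC).
Maternal birth histories record every child ever born to interviewed
mothers, with survival outcomes. Sickle cell disease (SCD) means HbSS or
HbSC; sickle trait means HbAS or HbAC; CC is treated as class "Other" and
excluded from mortality inference. All ages and offsets are completed
months; the interview is the time origin; under-5 death means death before
60 completed months; mortality rates are per 1000 livebirths.

## Prevalence under Hardy-Weinberg equilibrium

Weighted allele frequencies are estimated by counting two allele units per
tested child, scaled by the household sample weight. "Other" test results
are counted as CC by default (the test device has no CC readout; a flag
drops them instead). HWE expansion ($p^2$, $2pq$) converts allele
frequencies into birth prevalences. HWE is used deliberately as a
stabiliser: trait carriers are numerous and nearly unaffected by early
mortality, so inferring the HbSS birth prevalence from $p_S^2$ avoids the
attrition bias that depresses the *observed* HbSS share among living
children. `hwe_consistency_check` reports observed vs expected HbSS by
group; a ratio below 1 in the tested cohort is the expected attrition
signature, not a model failure.

Uncertainty: a stratified cluster bootstrap. Within each sampling stratum
the clusters present in the data are resampled with replacement, keeping the
cluster count; the estimator is recomputed on the concatenated sample; 1000
replicates by default; the point estimate reported from the bootstrap is the
replicate median and the CI the 2.5/97.5 percentiles (the plug-in estimate
is reported alongside). Weights are used as-is inside replicates — no
per-replicate reweighting for cluster multiplicity — which is the standard
rescaling-free cluster bootstrap and is documented as an approximation to
the design. Percentile intervals (not BCa) keep replicates interpretable.

## Sibling groups and labels

Children sharing household and mother identifiers are full siblings; sharing
exactly one of the two makes half-siblings. Each full-sibling group with at
least one tested member is labelled by the most severe tested genotype class
(SCD > Trait > AA). A group with no tested member borrows the most severe
half-sibling group label, capped at Trait when that label is SCD (half
siblings share only one parent, so an SCD half-sibling guarantees at most
one carrier parent). A group labelled AA from its own members is promoted to
Trait when a half-sibling group is labelled SCD. Groups with no tested
relative stay unlabelled and leave the mortality models. When a child has
several half-sibling groups with different labels, the most severe capped
label wins (the rule set is silent here; this is consistent with the
severity ordering). Labelling is idempotent, and removing an untested child
never changes another child's label (tested genotypes are the only
evidence).

Cohort windows are half-open month intervals on the birth offset:
tested [6, 60), older [60, 180), KM [0, 180). The older cohort is the
inferential cohort: its under-5 survival is fully observed, and a child's
untested status there cannot have been caused by its own death (all children
born more than 60 months before the survey are outside the testable age
range regardless of survival).

## Excess mortality by label (β)

On the older cohort, a weighted linear probability model regresses the
under-5 death indicator on SLC dummies, geopolitical-zone dummies and an
urban indicator, with a random intercept per survey cluster. The linear
model (rather than logistic) is used because the estimand is an absolute
risk difference per 1000 livebirths, which the linear model yields directly
and, in simulation, without bias. Sample weights enter as regression
weights — an approximation to the survey design, with cluster resampling
carrying the design-based uncertainty.

The weighted random-intercept model is fitted by profiled REML. Writing the
marginal covariance as $\sigma^2(\mathrm{diag}(1/w) + \rho\,J)$ blockwise per
cluster, the Woodbury identity reduces each objective evaluation to
per-cluster weighted sums, so the fit costs O(clusters × p²) per evaluation;
the scalar ρ is optimised on a log grid with a bounded Brent search, with an
explicit comparison against the ρ = 0 boundary. Covariates constant within
clusters make the profile singular as ρ → ∞; such evaluations return an
infinite criterion and the optimiser steps past them. On a singular or
failed fit the estimation ladder falls back to weighted least squares with
cluster-robust standard errors, and the fallback is recorded in the result
and the pipeline outputs. Empty covariate levels are dropped with a warning,
as is a constant urban indicator.

Descriptive companions: weighted Kaplan-Meier curves per SLC on [0, 60]
months (weights in both event and at-risk sums; living children censored at
min(attained age, 60)), and a Cox proportional-hazards fit stratified by
zone × urbanicity with robust variance, reported as hazard ratios.

## The Mendelian decomposition (γ)

An SLC is a genotype mixture. For each full-sibling group, the 21 unordered
parent-pair states get a prior from HWE individual genotypes with the SS/SC
probabilities multiplied by a survival-to-parenthood factor `f_scd`
(default 0.5) and renormalised before independent pairing; the likelihood is
the product of Mendelian transmission probabilities of the tested members'
genotypes; the posterior is the Bayes update. An untested sibling's genotype
distribution is the posterior mixture of Mendelian offspring distributions,
collapsed to classes (AA, Trait, SCD) and renormalised over not-Other.

The composition matrix $M$ averages these class probabilities over the older
cohort's members within each SLC, weighted by sample weight (tested members,
which cannot occur in the older cohort by construction, would contribute
point masses). With $\gamma_{AA} \equiv 0$, expected label-level excesses
are $\beta_s = \sum_g (M_{sg} - M_{AA,g})\gamma_g$ for $s, g \in$
{Trait, SCD}: a 2×2 linear system solved directly. This reference-coded
row-difference solve is the only formulation consistent with β being an
excess over the AA SLC; the condition number of the difference matrix is
reported, and a determinant below 1e-10 raises with diagnostics.

The AA-genotype baseline is recovered as the AA-SLC crude rate minus the
solved excess contributions of that label's non-AA members
($m_{AA} = \mathrm{crude}_{AA} - M_{AA,T}\gamma_T - M_{AA,S}\gamma_S$); the
naive AA-SLC crude rate is reported alongside, since both conventions are
defensible. Then $m_{SCD} = m_{AA} + \gamma_{SCD}$, the relative risk is
their ratio, and burden shares are
$\text{total} = \mathrm{prev}\cdot m_{SCD}/m_{\text{overall}}$ and
$\text{excess} = \mathrm{prev}\cdot\gamma_{SCD}/m_{\text{overall}}$ (×100),
with absolute annual excess deaths available when a national under-5 death
count is supplied.

### Uncertainty

A single end-to-end stratified cluster bootstrap: every replicate resamples
clusters within strata and recomputes allele frequencies, the parent-pair
prior (national frequencies re-estimated from the resampled tested
children), all family posteriors, $M$, β, γ, baselines and burden shares.
Optionally `f_scd` is redrawn per replicate from Uniform(0.2, 0.8) —
centring the survival-to-parenthood assumption at 50% with generous
bounds — to propagate that prior uncertainty. Replicates with a singular
composition system are dropped and counted; more than 10% drops triggers a
warning. Inside replicates β comes from the WLS fixed-effects fit: the
resampling itself carries the cluster correlation, only the point value is
needed per replicate, and the two estimators agree to well under 1 per 1000
at the survey's size; the full-data point estimate uses the complete ladder.
The replicate computation is organised so a replicate is a few small matrix
products: per-cluster allele counts, regression Gram matrices and weighted
class-probability aggregates are precomputed once, and cluster resampling
only changes per-cluster multiplicities.

### Conditioning choices

Posteriors condition on the tested full siblings' genotypes only — not on
their survival to testing age (handled instead by restricting inference to
the older cohort), and not on half-siblings' genotypes (half-siblings share
one parent; folding them in would require a joint two-pair model for little
information). Both choices are conventions of this package where the
methodology is open; the half-sibling information still enters through the
labelling rules.

## The synthetic-data generator

`simulate_survey` emulates the structure the pipeline assumes, at the scale
of a national DHS: 74 strata in zone blocks × 19 clusters × 30 households
with a third selected for testing; zone-specific A/S/C frequencies patterned
on Nigeria's six geopolitical zones; a household contains an interviewed
mother with probability 0.66; mothers and fathers draw genotypes from HWE
thinned by `f_scd` = 0.5; births are Poisson (mean 3.9 per mother over 15
years, a Nigeria-like fertility level) at uniform offsets over 180 months;
children inherit one allele per parent. Under-5 death occurs with
probability $m_g/1000$ times a lognormal cluster frailty with mean exactly
one (so configured rates are the marginal truth; SD 0.3 on the log scale,
which implies a within-zone mortality ICC of roughly 0.013, a realistic
residual clustering level); death ages place 60% of under-5 deaths in
infancy, uniform within the pieces (only the binary under-5 outcome feeds
the main models). Testing applies to living children aged 6–59 months in
selected households, with optional misclassification (SCD reported as the
corresponding trait with probability 1−sensitivity, non-SCD as the
corresponding SCD genotype with probability 1−specificity; both default to
1 so recovery tests are clean). Household weights are lognormal around
stratum means, normalised to mean 1. A fraction of mothers (default 9%)
fail to match the test roster, emulating record-linkage loss; an optional
half-sibling rate creates polygynous households and fostered-out children to
exercise the half-sibling rules (off by default: monogamy).

These defaults yield ~10k tested children and ~27k children in the matched
modelling dataset, matching the scale of the survey the method targets.

What the generator does **not** emulate: real DHS weight construction
(weights capture dispersion only), migration, multiple births, assortative
mating, consanguinity, β-thalassaemia or fetal-haemoglobin modifiers, the
malaria-dependent fitness of trait carriers, and cause-of-death structure.
Passing closed-loop tests therefore demonstrates internal consistency of
the estimator under the stated sampling and inheritance model, not
robustness to those real-data departures.

A known property visible in simulation: because only living children can be
tested, families whose SCD child survived — disproportionately in
low-frailty clusters — are the ones that acquire the SCD label, which
attenuates the label contrast slightly relative to the configured truth.
The recovery tests bound this: across 50 simulated surveys at the default
scale the mean estimated SCD excess stays within 80 per 1000 of the
configured 370, and the bootstrap CI covers the truth in ≥90% of surveys.
The same mechanism operates in real surveys of this design; estimates
should be read as mildly conservative.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `f_scd` | 0.5 | relative probability | SCD survival to parenthood; thins SS/SC parents in the prior |
| `fitness_bounds` | (0.2, 0.8) | — | per-replicate uniform redraw of `f_scd` when enabled |
| `n_reps` | 1000 | replicates | cluster bootstrap size (200 in the heavier closed-loop tests) |
| `other_as_cc` | True | — | count "other" test results as CC in allele estimation |
| cohort windows | [6,60), [60,180), [0,180) | months | tested / older / KM cohorts |
| `m_aa`, `gamma_trait`, `gamma_scd` | 120, 0, 370 | per 1000 | generator mortality truth |
| `cluster_frailty_sd` | 0.3 | log scale | shared within-cluster mortality variation |

## Numerical choices and degenerate inputs

Distributions validate to sum 1 within 1e-9 and renormalise exactly;
composition rows must sum to 1 within 1e-9. A replicate whose resampled
allele frequencies make a family's evidence impossible under the prior
(e.g. a C-allele family when the resampled $p_C = 0$) falls back to a
likelihood-only posterior for that family rather than failing the
replicate. Empty SLCs raise in composition estimation; empty KM groups warn
and return empty curves; a Cox non-convergence is reported, not fatal.
Bootstrap results are bit-reproducible given (seed, n_reps, data) and
independent of row order; estimators are invariant to positive rescaling of
all weights. Deaths reported in whole years in real data should be mapped
to the interval midpoint (48–59 months → 54) before use; the generator
works in exact months so the main models only consume the binary indicator.

## Known limitations

- The survey design enters through weights and cluster resampling, not a
  full design-based variance; weights are treated as frequency weights in
  regression.
- The decomposition assumes equal mortality for a genotype class across
  SLCs and no interaction with region beyond the adjustment set.
- Half-sibling genotype information is used for labelling but not in the
  Mendelian posterior.
- The genotype classes (not the six genotypes) are the decomposition basis;
  survey-scale data are too sparse to separate HbSS from HbSC mortality.
- Real-data biases the generator does not emulate (test error defaults off,
  no consanguinity or assortative mating) mean closed-loop recovery is a
  necessary, not sufficient, validation.
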