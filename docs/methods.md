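# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical machinery, and the design choices that were genuinely open.
Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## The estimation problem

Two survey streams describe adult (30+) hypertension in a set of counties:

* an **examination survey**: measured systolic blood pressure (SBP),
  self-reported diagnosis/medication, individual covariates, design
  weights — but no geography;
* a **telephone survey**: the same self-report variables plus county and
  year — but no measured SBP.

County-level prevalence, awareness, treatment, and control all hinge on
*uncontrolled hypertension* (SBP ≥ 140 mm Hg), which the telephone survey
never observes, and on county sample sizes that are often far too small for
direct estimation. The pipeline therefore (1) transports a measurement
model from the examination survey into the telephone survey by multiple
imputation and (2) smooths the imputed county data with a spatio-temporal
hierarchical model.

The systolic-only threshold is used throughout: the hypertensive population
is SBP ≥ 140 and/or current antihypertensive medication; control is
SBP < 140 on medication. Diastolic pressure is not modelled. Outcomes nest
by definition (controlled ⇒ treated ⇒ aware ⇒ in population), with
awareness defined as *in population and previously diagnosed* — this keeps
aware ≥ treated ≥ controlled as identities; a literal reading of the usual
definition table (awareness requiring current uncontrolled BP) would break
the nesting, so the nested convention is adopted.

## Stage 1 — bias correction

Four logistic models, one per sex × previous-diagnosis stratum, with terms
intercept, age, age² (age centred at 55, scaled per decade), race dummies
(white reference), BMI (centred 28, scaled per 5 kg/m²), insurance, and —
in diagnosed strata only — medication plus medication × wave dummies (first
wave reference), encoding a time-varying treatment effect. Fits are
weighted maximum pseudo-likelihood (statsmodels GLM with variance weights);
weights are normalised within stratum to sum to the stratum sample size so
the pseudo-likelihood does not overstate its information; the reported
covariance is the HC0 sandwich. Quasi-complete separation (any |β̂| > 15 on
the logit scale) raises an error naming the offending term; strata need at
least 10 events and 10 non-events. Records with missing covariates are
dropped with a logged count.

**Imputation.** The coefficient posterior is approximated as
MVN(β̂, Σ̂_sandwich) — the standard asymptotic approximation; no Bayesian
refit is attempted. Per imputed dataset (M = 10 by default) one coefficient
vector is drawn per stratum, each phone record's probability is evaluated
(mapping its survey year to the nearest examination wave), and its
uncontrolled flag is a Bernoulli draw. One draw per dataset — not per
individual — is deliberate: it preserves between-imputation parameter
uncertainty, which per-individual draws would average away. Draws are kept
on the dataset object for audit.

**Holdout validation.** k = 10 random 20% holdouts; models refit on the
remainder; held-out individuals classified uncontrolled at predicted
probability ≥ 0.5; accuracy is the proportion correctly classified, per
stratum and pooled, with all replicate values reported. Holdout refits use
a weakly ridge-stabilised weighted logistic (λ = 1e-6 on the mean negative
log-likelihood) rather than raw IRLS: on regular data the penalty is
numerically invisible, but on separable data it makes the decision boundary
converge to the max-margin split instead of whatever direction saturated
IRLS last wandered into. The sandwich-covariance GLM path is unaffected.

## Stage 2 — small-area model

Imputed individuals aggregate into county × year × sex × age-group × race
binomial cells. Denominators follow the outcome: all adults for self-report
and total prevalence; the hypertensive population for awareness, treatment,
and control. Per sex and outcome:

logit p_cell = α + Σ age dummies + Σ race dummies + x_c'β
               + u_c + v_c + δ_t + γ_c·t̃

* **u_c** — proper CAR: u ~ N(0, σ_u² Q⁻¹), Q = D − ρA with ρ = 0.95 fixed
  and the covariance rescaled to unit mean marginal variance, so σ_u is a
  typical marginal SD; requires a connected county graph (checked, with the
  component count reported on failure).
* **v_c** — iid N(0, σ_v²); together with u this is the usual
  spatial-plus-heterogeneity decomposition.
* **δ_t** — first-order random walk over years, centred.
* **γ_c** — iid N(0, σ_γ²) county slopes on standardised year t̃.
* **x_c** — county covariates (education, income, poverty, restaurants /
  doctors / dentists per 100k), z-scored across counties.

Fixed effects have N(0, 5²) priors; the four scales σ have half-normal
priors (scales 1, 1, 0.5, 0.2 for u, v, δ, γ). All random-effect blocks are
sum-to-zero centred and sampled non-centred; centring resolves the
intercept/level confounding among α, v̄, δ̄ and between mean slope and the
walk. Every structural block is a config switch, so the model collapses to
exchangeable or non-spatial variants; with a single county or year the
corresponding blocks switch off automatically. Exact model algebra beyond
the verbal description "grouped logistic spatio-temporal hierarchical
model" was an open design point; the BYM-style structure above is this
package's declared choice, and the four outcomes are fit as independent
models per sex (auditable, simplest).

Cells are fit **per imputed dataset** and posterior draws pooled
afterwards, preserving between-imputation variance; survey weights are not
used inside stage 2 (weighting enters through post-stratification).

**Sampler.** No probabilistic-programming backend is used; the posterior is
sampled by the package's own HMC: analytic gradients, static trajectories
with jittered length (half to `max_leapfrog` = 24 steps), dual-averaging
step-size adaptation to 0.8 acceptance, and a diagonal mass matrix
estimated from the second half of warmup. Defaults: 2 chains × 500 warmup +
500 draws — sized for the ≤ 200-county problems in the tests; scale up via
config for larger worlds. Split-R̂ and bulk ESS (arviz) are recorded for
every parameter; max R̂ > 1.05 triggers a quality warning, and trajectories
with energy error beyond 500 count as divergences. A Gaussian-target test
suite covers the sampler itself.

## Post-estimation

Age standardisation is a fixed convex combination of age-group draws
against a standard population (weights must sum to 1 within 1e-9); race
weighting is the analogous combination with county race shares. Both apply
per draw, hence commute and stay inside [min, max]. The synthetic world
supplies its own standard population and race shares; real standard-
population tables enter as config inputs, never bundled data.

Imputation pooling concatenates draw arrays across imputations and reads
medians and equal-tailed 95% intervals off the pooled draws — the
draw-level analogue of nested-imputation combining, chosen over
moment-based rules because draws are available and probabilities are
bounded; a moment-based (within + (1+1/M)·between variance) cross-check is
provided. County summaries report the median and min–max range across
counties (the "range" convention for summary tables), in percent to two
decimals; within-state spread is max − min of county point estimates per
state, flagged when a state has a single county.

## Validation framework

The reference for county comparisons is a **pooled gold standard**:
design-weighted county proportions pooled over a window of years, excluding
counties below `min_n` = 50 pooled observations (configurable). Model
predictions for the central year of the window (the alignment rule is
declared, configurable) and single-year direct estimates are both scored
against it by RMSE and **Lin's concordance correlation**
(2s_xy / (s_x² + s_y² + (x̄−ȳ)²), population 1/n moments; a sample-moment
variant exists), overall and within county-sample-size bins; bins with
fewer than three counties are flagged. CCC ≤ |Pearson r| always; both
metrics are symmetric.

## Synthetic world

The generator is the package's stand-in for the restricted microdata and
defines the default study conditions:

* counties on a near-square rook-adjacency grid (connected by
  construction); states as contiguous grid blocks;
* county effects = 0.7 · (0.3 · standardised proper-CAR draw) + 0.3 ·
  (0.1 · iid normal) on the logit scale, i.e. mixing weight 0.7 toward the
  spatial component, plus a mild secular trend of −0.02 logit/year;
* one covariate generator for both surveys (ages drawn from the same
  age-group shares as the county population tables — 22/21/20/17/12/8% for
  30s through 80+, uniform within group; race 70/11/13/6%; BMI ~ N(28.5,
  5.5²) clipped; insurance and diagnosis logistic in age/BMI/race;
  medication only among the diagnosed), so the stage-1 transport assumption
  holds *by construction*;
* truth coefficients follow the qualitative epidemiology (risk rising
  nonlinearly in age, higher in black adults, BMI effects among the never
  diagnosed, protective insurance and medication, medication improving
  across waves) at conventional logit magnitudes;
* design weights log-normal with CV 0.5, normalised to the sample size —
  unequal selection without a full complex design;
* SBP is generated to agree exactly with the latent uncontrolled indicator
  (gamma-distributed offsets on either side of 140);
* the telephone sample's latent uncontrolled truth lives in a separate side
  table that pipeline stages never read — only tests and validation code
  touch it.

What passing tests therefore show: the estimators recover *this* data-
generating process — correct transport, calibrated imputation, shrinkage
that beats direct estimates under sparse sampling. What they cannot show:
robustness to transport violations between real surveys (mode effects,
nonresponse, self-reported BMI error), real multistage cluster designs, or
real county geography; none of these are emulated.

## Experiment sizes and stochastic margins

The benchmark experiments (in `countybp.experiments`, shared verbatim by
the tests and the reproduction script) use: 150 replicates × 20,000 per
stratum for coefficient-recovery coverage (150 rather than the minimal 50
keeps each per-coefficient coverage estimate's binomial noise far from the
0.88 acceptance bound — at nominal 95% coverage a single coefficient dips
below 0.88 with probability ~1e-4 at 150 replicates, versus ~1.2% at 50,
which across 42 coefficients would fail a correct implementation in roughly
a third of runs); a 6,000-person world for the exact-accuracy threshold
rule (integer ages, and the fitted model carries exactly the rule's terms —
with extra covariates the separating direction is non-unique and exact
holdout accuracy 1.0 is unattainable by any fitting procedure); 16 counties
× 3 years × 100 interviews for imputation calibration (M = 10); and 100
counties × 3 years × 10 interviews × 10 seeds for the shrinkage comparison,
with stage 2 run at county-year level (2 chains × 350/350). These sizes are
the package's chosen desk-scale defaults; config scales everything up.

## Known limitations

* The MVN coefficient posterior is asymptotic; with rare covariate patterns
  or small strata the imputation understates tail uncertainty.
* The CAR mixing parameter ρ is fixed (0.95), not sampled; σ_u/σ_v carry
  the spatial-vs-iid trade-off instead.
* Static-trajectory HMC mixes more slowly than NUTS on strongly varying
  posteriors; the R̂/ESS diagnostics are the guard — raise warmup/draws when
  they complain.
* Stage 2 ignores telephone-survey design weights inside cells (unweighted
  imputed counts); population weighting enters only through
  post-stratification. A weighted-cell variant would need an
  effective-sample-size correction and is left as a config extension.
* Single-chain fits cannot compute split-R̂ (reported as NaN); use ≥ 2
  chains for anything that matters.
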