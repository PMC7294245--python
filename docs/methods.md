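# Methods

This note documents the model implemented by `dcea`, the assumptions
behind each stage, the synthetic-data generator's scope, and the design
choices made where the methodology left room.

## Stage 1 — distributional net health benefit

Each intervention is described by aggregate cost-effectiveness inputs:
eligible population per year *A*, incremental benefit per use *B*
(DALYs averted) and incremental cost per use *C* (USD).  Subgroup
distributions come from survey estimators:

* **Prevalence shares D** — each subgroup's share of survey-reported
  cases of the linked condition.  *A·D_g* is the eligible population in
  subgroup *g*.
* **Uptake E** — care-seekers over cases, per subgroup; *A·D_g·E_g*
  people are treated, each gaining *B* (equal efficacy across subgroups
  is assumed; if the rich benefit more per use, pro-poor benefits are
  overstated).
* **Opportunity-cost shares F** — the distribution of public/church
  care episodes across subgroups, used as a proxy for who loses health
  when the budget is displaced.  Total cost divided by the marginal
  productivity of expenditure *k* ($ per DALY, base 61) gives the
  health opportunity cost; *F* allocates it.

Net health benefit is `NHB_g = A·B·D_g·E_g − F_g·cost/k`; conservation
identities (Σ eligible = A, Σ oc = cost/k) hold to 1e-9 relative and are
property-tested.

**Total-cost conventions.** Published programme budgets do not always
equal *A·C* (the packaged worked example's budget is $809,318 while
*A·C* = $359,697).  Three modes are exposed: `per_treated`
(*A·C·Σ D_g E_g* — cost only for delivered services; the pipeline
default, since undelivered services should not displace health),
`per_eligible` (*A·C*) and `fixed` (a supplied budget used verbatim;
the worked-example fixture pins its published budget this way).  The
full-coverage scenario sets every *E_g* = 1 and rescales a fixed budget
in proportion to treated persons.

**Imputation.** Interventions absent from the survey receive the mean
of the observed prevalence distributions (renormalised); missing uptake
entries receive the subgroup's mean uptake across observed
interventions.  Only missing entries are replaced — observed entries in
a partially missing uptake vector are kept, the minimal extension of
the whole-vector rule.  Imputed rows are flagged in all outputs.
Missingness is encoded as blank cells/NaN, never 0, so "no data" and
"zero uptake" stay distinguishable.

## Stage 2 — baseline HALE

Survey respondents report sibling deaths (all ages) and offspring
deaths (ages 0–35); the respondent's subgroup proxies the decedent's.
Deaths are binned in 5-year bands to 55 plus one 55–75 band; deaths
above 75 are discarded and the lifetable closes at 75 (an optional
terminal rate adds `l(75)/M` open-interval person-years instead).
Per-band subgroup death rates, normalised to a population-weighted mean
of one, scale a reference age-specific mortality schedule; a
`children_only` mode (offspring deaths to age 20) supplies the
alternative baseline for sensitivity analysis.  Subgroup-band cells
with no observed deaths keep factor 1 (logged), and the remaining
factors are renormalised.

Lifetables use mid-interval deaths (`nax = n/2`) in every band,
including infancy — a documented simplification; with it,
`nqx = n·nMx / (1 + (n/2)·nMx)` and `nLx = n·(lx + l(x+n))/2`.  A fine
sub-banded table converges to the constant-hazard closed form
`(1 − e^(−75μ))/μ` to 1e-6, which the tests assert.

YLD (years lived with disability) enters as a dimensionless proportion
of band person-years.  The population YLD rate per band is split across
subgroups in proportion to their share of reported disease over their
population share, preserving the population mean per band.  Sullivan
HALE is `Σ nLx·(1 − yld) / l0`; it equals life expectancy iff YLD is
zero and is linear in a constant YLD rate.

The reference mortality and YLD schedules bundled for end-to-end runs
(`SYNTHETIC_REFERENCE_RATES`, `SYNTHETIC_YLD_PROPORTIONS`) are
synthetic illustrative values — high infant mortality, rising adult
mortality — not estimates from any published source; real analyses
should supply their own schedules.

## Stage 3 — inequality valuation

Subgroups are evaluated as homogeneous blocks with population-share
weights (quintiles at 0.2 each by construction; residence at the census
85/15 rural/urban split).  The Atkinson EDE uses a log-sum-exp
formulation with `expm1`/`log1p`, so it is numerically continuous at
ε = 1 (geometric mean) to ~1e-14 and stable at high aversion (ε = 25).
ε = 0 returns the mean.  Properties verified by tests: EDE ≤ mean with
equality iff flat; the Pigou–Dalton transfer principle; and the
translation property — a uniform +c per person raises the EDE by at
least c (power means with exponent < 1 are superadditive) and at most
c plus the baseline cost of inequality.

An intervention's subgroup NHB is converted to healthy years per person
(dividing by subgroup population) and added to baseline HALE; ΔNHB and
ΔEDE are scaled by total population, and the inequality impact is their
difference.  Quadrants on the equity plane use strict positivity:
a zero coordinate counts as "not improving".  Priority orderings by
ΔNHB and by ΔEDE break ties by intervention name.

## Stage 4 — sensitivity scenarios

Scenarios are named lists of transforms, each touching a disjoint
input: flatten or tilt prevalence, uptake or opportunity-cost shares,
change *k* (37/116 $ per DALY), swap the baseline, change ε (2/25).
The ±10% tilt multiplies the two poorest entries by 1.1 and the two
richest by 0.9; sum-constrained vectors are then renormalised to 1
(the alternative, treating tilted shares as unnormalised rates, is
available via a flag), while uptake is clipped to [0, 1] without
renormalisation.  "Equal uptake" assigns each intervention its own
prevalence-weighted average uptake, preserving total utilisation —
which is why it leaves the package ΔNHB unchanged under the
per-treated cost mode.  Transforms are pure; the suite re-runs the base
case bit-identically afterwards, and tests assert that ΔNHB is
invariant to aversion and to opportunity-cost-share transforms.

## Synthetic survey generator

The generator emulates the *structure* of integrated household and
demographic surveys, not Malawi's actual marginals:

* Households carry a latent wealth score u ~ Uniform(0, 1); 15% are
  urban.  Asset ownership is independent Bernoulli given u with a
  logistic link over 40 staggered thresholds — a fine-grained,
  monotone asset index in the spirit of the International Wealth Index.
  The steep link (slope 100) keeps quintile misclassification well
  below one quintile width, which the parameter-recovery tests
  require.
* Illness is categorical per person (at most one two-week code), with
  quintile-specific probability = base × gradient, clipped to [0, 1];
  this preserves each disease's marginal probability exactly, so
  expected prevalence shares, uptake and opportunity-cost shares are
  available in closed form for recovery tests.  Default gradients are
  calibrated to the published population pattern: dominant-condition
  prevalence shares ≈ (0.36, 0.16, 0.23, 0.13, 0.12), uptake ≈
  (0.48, 0.39, 0.46, 0.49, 0.43), aggregate public-care shares ≈
  (0.24, 0.21, 0.20, 0.18, 0.16).
* One respondent per household reports sibling and offspring deaths as
  Poisson counts per age band with a 2:1 poorest-to-richest hazard
  factor by default.
* All randomness flows from the single configured seed.

What the generator does **not** emulate: survey weights and cluster
design (a simple random sample is drawn; the source surveys' design is
not public in the inputs used here), household demography beyond a
Poisson size distribution, reporting biases in self-reported illness,
and correlation between a respondent's wealth and that of their adult
siblings' own households.  Passing recovery tests therefore show the
estimators are consistent under clean sampling — not that real-survey
biases are handled.

## Numerical and degenerate-input choices

* Wealth quintiles are person-weighted (the target population is
  persons, not households); boundary ties break by household id.
* A subgroup with no cases yields a missing uptake entry (imputation),
  not zero; zero public-care episodes overall is an error since the
  opportunity-cost distribution would be undefined.
* Report tables round DALYs/persons half-up to integers and
  proportions to 2 d.p.; full precision is kept internally, and CSVs
  use 9 significant digits so manifest digests are platform-stable.
* Default problem sizes (4,000 households in the demo pipeline, 20,000
  in recovery checks averaged over 5 seeds, 73-intervention catalogs
  with 51 flagged in-package) mirror the scale at which the estimators'
  sampling noise is comfortably inside the documented tolerances.

## Known limitations

* Single-year horizon, no discounting, no within-subgroup
  heterogeneity in benefit per use.
* One inequality dimension at a time (wealth *or* residence); no joint
  wealth × residence analysis.
* Deterministic scenarios only — no probabilistic sensitivity
  analysis.
* The bundled mortality/YLD schedules are illustrative; subgroup HALE
  levels from the demo pipeline are not estimates for any real
  population.
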