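# Methods

`iemscreen` models the cost-utility and budget impact of expanding Thailand's
newborn-screening programme from Guthrie-test PKU screening to tandem mass
spectrometry (MS/MS) screening of six inborn errors of metabolism:
phenylketonuria (PKU), isovaleric acidemia (IVA), methylmalonic acidemia
(MMA), propionic acidemia (PA), maple syrup urine disease (MSUD) and multiple
carboxylase deficiency (MCD). All costs are 2013 THB; effects are life years
(LY) and quality-adjusted life years (QALYs).

## Decision tree

Each of 750,000 annual newborns is healthy or carries one disease at its
incidence (2.2 per 100,000 births for PKU down to 0.54 for PA). Screening
uptake is 97%. Under the expanded strategy, MS/MS (sensitivity and
specificity 1.00, 294 THB/sample) detects every screened case of all six
diseases; under current practice, the Guthrie test (sensitivity 0.985,
specificity 0.9995, 5 THB/sample) detects PKU only. A screened-and-detected
child is treated *early* (pre-symptomatically); everyone else presents
clinically and is treated *late*. Screen positives — true ones, and the false
positives the Guthrie test's imperfect specificity creates among unaffected
newborns — each incur one 2,349 THB confirmatory test. Unaffected newborns
follow an all-cause-mortality life course at utility 1.

## Markov cohort model

Affected children are followed in one-year cycles for 100 years. State
spaces: Well / Neurological / Dead for PKU, IVA, MSUD and MCD; MMA adds Renal
and Neurological+Renal; PA adds Cardiomyopathy and
Neurological+Cardiomyopathy. Dead is absorbing and complications are
irreversible.

Within a cycle, death is resolved first: the disease-specific probability and
the other-cause probability (from a bundled approximate Thai 2013 period life
table, life expectancy 75.1 years) combine as
`1 - (1-q_disease)(1-q_other)`. Survivors then acquire complications at
age-banded annual probabilities; where two complications exist, onsets are
independent, and the probability of entering the second complication from an
existing one equals the probability from Well. Costs and utilities accrue at
cycle start, discounted at 3%/year by `(1+r)^(-age)`; no half-cycle
correction is applied (full-cycle accrual matches spreadsheet practice in
this literature).

Disease-specific mortality:

* IVA, MMA, PA, MSUD — a Weibull baseline hazard with cumulative hazard
  `H(t) = lambda * t**gamma`, survival `S(t) = exp(-H(t))`, and per-cycle
  death probability `tp(u) = 1 - exp(lambda*(t-u)**gamma - lambda*t**gamma)`,
  evaluated from birth (the first cycle uses the limit form
  `1 - exp(-lambda*u**gamma)`). Coefficients are stored and sampled on the
  log scale, matching how registry-based regression output reports them.
* PKU — age-banded annual probabilities (0.00253/yr under age 10 up to
  0.113/yr from 60).
* MCD — no excess mortality over the general population.

Early treatment multiplies complication probabilities by their relative
risks (e.g. RR 0.02 for PKU neurological damage; 0 for MCD) and scales
disease mortality: a *reduction* r multiplies the death probability by
(1 - r) (20-25% for IVA/MMA/PA/MSUD, 100% for MCD), while PKU's factor 0.67
multiplies its age-banded probabilities directly. Other-cause mortality is
never modified. Late-diagnosed patients enter the model at birth with
baseline (RR-free) parameters; diagnosis timing acts only through the effect
sizes, not through delayed entry.

Costs per patient-year: inpatient care (first treatment year vs subsequent
years; PKU has no reported second-year inpatient cost and uses 0), outpatient
care, age-banded metabolic formula (printed ranges are interpolated linearly
per single year of age), pharmaceuticals, and — by complication status —
direct non-medical and productivity costs. Utilities are state-specific
expert-panel EQ-5D weights (0 for Dead). The first-year inpatient cost
applies to both pathways: the underlying cost study found no difference
between early- and late-diagnosed patients.

## Economic outputs

Per-newborn expected costs and effects of the two strategies yield
incremental cost (ΔC), ΔLY, ΔQALY, and ICERs in THB (and I$ at the 2013 PPP
rate of 17.79 THB/I$), judged against the Thai threshold of 120,000 THB per
QALY. Net monetary benefit at threshold k is `k*ΔQALY - ΔC`; the CEAC is the
fraction of PSA draws with positive NMB on a 0-3,000,000 THB grid in
10,000-THB steps, and the crossover is the first threshold where the
expanded strategy's probability exceeds 0.5.

## Uncertainty analysis

Every input is a `(family, mean, SE)` triple. PSA (default 1,000 draws)
samples beta distributions for probabilities and utilities (method of
moments; infeasible variances are rejected at load time), gamma for costs,
lognormal for relative risks, and normal-on-log-scale for the Weibull
coefficients; inputs printed without an SE are fixed, as are degenerate beta
means (0 or 1) and the RR of 0. Draws are independent across parameters (no
correlation information exists). Each draw re-runs both strategies; the
engine is vectorised over the draw axis, so 1,000 draws of the full model
take well under a second. The headline PSA ICER is the ratio of means
mean(ΔC)/mean(ΔQALY); the mean of per-draw ratios is also reported but is
unstable because single-draw QALY differences can approach zero. Interval
estimates are empirical 2.5/97.5 percentiles.

The one-way analysis uses thirteen grouped factors (incidences, complication
probabilities, relative risks, utilities, first-year inpatient+outpatient
cost, later direct medical cost, formula+pharmaceuticals, direct non-medical
and productivity costs by complication status, uptake, MS/MS unit cost). A
factor's members move simultaneously to the same 95% CI bound — mean ±
1.96 SE clamped to the distribution's support, or mean ± 50% for
formula/pharmaceutical costs, which carry no SE — while all other parameters
are sampled; the tornado ranks factors by the spread of the mean ICER
between bounds. The same seed is reused across factors and bounds so spreads
are not Monte-Carlo noise.

## Budget impact

Ten calendar years (2013-2022), undiscounted, inflated at 0.5%/year, payer
perspective. Screening budget: 750,000 births x uptake (ramping
0.80/0.85/0.90/0.95/1.00, then flat; status quo fixed at 0.97) x unit cost,
plus confirmatory tests for MS/MS screen positives. The 294 THB per-sample
MS/MS cost was itself built up from machine capital, maintenance, reagents
and labour, so machine equivalent annual cost is **not** added on top — doing
so would double-count capital; an annuitisation helper
(`equivalent_annual_cost`) and machine-cost settings exist for re-costing
scenarios (`include_machine_eac=True`). Guthrie positives are confirmed by
inexpensive phenylalanine quantitation rather than the MS/MS confirmatory
panel, so the status-quo screening budget is the bare screening product.
Treatment budget: for every incident cohort detected by the respective
programme, the survival-weighted expected *direct medical* cost
(inpatient + outpatient + formula + pharmaceuticals) at the cohort's current
age — the components the payer reimburses; societal components (productivity,
direct non-medical) stay in the cost-utility analysis only. Min/max
scenarios move the screening unit cost and all incidences to their 95% CI
bounds.

## Synthetic registry

The survival and complication inputs originate from a 119-patient
retrospective record review (IVA 23, MMA 20, PA 8, PKU 26, MSUD 32, MCD 10)
accrued over twenty years. The generator emulates that design: entry years
uniform over the accrual window (so administrative censoring times are
U(0, 20) years), Weibull death times by inverse-transform sampling,
complication onsets piecewise-exponential with annual hazard `-ln(1-p)` per
band (the onset year is then exactly geometric with per-year probability p).
Onset and death are generated independently, mirroring the cohort model's
independence assumption. What it does not emulate: hospital-level
clustering, diagnostic drift over the window, and any dependence between
complications and death — so parameter-recovery results validate the
estimation pipeline, not those aspects of real registry data.

Estimation back from records: the censored Weibull log-likelihood is
maximised by profiling out the scale (`lambda_hat = deaths / sum(t**gamma)`)
and optimising the shape in one dimension; standard errors come from the
observed information. The exponential special case is fitted alongside and
compared by AIC (ties resolved toward fewer parameters). Complication
probabilities are nonparametric: band-wise events / person-years, converted
to annual probabilities by `1 - exp(-rate)`. All-censored records (the
PKU/MCD situation) raise a no-events error rather than producing a fit.

## Numerical choices and degenerate inputs

* Probabilities produced by multiplying a sampled baseline by a sampled RR
  are clamped to [0, 1] with a counted warning (relevant only in extreme PSA
  draws).
* `tp(u)` uses `expm1` to stay accurate for small hazards; survival-identity
  checks hold to 1e-12 away from underflow (H(t) < 30).
* Parameter-file validation aggregates all schema violations into one error
  naming each offending key.
* Seeds: every stochastic entry point takes an explicit seed
  (`numpy.random.default_rng`); identical seeds give bitwise-identical
  results.

## Known limitations

* The published evaluation's spreadsheet internals are not fully
  recoverable from its printed inputs: the printed survival coefficients
  imply far less disease mortality than the printed per-patient life years
  (PA's coefficients give a *lower* hazard than IVA's, yet its printed
  survival is much shorter), and the strategy-level deltas cannot be
  decomposed from the per-disease table. This package computes everything
  from the printed inputs; per-patient QALY gains for PKU and MSUD, the PSA
  uncertainty interval, the direction of every sensitivity ranking and the
  budget rows reproduce well, while quantities dominated by the survival
  levels (ICER per LY, IVA/MMA/MCD gains, MMA/MCD cost differences) land
  outside the printed values. Both discounting conventions are emitted
  because the published totals mix them.
* Perpetual application of the age-banded annual complication probabilities
  (the open-ended last band applies for life) is the standard Markov
  convention but accumulates more lifetime complications than the published
  per-patient figures imply for the single-band diseases.
* No correlation between sampled parameters; no microsimulation-level
  heterogeneity; family/caregiver disutility and treatment non-adherence are
  out of scope.
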