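# Methods

## Model

`demsim` simulates one closed birth cohort (default birth year 1980) from
age 0 to a closing age of 100, in annual cycles.  Each individual belongs
from birth to one of four fixed risk groups — none, late-life smoking,
mid-life hypertension, both — and occupies one of seven states: cognitively
normal, MCI, mild, moderate or severe dementia, dead of dementia, dead of
other causes.  Stage transitions are unidirectional; an individual
experiences at most one transition per cycle, and "dementia onset" in the
reported outcomes is, by default, the entry into mild dementia
(`incidence_event="dementia_entry"`; entry into MCI can be counted instead
via `incidence_event="mci_entry"` — the literature is not explicit about
which transition an observed incident case corresponds to, so both are
supported).

Within each annual cycle events are applied in a fixed order, each hazard
`h` converted to a probability `1 − e^(−h)`:

1. other-cause death, hazard `RR_g^mort(a) · m₀(a)`;
2. dementia onset (normal → MCI) with hazard `RR_g^dem(a) · h₀(a)`, or a
   single stage progression with fixed annual probabilities;
3. dementia death with a stage-specific excess hazard.

The order is a modelling convention; it is documented because it defines
what the calibration closures mean (below).  Person-years use a half-cycle
correction: each year contributes the average of the start- and end-of-year
occupancy.

Exposure windows: hypertension RRs (both endpoints) act from age 40 onward
and persist lifelong — mid-life exposure with late-life consequences;
smoking RRs act from 65 onward.  Whether the hypertension *mortality* RR
should persist beyond 59 is genuinely open; it is a config flag
(`mortality_hypertension_midlife_only`, default off, i.e. lifelong).  Joint
exposure combines additively on the excess-risk scale
(`RR = 1 + Σ(RRᵢ − 1)`), the weaker of the usual combination conventions
(multiplicative would assume more).

The mortality RRs act on other-cause mortality only; dementia-stage
mortality is stage-specific and group-independent, so the life table
supplied to the model must be an *other-cause* table (a helper subtracts a
dementia-attributable share from an all-cause table).  This keeps dementia
deaths from being counted twice.

## Calibration

Calibrated parameters, per sex:

* **birth group fractions** — targets: survivor prevalence of smoking among
  those alive at 65–100, of hypertension at 40–59, of joint exposure at
  65–100, operationalized as person-year-weighted means over the window
  (how a cross-sectional survey aggregates ages);
* **baseline other-cause hazard `m₀(a)`** — target: the life table;
* **baseline onset hazard `h₀(a)`** — target: the population incidence
  schedule `H(a)` times the secular-trend multiplier.

The two hazard schedules are solved *exactly* during a single forward sweep
of the deterministic expected-value cohort model: at each age the alive
composition is known before the age is processed, so a Newton solve on
`Σ_g π_g (1 − e^(−RR_g m)) = q(a)` (and its incidence analogue on the
at-risk, cognitively normal survivors of the mortality step) closes the
target to machine precision, composition drift included.  Only the three
birth fractions need iteration; two optimizers are provided:

* `analytic` — a fixed-point loop rescaling the birth marginals by
  target/fitted prevalence ratios; converges in ~5 iterations to relative
  residuals below 1e−6;
* `ga` — a seeded real-coded genetic algorithm (tournament selection, blend
  crossover, Gaussian mutation with decaying scale, one-elite survival;
  population 100, 200 generations by default, early stop on objective
  1e−12) minimizing the sum of squared relative residuals.  It must reach
  1e−4 or a `CalibrationError` with diagnostics is raised.  The GA exists
  because group-size calibration in this model family is conventionally done
  that way; the analytic path is the fast default and both agree to better
  than 1e−3 on the default configuration (tested).

Scenario runs freeze the calibrated hazards and change only the birth
assignment: a reduction fraction `r` removes the factor from a fraction `r`
of its carriers, independently per factor (from the "both" group,
`r_s(1−r_h)` moves to hypertension-only, `(1−r_s)r_h` to smoking-only,
`r_s r_h` to none).  This is the simplest rule consistent with "reduce
prevalence, keep the risks of the still-exposed".

## Microsimulation and common random numbers

The stochastic engine simulates individuals in chunks with a counter-based
generator (Philox) keyed by `(master seed, sex, chunk)`.  Every individual
draws the same uniforms in every scenario: one latent-exposure uniform, two
removal uniforms, and three uniforms per year of age (drawn whether or not
the individual is still alive, so stream positions never depend on
history).  Scenarios act purely through a deterministic map of the latent
exposure — reduction `r` removes the factor when the removal uniform falls
below `r` — so the null scenario is bit-identical to the reference and
scenario differences contain no between-individual sampling noise.  Whether
the original analyses used common random numbers is not documented;
differences reported by this package are CRN-based.  Memory is
O(ages × groups × states); cohort size is limited only by time (10⁸
individuals are supported by chunked streaming; tests and the acceptance
script use 2×10⁵–6×10⁵, which the oracle-equivalence tests show is
sufficient because the deterministic engine provides the exact expectation
at zero Monte-Carlo cost).

## Outcomes

Per scenario: age-adjusted incidence (events per 100 person-years at risk;
the at-risk pool matches the counted onset event), age-adjusted prevalence
(% of alive person-years in the mild/moderate/severe states; MCI counts as
dementia-free), total cases (incident events — each individual at most
once), life years with and without dementia, lifetime risk at 65
(cumulative onsets after 65 over the dementia-free alive at 65), all also
by single year of age, and per-100 000-life-year differences that adjust
for the larger surviving population under risk reduction.  Age
standardization uses the *reference scenario's* person-year distribution
(at-risk shares for incidence, alive shares for prevalence), so the
reference's adjusted rates equal its crude rates and contrasts isolate the
scenario effect from the population-structure shift it induces.  No
standard external population is assumed; rate units are printed explicitly.
The crossover age — where the by-age case difference turns and stays
non-negative — is computed on a 5-year moving average (stochastic curves
flicker near zero) with the raw-curve value also reported.  A sub-85
restriction truncates person-years and events at the 85th birthday.

## Synthetic inputs: what they emulate, and what not

National life tables and cohort-study incidence curves are not
redistributable, so all analyses run on synthetic stand-ins:

* **Mortality**: Gompertz–Makeham hazard `a + b·e^(c·age)`, closed at 100.
  Defaults: Makeham term 5e−4/yr; slope `c = 0.14` — steeper than the
  classic period-table value (~0.1) because the emulated object is a
  *projected cohort* table, and projections rectangularize survival; level
  `b` fitted so the cohort's all-cause life expectancy (dementia mortality
  included) is 86.8 years for women and 84.1 for men, the values implied by
  the published reference-scenario life-year totals.  Male excess mortality
  enters through the lower target.
* **Incidence**: `h(a) = rate65 · 2^((a−65)/doubling)` above an onset floor
  of 40, zero below; doubling time 5.5 years; a linear secular decline of
  13% per calendar decade (the meta-analytic estimate for North
  American/European cohorts) anchored at 2015, which for a 1980 birth
  cohort flattens the effective old-age hazard — this decline is part of
  the emulated study conditions, not a free dial.  The default level is
  0.002/yr at 65; `DementiaModel.from_reference_matched` instead tunes the
  level so the *reference* lifetime risk of dementia at 65 matches the
  published 54.5% (women) / 35.5% (men).  Only reference-scenario
  quantities are ever tuned; every scenario contrast is a genuine model
  output.
* **Risk factors**: the packaged parameter table (prevalences with CIs,
  co-occurrence, dementia and mortality RRs with CIs) is shipped as a
  checksummed YAML fixture; hypertension prevalence reflects unmedicated
  hypertension, with the medication share carried for reference only.
* **Stages**: annual progression probabilities 0.25 (MCI→mild), 0.30
  (mild→moderate), 0.35 (moderate→severe) and excess mortality hazards
  0 / 0.05 / 0.10 / 0.20 per stage.  These are plausible natural-history
  defaults, not source-derived values — the upstream model that defined
  them is not publicly parameterized — and all are configurable.  A
  `collapsed` mode with a single dementia state exists for closed-form
  tests.

What the stand-ins do **not** emulate: the true age shape of sex-specific
incidence at the oldest ages (real male incidence flattens after ~90; the
generator is exponential-with-decline by construction), the exact
rectangularity of projected national tables, and calendar-period mortality
detail.  Consequently the model reproduces the *mechanisms* — calibration
closure, the life-extension offset, the case crossover at old age (88–90
for women here), compression of morbidity, the smoking-mortality sign
reversal in the sensitivity sweep — and the female elimination magnitudes,
but understates the male scenario effects: with the packaged parameters
alone, male smoking elimination lands at a case change of ≈0% (the
mortality offset almost exactly cancels the direct effect) and joint
elimination at ≈−2% rather than the published ≈−6%.  Passing tests
therefore certify internal correctness and the qualitative epidemiology,
not a quantitative reconstruction of the original male results.  For the
same reason the combined-elimination effect on adjusted rates is a few
percent *above* the sum of the single eliminations here, where the original
analysis found it slightly below: the sign of that interaction is governed
by the strength of the realized mortality offset.

## Numerical choices and edge cases

* Hazard↔probability conversions use `expm1`/`log1p` throughout; the
  per-age Newton solves start from the hazard-linear guess
  `−ln(1−q)/Σπ·RR` and converge to ~1e−15.
* The life table must close (`q = 1` at the top age); the solved baseline
  hazard is `inf` there and everyone alive dies of other causes in that
  cycle, before the onset step.
* Zero-mass groups, zero targets and empty at-risk pools short-circuit to
  zero hazards; occupancies are checked against the simplex every cycle and
  a violation raises `InvariantError`.
* All pipeline randomness derives from one master seed via named
  substreams (calibration / simulation / sensitivity); outputs carry no
  timestamps, so a rerun with the same config is byte-identical.

## Known limitations

Beyond the input fidelity noted above: no quality-of-life or cost
dimension; no within-lifetime exposure dynamics (group membership is fixed
at birth, scenarios re-assign at birth); no interval-censoring of
diagnosis; the univariate sensitivity sweep varies one parameter at a time
and does not explore joint uncertainty.
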