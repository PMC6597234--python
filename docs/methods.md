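# Methods

`dipsim` is a hybrid simulation model of diabetes in pregnancy (DIP) for a
small jurisdiction: a system-dynamics ageing chain carries the aggregate
female population, individually simulated agents carry latent metabolic
physiology and life-course state charts, and health-service contacts are
discrete events on each pregnancy's gestational clock. This note records the
model equations, the parameters that matter, the synthetic-data assumptions,
and the numerical and design choices.

## Population layer

The aggregate female population sits in 5-year age-band stocks (0–4 … 85+)
per risk group (standard / high-risk ethnicity). Flows are ageing
(stock / 5 years), per-capita exits (age-banded mortality plus
out-migration), and entries into the youngest band. Flows are rescaled when
they would overdraw a stock, so stocks stay non-negative; cumulative
entry/exit/budding counters make person conservation checkable to floating
precision at any time.

Women entering the reproductive window (15–49) are *budded*: removed from
the aggregate stock and instantiated as agents with sampled age, height,
initial BMI, and latent physiology. The default scope buds all reproductive-
age women (`bud_scope: all_reproductive`); `high_risk_only` reproduces a
design in which only high-risk women are individually simulated. Stocks are
real-valued; integer budding uses largest-remainder (for a requested count)
or stochastic rounding (for a rate), so expected person counts are
preserved. Children born to agents remain agents for life, which enables
intergenerational risk tracking; consequently aggregate entries default to
zero and the chain's child stocks only seed the first fifteen simulated
years of entrants. Only female babies become agents (male life courses play
no role in any model output), but every delivery is counted as a birth.

## Latent metabolic physiology

Each individual carries insulin sensitivity `S`, beta-cell function
`B ∈ [0,1]`, and cumulative dysglycemia exposure `E` (index-years).

* Sensitivity: `S = clamp(s_base · m_iv · exp(−k_bmi · max(0, BMI − 25)) ·
  preg_mult, s_min, 1)` with `preg_mult = 1 − ρ_preg · week/40` during
  pregnancy (ρ_preg = 0.5 at term) and `m_iv` the intervention
  physical-activity multiplier. The exponential link is the simplest form
  that is monotone, bounded, and spans the observed range of
  obesity-associated resistance.
* Glycemic index: `G = 1/(S·B)`, capped at `g_max = 6`; `G = 1` for a fully
  sensitive, fully secreting reference individual. Complete secretory
  failure returns the cap rather than dividing by zero.
* Exposure and beta-cell dynamics (explicit Euler, dt = 1 month):
  `y = max(0, G_chronic − g_thr)`, `E ← E + y·dt`,
  `B ← clamp(B + [r_regen·(1−B)·1(E < e_rev) − k_decay·y·B]·dt, 0, 1)`.
  Regeneration switches off once cumulative exposure passes the
  reversibility ceiling `e_rev` (1 index-year): newly impaired individuals
  can recover glycemic control, long-exposed individuals cannot. This is the
  mechanism behind the exposure-duration ordering of intervention
  effectiveness, and it is tested as such.

A deliberate split: the beta-cell update uses the *chronic*
(non-pregnant-equivalent) index `G_chronic` computed without the pregnancy
resistance ramp, while screening results, fetal exposure and adverse-outcome
draws use the circulating index including the ramp and any treatment
multiplier. The ramp is transient physiology lasting months; letting it feed
the decades-scale glucotoxicity loop would make two ordinary pregnancies
exhaust the reversibility budget of nearly every woman, which contradicts
the intended natural history. Similarly, glycaemic management after a
diagnosis (linear ramp to a 0.8 multiplier over four weeks) controls the
measured/fetal index but is not credited with slowing maternal beta-cell
decline.

Aetiological heterogeneity enters through three phenotypes — resistance-
driven (lowered `s_base`), secretion-driven (lowered `b_base`), mixed (both
moderately lowered) — with default mix (0.40, 0.25, 0.35) and lognormal
individual jitter (sd 0.05). Means 0.85/0.85/0.92 were chosen so that the
healthy-weight majority sits below the dysglycemia threshold while obesity
or an unfavourable phenotype can push the chronic index above it. A small
fraction (0.4%) is flagged type-1 at initialisation with `B` fixed low; no
type-1 mechanism is modelled.

## Weight dynamics

BMI is continuous: an age-dependent drift spline (growth in childhood,
slow gain through adulthood), a lifelong individual drift multiplier
(lognormal, sd 0.35 — persistent between-person heterogeneity, without
which in-run-born cohorts would converge to a far narrower adult BMI
distribution than the initialisation tables), Gaussian random-walk noise
(0.3 units/√year), postpartum retention (30% of a N(12,3) kg gestational
gain, converted via ΔBMI = kg/height²), and a secular trend. The secular
term is applied both per simulated year and as an entry-cohort offset
`s·(entry year − start year)`; together these make the age-specific BMI
distribution at age *a* in calendar year *y* equal `m₀(a) + s·(y − y₀)`
exactly, i.e. a genuine population trend rather than one that cohort
turnover cancels. Initial weight status is drawn categorically
(healthy/overweight/obese probabilities by age band and risk group, loosely
matching Australian female survey distributions), then a continuous BMI
within the category (obese: 30 + Exp(3), truncated at 45). Babies exposed
to dysglycemia in utero receive a 0.9 multiplier on `b_base` and a 1.3
multiplier on childhood BMI drift — implemented as a drift (not a setpoint
shift), an interpretation noted as such.

## Life course and services

Conception follows age-banded annual hazards (TFR ≈ 2); gestation is fixed
at 40 weeks; postpartum lasts 26 weeks. Screening is universal (routine
OGTT at week 26) or selective (adds a week-12 early screen for women
meeting the five-item high-risk rule: high-risk ethnicity, age ≥ 40, prior
GDM, family history, BMI ≥ 35 — a config-editable approximation of the
published clinical criteria). Attendance (default 95%) is drawn per
(agent, pregnancy, test) from counter-based keyed streams, so changing one
policy lever perturbs only the draws it logically touches — the
common-random-numbers contract that makes scenario deltas meaningful. The
OGTT is a deterministic threshold on the latent index; the threshold is a
piecewise-constant function of calendar year, which is how a
diagnostic-standard change produces an artefactual step in incidence with
no change in underlying physiology. Adverse perinatal outcomes follow a
logistic in mean pregnancy glycemic index (p_min 0.05, p_max 0.45, k 4,
midpoint 1.8). Service events carry unit costs; tallies are additive.

A legacy comparator aetiology (`etiology: risk_count`) replaces the latent
physiology with a linear probability in the count of risk flags and a
single Bernoulli draw per pregnancy — useful for demonstrating what the
mechanistic model adds (exposure memory, counterfactual pathways); the two
aetiologies are mutually exclusive per run.

## Clock, determinism and the event log

Fixed monthly steps drive the chain, BMI and metabolism; pregnancy
milestones and service events are detected as crossings of each pregnancy's
gestational clock within the month and recorded at their exact continuous
times, with the log ordered by (time, agent id, kind). An earlier design
used an explicit priority queue; crossing detection preserves the same
deterministic ordering contract at a fraction of the cost, which the
calibration budget needs. The per-agent arithmetic is fused into a single
compiled kernel (numba) with a vectorised numpy twin kept in lockstep by an
equivalence test; mortality is drawn annually. A run is a pure function of
(config, seed); the event log is the source of truth for all event-derived
annual statistics (births, diagnoses, incidence, outcomes, service
counts), and weight-category proportions and the age structure come from
year-boundary snapshots of the underlying BMI (intervention offsets are
reported through incidence and outcomes, not through the snapshot
categories).

## Scenario, calibration and sensitivity

The shipped baseline emulates a jurisdiction of 10,000 women (20% high-risk
ethnicity), simulation start 1982, 26 burn-in years, reporting 2008–2017.
Burn-in this long is needed because agents initialise with `E = 0`: by 2008
essentially every mother has lived her adult life inside the simulation, so
the reporting window is free of cold-start composition transients. The
pre-change diagnostic threshold (5.0) sits at the upper few-percent tail of
the simulated screening-week index distribution — under the old standard the
captured group is dominated by severe/pre-existing diabetes, consistent
with a ~6% baseline among births; the 2013 standard change (threshold a
free parameter, bounds 2.6–5.5) broadens the captured group.

Calibration minimises the replicate-averaged sum of squared differences
between simulated and observed DIP fractions at the anchor years
(6% in 2008, 16% in 2016). Three free parameters span the behavioural and
artefactual trend drivers: secular BMI drift (0–0.15 units/yr), beta-cell
decay rate (0.01–0.3 /index-year, log scale), and the post-change
threshold. The optimiser is Latin-hypercube screening (55% of the
evaluation budget, incumbent included) followed by bounded Nelder–Mead from
the best point; replicate seeds are derived deterministically from the
master seed and shared across evaluations (common random numbers smooth the
loss surface). The calibrated behavioural-vs-artefactual split is reported
but cannot be verified from administrative data alone. One-at-a-time
sensitivity reports elasticities of final-year incidence, sorted into
tornado order. The readiness report scores anchor agreement (±1.5
percentage points, the ~2σ Monte-Carlo noise at this population scale) and,
when references are configured, L1 distances for weight-category
proportions and age structure; missing references are marked "not
assessed".

## Problem sizes and runtimes

Default experiments use 10,000 initial women, monthly steps over 36 years
(~0.8 s per run after kernel compilation). The headline calibration is 200
evaluations × 5 replicates (~13 minutes single-core). Unit and property
tests use 1,500–5,000 women. The parameter-recovery experiment uses 3,000
women, three target years and 10 replicates per evaluation.

## What the synthetic population does and does not emulate

The generator produces a census-style age × ethnicity table with a plausible
pyramid and exact multinomial totals. It does not include migration age
profiles, partnership/parity structure, socioeconomic gradients,
breastfeeding effects, twin births, pregnancy loss, preterm delivery, or
maternal mortality; male agents are not simulated. Passing tests therefore
show internal consistency of the mechanisms and the calibration machinery
under these stylised conditions — not predictive validity for any real
jurisdiction. Under-ascertainment in administrative data (a known quality
concern) is not modelled.

## Numerical choices and degenerate inputs

Explicit Euler at dt = 1/12 year (all rates are slow relative to a month; a
convergence test shows halving dt moves a 5-year beta-cell trajectory by
< 1%). State-classification boundaries are inclusive on the upper state
(G = g_dm classifies as diabetes; test results at exactly the threshold are
positive). BMI has a floor of 10; `B = 0` returns the capped index. Zero
births in a year reports a null incidence fraction, not zero. Config
validation collects and reports all errors at once. Ties in the event log
break by (time, agent id, kind code).

## Known limitations

Insulin treatment is a within-pregnancy multiplier only; whether and how
its effect differs outside pregnancy is left open. Bariatric surgery and
diabetogenic medications are named intervention classes without mechanisms
and are not implemented. Health-care workers are not agents; services have
no queues or capacity constraints. Effect sizes for interventions are
scenario inputs, not estimates.
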