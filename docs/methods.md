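# Methods

## Study design emulated

The pipeline reproduces a retrospective open-cohort design on linked
primary/secondary-care records: children aged 0–17, observed between
1 April 2007 and 31 July 2017, contrasted by exposure to maternal
mental illness (MMI). Follow-up per child starts at the latest of
birth, practice up-to-standard (UTS) date, registration date and study
start, and ends at the earliest of transfer-out, 18th birthday, child
or mother death, practice collection end and study end. Children are
excluded without HES linkage, with under 30.5 days of in-study
follow-up, or when the mother was not UTS-registered at the child's
start of follow-up or lacks 2 years (730 days) of registration either
side of it (the window needed to ascertain exposure). Exclusions are
applied in that fixed order, so each child is tallied under the first
rule it violates.

All date intervals are half-open `[start, end)`; a boundary day belongs
to the older band and no person-time is counted twice. Person-years
use the 365.25-day year; 18th birthdays and band boundaries are
calendrical, with a 29 February anniversary mapped to 28 February in
non-leap years.

## Phenotyping

A mother is a case of an illness group through (a) any diagnosis
event, (b) a prescription within 91 days — inclusive, and by default
in either direction — of a same-illness symptom (qualifying on the
later date of the pair), or (c) a prescription or symptom with any
strictly earlier same-illness diagnosis. "Three months" is fixed at 91
days; the window direction, width and whether pathway (b) qualifies on
the prescription date are arguments, because record timing conventions
differ between databases. Historical look-back is unbounded within the
available record. Unknown codes are ignored and counted rather than
fatal: code lists in the wild are always incomplete.

Illness groups roll up to exposure categories — CMI (depression,
anxiety), SMI (non-affective/affective psychosis), addiction
(substance/alcohol misuse) and `any` (all eight; eating and
personality disorders appear only here). Categories are deliberately
not mutually exclusive.

A child is exposed for an age band when the mother has a case date in
`[band_start − 2 years, segment_end]` (closed). The window end uses
the child's actual censoring date rather than the nominal band end, so
classification never depends on unobserved time; a switch restores the
nominal band end. The sensitivity definition `[band_start − 2 years,
band_start)` ignores within-band exposure (a reverse-causation probe)
and is provably a subset of the main definition.

## Counting and costing

Healthcare use spans six outcomes. Same-type same-day events count
once; "same type" is resolved at the granularity costing
distinguishes: consultation × staff for primary care, the drug code
for prescriptions, the outcome alone elsewhere. When same-day
in-patient records collapse, the longest stay is kept so admissions
are not under-costed.

Costing joins each deduplicated event to the tariff row for its
calendar year: subtype unit costs for primary care, annual averages
for referrals/out-patient/A&E, drug-specific prescription costs
falling back to the year's average when no drug tariff exists, and
admissions by episode type with
`per_admission + per_bed_day × length_of_stay` for elective and
non-elective stays (the published wording supports bed-day dependence
without fixing the functional form; a pure bed-day variant is a
switch). Everything is CPI-adjusted to 2017 pounds via
`amount × index(2017)/index(year)`, which is invariant to rescaling
the index.

## Inference

Counts (or costs) per child × band segment are modelled by NB2
negative-binomial regression with log person-years offset, period
(calendar year the band started, categorical) and age band as
covariates, and a band × exposure interaction giving one log
rate-ratio coefficient per band. The pooled ("all ages") estimate
refits without the interaction. A single dispersion scalar α is
estimated by maximum likelihood (Var = μ + αμ²); fits start from
Poisson estimates and restart with a derivative-free method before
failing loudly. Standard errors are cluster-robust (Huber–White) on
the mother, which is what the shared-frailty data generating process
requires — the plain information-matrix SEs are demonstrably
anti-conservative here.

Adjustment for band and period matters beyond taste: because the
exposure window accumulates with age while baseline rates fall with
age, exposure prevalence and baseline rate are negatively confounded,
and the unadjusted two-group contrast is biased toward the null. The
calibration studies therefore fit the adjusted model.

Absolute differences come in two forms: the crude ratio-of-sums
difference in arm rates (matching the pounds-per-child-per-year
framing, and the input to extrapolation), and a model-standardized
difference — the person-year-weighted average of predicted rates over
a band's observed covariate rows with exposure switched on minus off.
CIs for ratios are Wald on the log scale; CIs for crude differences
use the mother-level bootstrap below. Bands with an all-zero arm are
reported with an explicit degenerate flag and undefined (not infinite)
ratios.

## Extrapolation

National annual excess = Σ over bands of cost-difference ×
MMI prevalence × number of children, so the estimate is linear in the
population table. Uncertainty comes from a cluster bootstrap:
mothers are resampled with replacement (children travel with their
mother; a resample can never split a sibship), the per-band crude cost
differences and the national total are recomputed per resample, and
the CI is `point ± 1.96 × SD(bootstrap totals)` — the normal
approximation — with a percentile option. The bootstrap is fully
vectorised (a multinomial weight matrix times a per-mother
band × arm sum matrix), so 1000 resamples cost one matrix product.
Resamples in which a band loses an entire arm are dropped and counted.

## Synthetic data generator

No public extract of the source records exists, so the generator
produces cohorts with the statistical features the estimators rely
on, and those features are what passing tests certify:

* **Sibship clustering** — a mother-level gamma frailty (mean 1,
  variance = `overdispersion`, default 0.5) shared by all her
  children, times a per-child gamma frailty (variance
  `child_overdispersion`, default 0.2). Counts are Poisson given the
  frailties, hence marginally negative-binomial and within-family
  correlated.
* **Exposure via the real pipeline** — raw coded clinical events are
  planted per case (one of the three pathways at random) and pushed
  through the actual phenotyping and window logic; the generator never
  writes exposure flags directly. Onsets cluster perinatally (70%
  within a normal spread of one year around the mother's first
  recorded delivery), reflecting the concentration of maternal mental
  illness around childbearing; sibling births follow 1–4 years apart.
* **Study conditions** — study window 2007-04-01 to 2017-07-31;
  per-illness maternal prevalences totalling ≈ 25% ever-cases;
  unexposed outcome rates per child-year anchored to the published
  overall arm rates (primary care 4.27, prescriptions 3.90,
  out-patient 0.76, in-patient 0.14) with an infancy-heavy age
  profile; exposure rate ratios per outcome defaulting to the
  published estimates (1.24–1.37); a log-linear period effect of
  0.02/year; 10% same-day duplicate events; registration dropout
  hazard 0.05/year. Note the exposed share of any one band's
  person-time (≈ 13–15% in infancy) is necessarily below the ever-case
  share, because a single onset date is captured by a 3-year window.
* **What it does not emulate** — disease natural history, real drug
  dictionaries or code lists, multiple registration spells, geographic
  or ethnic structure, and HES episode/spell construction. Passing
  tests therefore certify the estimators against the assumed
  generative structure, not against idiosyncrasies of real records.

`simulate_counts` is the generator's count layer alone (numpy
throughout, 365.25-day band boundaries, no event realisation), used
where thousands of Monte-Carlo replicates are needed; the full
event-realisation path is verified once against it by checking that
deduplicated pipeline counts reproduce the drawn counts exactly.

## Monte-Carlo study sizes

Calibration of the rate-ratio estimator runs 200 replicates of
5000-mother cohorts (true total-use ratio 1.27, frailty variance 0.5):
the mean estimated log-ratio is required within 2 Monte-Carlo SEs of
log 1.27 and CI coverage within [92%, 98%]. Bootstrap calibration
runs 300 outer replicates of 400-mother cost cohorts with 200
resamples each against the known generative national excess, same
coverage band. The brute-force phenotyping oracle runs on 1000
mothers with up to 100 events each. These sizes were chosen so the
whole suite runs comfortably on a single CPU while keeping the
Monte-Carlo error of each check well inside its tolerance.

## Known limitations

* Rate differences from an NB model are not uniquely defined; the
  marginal-standardization choice here is one of several defensible
  conventions, which is why the crude difference is always reported
  alongside.
* The band-specific estimates default to one interaction model;
  stratified per-band fits are available behind a flag and agree to
  Monte-Carlo accuracy on synthetic cohorts.
* Tariffs, CPI and population tables shipped by the generator are
  synthetic stand-ins with realistic orders of magnitude; national
  cost figures computed from them are illustrative, not accounting.
* Single registration spells are assumed per patient; cumulative
  multi-spell registration is out of scope.
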