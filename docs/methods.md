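# Methods

## Occupancy model

D2 receptor occupancy is tied to a plasma-level dose-equivalent `d` (mg/day)
by a saturating Emax relation, `occ = occ_max · d/(d + ED50)`, with
ED50 = 2.38 mg/day and `occ_max` = 100 % by default (`occ_max` is exposed as
a parameter for exploration). All patients are assumed stabilised at a
common trough occupancy of 80 % at randomization — the level at which
efficacy is near-maximal without severe extrapyramidal effects — and the
trough is varied to 75 % and 85 % in sensitivity re-runs.

Trajectories live on an integer daily grid (day 0 = randomization). This
resolution matches the daily covariate definition used by the survival
analyses; nothing downstream needs a finer grid.

* **Active injectable arms.** Randomization is taken to coincide with a
  scheduled injection, given at trough. Plasma then rises *linearly* to the
  steady-state peak over the time-to-peak (5 d for the 1-monthly, 28 d for
  the 3-monthly) and decays first-order (half-lives 37 d and 111.5 d) back
  to the trough over the rest of the dosing interval (30 d / 90 d),
  repeating indefinitely — i.e. steady state is assumed from day 0, with no
  further accumulation. The linear rise applies to the *plasma* level;
  occupancy follows through the Emax transform. The steady-state peak is
  pinned by requiring the post-peak decay to land exactly on the trough:
  `peak = trough_plasma · 2^((interval − t_peak)/t_half)`. With the default
  parameters the peak occupancies are 86.5 % (1-monthly) and 85.5 %
  (3-monthly), i.e. active-arm ranges of 80–86 % and 80–85 % after rounding
  to whole percent (the package compares such checkpoints after rounding,
  since they are conventionally reported as whole percents).
* **Placebo arms.** First-order decay from the randomization trough with the
  formulation's half-life. Because the Emax curve is concave, occupancy
  decays more slowly than plasma — an invariant the tests enforce.
* **Oral.** The active oral arm is modelled as a constant daily-average
  plasma level at the trough-derived value. Oral placebo washes out with a
  configurable half-life defaulting to 1 day, so occupancy collapses within
  days; for this reason oral trials are excluded from all occupancy- and
  rate-based analyses, and the oral `half_life_days` parameter affects the
  placebo arm only.
* **Rate of change.** The daily rate is the forward first difference of the
  occupancy series, assigned to the start day of each one-day interval; the
  final grid point repeats the last defined difference. Against the analytic
  chain-rule derivative of the Emax∘exponential composition, the forward
  difference agrees to within 1 % at the placebo curve's steepest point.

Deliberately out of scope: multi-compartment kinetics, absorption-rate
constants, and inter-individual pharmacokinetic variability — the model
assumes identical kinetics and a common starting occupancy across
participants.

## Trial simulator

The generator emulates a five-trial discontinuation program: arm sizes
159/144 (3-monthly), 164/170 and 205/203 (1-monthly), 105/102 and 65/71
(oral), totalling 1 388 participants. Follow-up horizons are 487 days for
the "up to 16 month" trials, 426 for "up to 14 months" and 365 for "up to
12 months" (30.4375 days/month, rounded), since the source designs specify
only month counts.

Each subject's relapse hazard over the day interval (d, d+1] is

    h(d) = h₀ · exp(β_g·active + β_occ·occ(d)/10 + β_rate·occ′(d) + β_int·active·d)

with the covariates taken from the subject's arm-level trajectory at the
interval's start day — exactly the alignment later used by the analysis, so
parameter-recovery studies are internally consistent. Event days are drawn
by discrete inverse transform: relapse occurs on the first day whose
accumulated hazard exceeds an Exp(1) draw (piecewise-constant hazard within
days). Dropout is independent exponential censoring rounded up to whole
days, and administrative censoring applies at the horizon; relapse wins
same-day ties.

Defaults, chosen once as a realistic discontinuation-trial regime:

* `baseline_hazard_per_day` = 0.005 — with the default occupancy effect this
  yields roughly 10 % relapse in active arms and 50–80 % in placebo arms
  over follow-up, in the range reported by paliperidone discontinuation
  trials (the oral placebo arms sit at the high end because occupancy,
  and hence protection, vanishes within days).
* `beta_occ_per_10pct` = −0.34 with all other effects zero — the generative
  analogue of the occupancy association the analyses estimate, used for
  parameter-recovery studies, not as a claim of truth.
* `dropout_hazard_per_day` = 0.0006 — about 20 % non-relapse dropout over a
  year. The source trial designs do not describe censoring mechanisms, so
  independent exponential dropout is a modelling convenience.

What the generator does **not** emulate: individual titration and
pharmacokinetic heterogeneity, pre-randomization enrichment/stabilisation
dynamics, informative dropout, or relapse-severity scales. Passing
recovery and calibration tests therefore demonstrate that the estimators
are correct under the stated generative model — not that the empirical
estimates from the original access-controlled patient data are reproduced.

## Survival analyses

**Counting process.** Subject records are expanded to daily (d, d+1]
intervals carrying that day's covariate values, then consecutive intervals
with identical covariates are merged. The merge is lossless: per-subject
exposure is preserved exactly and fits on merged and strictly-daily tables
agree to 1e-8 (enforced by test).

**Cox model (analyses i, iii, iv).** The start-stop partial likelihood with
the Efron tie correction is maximised by Newton iteration with step-halving
(convergence at score norm < 1e-9 or relative log-likelihood change
< 1e-12, max 50 iterations). Efron was chosen over Breslow because the
daily grid produces many ties. Risk-set sums are accumulated with
difference arrays over the sorted event times, making each iteration O(N)
in the number of intervals — this keeps 200-replicate simulation studies
within minutes on one CPU. A coefficient magnitude exceeding 15 on the
log-hazard scale triggers a separation diagnostic rather than a silently
divergent "estimate"; eventless tables and collinear covariates are
rejected. The solver is cross-checked in the tests against a dense
grid-search maximisation of an independently coded partial likelihood on
tiny instances and against lifelines' `CoxTimeVaryingFitter` on simulated
trials. Occupancy enters per 10 percentage points (configurable via
`occupancy_scale_pct`) so coefficients are on an interpretable scale; the
rate and the absolute occupancy are fitted in *separate* models, each
adjusted for randomization group.

**Case-base model (analysis ii).** The case series (all event
person-moments) is contrasted with a base series sampled uniformly over
observed person-time — subject chosen proportional to follow-up, day
uniform within follow-up, with replacement, default 100 base moments per
case — in a logistic model of case status on (group, day, group×day). Time
enters linearly on the log-hazard scale, matching a single interaction
coefficient summary. The sampling constant log(B/b) is absorbed by the
intercept and subtracted whenever an absolute log-hazard is reported, so
doubling the base ratio shifts the intercept by −log 2 and leaves the
slopes unchanged. With no interaction term the fitted group coefficient
agrees with the Cox log-HR within 5 % on large constant-hazard simulations.

**Pooling.** Per-trial coefficients are combined by DerSimonian–Laird
random effects (moment estimator with τ² truncated at zero; the default
estimator of the ecosystem this mirrors). Formulation moderation is tested
by a fixed-effect inverse-variance Wald chi-square across formulation
levels with all pairwise z contrasts; no small-sample (Knapp–Hartung)
adjustment is applied, keeping the test a plain Wald type. With a single
trial in a formulation the pooled value is the trial's own estimate.
Note that `statsmodels.stats.meta_analysis.combine_effects` does not
truncate τ² at zero, so the cross-check test compares on a heterogeneous
configuration where both definitions coincide.

## Pipeline

`run_full_analysis` always emits all four analysis blocks; a trial or
analysis that cannot be fitted (no events, single arm, separation) is
flagged with an explicit reason, never dropped silently. Statistical
significance is two-sided 0.05 throughout, with no multiplicity
correction. Reports are deterministic given (config, seed) apart from a
`created` timestamp. Sensitivity re-runs hold the subject records fixed
and regenerate only the covariate trajectories at each trough value, so
trough assumptions affect analysis covariates, never the simulated data.

## Problem sizes used in validation

Replicate-based studies use the full five-trial program (1 388 subjects)
with 200 replicates for parameter recovery and interval coverage; null
type-I calibration uses 400 replicates of a lighter five-trial program
(100 per arm, 365-day horizon); the Kaplan–Meier vs analytic-survival check
uses a single 50 000-subject placebo cohort (sup-norm tolerance 0.01,
comfortably above the ~0.006 binomial envelope at that size).

## Known limitations

* The steady-state peak formula is the single-exponential reading of
  "peak computed from trough, time-to-peak and dosing interval"; an
  explicit multi-dose superposition model could place the peak slightly
  differently.
* The occupancy coefficient's scale (per 10 points here) is a reporting
  convention; comparisons against estimates quoted on an unknown scale
  should be made by sign and significance, not magnitude.
* DerSimonian–Laird with k = 3–5 trials has the usual small-k limitations;
  the coverage bands asserted in the tests (≈95 % ± binomial noise) reflect
  its finite-k behaviour under homogeneity.
* Case-base day sampling is on the integer day grid; with hazards of order
  10⁻² /day or more the discrete-time approximation to the smooth-in-time
  hazard would begin to matter.
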