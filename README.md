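# occrelapse

Receptor-occupancy-driven relapse analysis for antipsychotic discontinuation
trials.

When patients with schizophrenia stop antipsychotic treatment, relapse risk
rises — but is the risk driven by *how fast* striatal dopamine D2 receptor
occupancy falls, or by the *absolute* occupancy level at any moment?
Discontinuation trials of three paliperidone formulations with very different
elimination half-lives (daily oral, 1-monthly and 3-monthly long-acting
injectables) let those two hypotheses be separated: after withdrawal, each
formulation traces a different occupancy time course, so rate and level
decouple across trials. `occrelapse` provides the modelling machinery for
this question, aimed at psychiatric epidemiologists and trial
methodologists:

1. **Occupancy trajectories.** Plasma dose-equivalents map to D2 occupancy
   through an Emax model, `occ = occ_max · d / (d + ED50)` with
   ED50 = 2.38 mg/day and occ_max = 100 %. Stabilised patients start at a
   trough occupancy (80 %, sensitivity 75/85 %). Active injectable arms follow
   a steady-state sawtooth — linear rise to the peak
   `peak = trough · 2^((interval − t_peak)/t_half)` then first-order decay —
   while placebo arms decay exponentially from the trough.
2. **Synthetic trial program.** A generator reproduces the structure of five
   placebo-controlled discontinuation trials (1 388 participants; two oral,
   two 1-monthly, one 3-monthly) with per-day relapse hazards
   `h(t) = h₀ · exp(β_g·active + β_occ·occ(t)/10 + β_rate·occ′(t) + β_int·active·t)`.
3. **Survival analyses.** Per-trial Cox models with the daily occupancy and
   its first derivative as time-varying covariates (counting-process format,
   Efron ties, authored Newton solver cross-checked against lifelines);
   case-base sampled smooth-in-time hazards for time-varying hazard ratios;
   DerSimonian–Laird random-effects pooling and Wald-type formulation
   moderator tests.

## Worked example

```bash
occrelapse trajectories --out traj/
# lai_1m: active occupancy spans [80.0, 86.5]%
# lai_3m: active occupancy spans [80.0, 85.5]%
# oral:   active occupancy spans [80.0, 80.0]%

occrelapse simulate --seed 17 --out data.csv
# wrote 1388 subjects (548 events) to data.csv

occrelapse analyze --data data.csv --seed 17 --out report/
occrelapse report --report report/report.json
# subjects: 1388  events: 548  trough: 80.0%
#   group: LAI pooled -2.034 (SE 0.167, p=5.15e-34)
#   occupancy: LAI pooled -0.406 (SE 0.065, p=4.27e-10)
#   rate: LAI pooled +0.363 (SE 0.296, p=0.22)
#   time_interaction: pooled interaction -0.0041 (SE 0.0014, p=0.00301)
```

Reading the output: active-arm occupancy peaks at 86 % (1-monthly) and 85 %
(3-monthly) before returning to the 80 % trough at each dosing time. The
simulated program was generated with an occupancy effect of −0.34 per
10 percentage points and no other effects; the analysis recovers a strongly
protective group hazard ratio (log-HR −2.03, induced entirely by the
occupancy gap between arms), a negative pooled occupancy coefficient
(−0.41 per 10 points, within sampling error of the generative value), a
rate-of-change coefficient compatible with zero, and a negative group×time
interaction (the protective effect strengthens as placebo occupancy keeps
falling). `occrelapse sensitivity` repeats everything at troughs 75/80/85 %.

The same analyses run on any patient-level CSV with columns
`subject_id, trial_id, formulation, arm, time_days, event`.

In Python, the fitting surfaces are model/results objects:

```python
from occrelapse import (default_formulations, active_trajectory,
                        placebo_trajectory, CoxTimeVaryingModel,
                        build_counting_process)

p = default_formulations()["lai_1m"]
traj = {"active": active_trajectory(p, 365), "placebo": placebo_trajectory(p, 365)}
table = build_counting_process(subjects, traj, ["group", "occupancy"])
res = CoxTimeVaryingModel(table, ["group", "occupancy_pct"]).fit()
print(res.summary())
```

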