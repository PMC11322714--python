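# walletrdd

Regression discontinuity in time (RDiT) for mobile-money health-wallet
utilization. The package estimates the causal effect of a COVID-19
lockdown on three binary person-day outcomes of a maternal mobile-money
wallet — savings, payments, and electronic voucher redemptions — from raw
transaction logs (or a calibrated built-in simulator), using modified
Poisson segmented regression with robust sandwich variance, data-driven
Imbens–Kalyanaraman (IK) bandwidth selection, counterfactual recovery
times, and age-stratified sensitivity analyses.

It is written for epidemiologists and health-economics analysts working
with interrupted service-utilization data where treatment switches on at a
known calendar date.

## Model

The unit of analysis is the person-day: a fixed cohort of *n* users
observed over *T* days yields an *n × T* dense binary panel per outcome
(days with no recorded event are structural zeros). For day *t* with
cutoff *c* (the first lockdown day), the daily event probability follows

```
log p(t) = β₀ + β₁ (t − c) + β₂ D(t) + β₃ (t − c) D(t),   D(t) = 1{t ≥ c}
```

fitted by Poisson regression (log link, IRLS) on person-days within a
symmetric bandwidth window |t − c| ≤ h. Because the outcome is binary, the
Poisson likelihood is misspecified; the "modified Poisson" device pairs it
with the heteroskedasticity-robust sandwich covariance B⁻¹MB⁻¹
(B = Σ μᵢxᵢxᵢᵀ, M = Σ(yᵢ−μᵢ)²xᵢxᵢᵀ) so that exponentiated coefficients
are valid incidence rate ratios (IRRs):

- `exp(β₂)` — IRR at the lockdown (the discontinuity),
- `exp(β₁)` — prelockdown daily trend IRR,
- `exp(β₁+β₃)` — lockdown daily trend IRR,
- `exp(β₀ − β₁·c)` — baseline IRR at the study start (running variable 0).

The bandwidth h is chosen by the IK plug-in computed on the daily
aggregate rate series with the uniform-kernel boundary constant
(matching the unweighted hard estimation window). Recovery time is the
closed form s* = −β₂/β₃: the days after the cutoff until the fitted
lockdown curve recrosses the extrapolated prelockdown counterfactual
(`999` encodes "never"). A containment stringency index (the 0–23 sum of
the eight OxCGRT containment-and-closure ordinals) verifies the cutoff
date from policy data.

## Worked example

```python
import walletrdd as w

panels, truth = w.simulate_panel(w.SimulationConfig(seed=1))  # 3416 users x 240 days
res = w.fit_rdd(panels["saving"], bandwidth_days=82)
print(res.summary())
```

```
Poisson RDD fit — outcome=saving, stratum=all
bandwidth=82 days, cutoff=day 82, users=3416
------------------------------------------------------------------------
quantity                           IRR                95% CI         p
IRR at baseline (day 0)         0.0094      (0.0088, 0.0100)         0
IRR at the lockdown             0.4434      (0.4082, 0.4816)   8.9e-83
IRR per day (prelockdown)       1.0113      (1.0100, 1.0126)   1.2e-65
IRR per day (lockdown)          1.0113      (1.0101, 1.0125)   6.2e-78
change at lockdown               55.7% decrease
p (slope change, robust) = 0.95
```

The simulated lockdown cut the daily probability of a savings event to
44% of its prelockdown level (a 55.7% decrease at this seed; the
generating IRR is 0.4152), daily trends on both sides are ≈+1.1% per day,
and `res.recovery()` reports no crossing of the extrapolated
counterfactual within 999 days — a negative jump with no slope gain never
recovers. `w.PoissonRDD(panel).select_bandwidth()` returns the IK window,
`res.sensitivity = w.sensitivity_scan(panel, h_opt=..., delta=20)` refits
across ±20 days, and `w.recovery_by_age(panels)` produces the
age-stratified (<25, 25–30, >30) recovery table.

The same analysis runs from the shell:

```bash
walletrdd simulate --n-users 3416 --seed 1 --out data/
walletrdd analyze --mode real-data --events-path data/transactions.csv \
    --registry-path data/registry.csv --output-dir runs/demo --seed 1
walletrdd report runs/demo
```

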