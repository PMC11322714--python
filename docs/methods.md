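# Methods

## Design and model

The package implements a regression discontinuity in time: calendar day
(zero-based from the study start, default 2020-01-01) is the running
variable, and treatment — a national lockdown — switches on at a known
cutoff day (default day 82 = 2020-03-23; the cutoff day itself belongs to
the lockdown side). For each outcome (saving, payment, voucher) the unit
of analysis is the person-day of a fixed cohort, with a dense binary
panel: y(u,t) = 1 iff user u had ≥1 event of that type on day t. The
fitted model for the daily event probability is piecewise log-linear with
a multiplicative discontinuity:

log p(t) = β₀ + β₁(t−c) + β₂D + β₃(t−c)D, D = 1{t ≥ c},

estimated on person-days within a symmetric window |t−c| ≤ h (pre side
t < c, post side t ≥ c, both ends inclusive of the window bounds).

Identifying assumptions are those of any sharp RDiT: the conditional mean
is smooth through the cutoff absent treatment, and nothing else changes
discontinuously on the cutoff day. The model assumes independence across
person-days given p(t); the variance is nonetheless estimated robustly
(below), so only the point estimates rely on the working likelihood.

## Modified Poisson estimation

Coefficients maximize the Poisson log-likelihood with log link via IRLS
(working weight μ, working response η + (y−μ)/μ), initialized at
β = (ln ȳ, 0, …, 0). Convergence requires the deviance change to fall
below 1e-10 × (|deviance| + 1); the unit floor lets an exact
(zero-deviance) fit terminate despite floating-point oscillation. The cap
is 100 iterations; non-convergence raises with the deviance trace.
Collinear designs are rejected, never silently repaired. A fitted mean
above 1 for a binary outcome (possible under the log link) produces a
warning, not an error.

Because a 0/1 outcome is not Poisson, standard errors come from the HC0
sandwich B⁻¹MB⁻¹ with bread B = Σμᵢxᵢxᵢᵀ and meat M = Σ(yᵢ−μᵢ)²xᵢxᵢᵀ.
HC0 is the default — with 10⁵–10⁶ person-days, finite-sample corrections
are immaterial — HC1 is a flag away, and a cluster-by-user sandwich is
available as a sensitivity variance (person-days within a user may
correlate; the headline estimator deliberately does not cluster). Wald
inference is normal-approximation: CI = estimate ± 1.959964·SE,
exponentiated to the IRR scale. The slope-change p-value is reported from
both the robust and the model-based covariance, since either convention
is defensible.

### Aggregation identity (computational core)

With day-level covariates only, the Poisson likelihood factorizes, so
fitting person-day binaries equals fitting daily event counts with a
log(cohort size) offset — coefficients agree to numerical precision.
The default engine therefore fits 2h+1 day rows instead of n×(2h+1)
person-day rows. The person-day HC0 sandwich is also recovered exactly
from day-level sufficient statistics: for binary y, Σᵢ(yᵢ−μ)² within a
day equals Yₜ(1−2pₜ) + n pₜ², with Yₜ the day count and pₜ the fitted
per-person rate. Both identities are standing tests (1e-8 and 1e-10).

## Bandwidth selection

The Imbens–Kalyanaraman plug-in is computed on the daily aggregate rate
series. For a fixed cohort this is numerically equivalent to running it
on person-day records — every step depends on the data only through
σ²/N-type ratios that match across the two representations. The recipe:

1. pilot window h₁ = 1.84·SD(t−c)·N^(−1/5); within it, the conditional
   variance σ²(c) (pooled residual variance around the side means) and the
   density f(c) of the running variable;
2. a global cubic with jump dummy (fitted between the side medians)
   estimates m‴(c); side-specific pilot windows
   h₂± = 3.56·(σ²/(f·m‴²))^(1/7)·N±^(−1/7) feed one-sided local
   quadratics whose second-order coefficients give m″±(c);
3. regularization r± = 2160·σ²/(N₂±·h₂±⁴) — exactly 3× the variance of a
   uniform-kernel local-quadratic curvature estimate, so the constant is
   consistent with the hard estimation window;
4. h = C_K·[σ²/(f·((m″₊−m″₋)² + r₊ + r₋))]^(1/5)·N^(−1/5), truncated to
   the available symmetric range and rounded to whole days.

C_K is derived from the boundary equivalent kernel of a local linear fit.
For the uniform kernel, K*(u) = 4−6u on [0,1], giving bias constant
C1 = 1/6, variance constant C2 = 4, and C_K = (2·C2/C1²)^(1/5) =
288^(1/5) ≈ 3.105 (the analogous computation for the triangular boundary
kernel reproduces the published 3.4375 once σ² is read as the sum of the
two one-sided variances, which validates the parametrization). The
uniform constant is used because the estimation stage weights the window
uniformly. A scale floor of 0.01 on m‴² that appears in some published
implementations is omitted: it presumes outcomes of order 1 and collapses
the bandwidth for rate-scale outcomes of order 0.01; the guard here is
only against an exactly zero estimate.

Two behavioral notes, verified by simulation and reflected in the tests:
the selector is scale-equivariant (multiplying all rates by a constant
leaves h unchanged, up to the variance-estimation channel), and on a
curvature-free series the selected h is *independent of the noise
amplitude* and sits well below the range cap — both the noise-driven
curvature estimates and the regularization scale with σ², so their ratio
is fixed. A regularized plug-in therefore never "opens up" to the full
window even when the truth is exactly linear; where the rate curve has
genuine curvature (the case the selector is designed for), the selection
tracks the brute-force MSE-minimizing bandwidth closely (within ~5% in
the validation simulation). An exactly constant series raises an error
advising a manual bandwidth. The analysis cutoff itself is always
configuration-supplied; `detect_cutoff` (first day with stringency index
≥ threshold) is a verification aid, not the cutoff definition, because
the cutoff is a known policy date.

## Recovery times

The counterfactual is the prelockdown segment extrapolated past the
cutoff; the log-rate gap at s days post-cutoff is β₂ + β₃s, so the curves
cross at s* = −β₂/β₃ when the jump and the slope change have opposite
signs and s* lies within the horizon (default 999 days, which doubles as
the "never" sentinel in tabular export). A bisection root-finder on the
gap is kept alongside the closed form and agrees to 1e-6 (standing test
over 1000 random coefficient pairs). The sentinel 999 is only ever
written for "never"; strata where the model cannot be fitted at all (no
events on one side) are flagged "inestimable" instead. Crossings are
computed from the same bandwidth-restricted fit and then extrapolated
beyond the window (refitting on all data is exposed as an option);
age-stratified fits reuse the pooled per-outcome bandwidth by default,
with per-stratum reselection behind a flag. As a coefficient ratio, the
Monte Carlo *mean* of ŝ* carries a finite-sample (Jensen) bias of order
s*·CV(β̂₃)²; the parameter-recovery test sizes its cohort so this bias is
well inside the Monte Carlo band.

## Stringency index

The eight OxCGRT containment-and-closure ordinals (codebook maxima
3,3,2,4,2,3,2,4) are summed to a 0–23 index per day. Geographic-scope
flag columns are ignored; only ordinal severity enters. Missing values
impute to 0 (least severe) with a logged warning and a per-day flag —
conservative and simple; carry-forward would require a judgment about
policy persistence the data should make, not the parser. Ordinals out of
bounds are hard errors naming the indicator and row. (Some published
descriptions state all indicators run 0–4; the heterogeneous codebook
bounds that produce the 0–23 range are used here.)

## Synthetic data generator

The generator emulates the study's structure: a fixed cohort (default
3416 users; 819,840 person-days per outcome over 240 days) with
independent Bernoulli event indicators whose probability follows the
piecewise log-linear model, using the published pooled estimates as
defaults (baseline/pre-trend/jump/post-trend IRRs — savings
0.0090/1.0124/0.4152/1.0113, payments 0.0026/1.0111/0.5412/1.0054,
vouchers 0.0051/1.0034/0.5047/1.0067). Ages are drawn from a log-normal
calibrated to median 26 and IQR 9 (the family is a free choice given only
those two statistics), rounded to integer years; groups <25 / 25–30
(closed interval, so the labels partition the integers) / >30. Per-group
overrides of any outcome parameter support heterogeneity experiments.
Wallet rules are enforced in generation and in ingestion: at most one
payment per user for the whole period (keep-first suppression — later
draws are zeroed, matching the deterministic system rule) and at most one
voucher per user-day (automatic under binarization). A configuration
whose implied probability reaches 1 on any day raises an error naming the
day rather than silently clipping.

Two person-day accounting conventions exist in cohorts with rolling
enrollment; the generator exposes both. By default every user is at risk
from day 0 (the fixed-cohort convention implied by n×T person-day
accounting). With `simulate_enrollment`, each user receives an enrollment
day uniform on [0, cutoff] and contributes structural zeros before it.
Note the published pooled rate parameters combined with a fixed cohort
over-predict the published raw event totals — the discrepancy is exactly
this denominator convention, which cannot be adjudicated without the raw
data; the default parameters are taken at face value as rates.

Deliberately absent from the generator: within-user correlation or
frailty, behavioral dynamics, facility-level structure, and seasonality.
Passing parameter-recovery tests therefore show that the estimator
recovers the generating process when its independence assumptions hold —
not that real wallet data satisfy them; the cluster-by-user variance
exists precisely because they may not. One stochastic subtlety: keep-first
payment suppression thins later payment events, making the realized
payment process slightly non-log-linear; the jump remains locally
identified, and recovery tests for payments use the published 55-day
window where the residual curvature bias is an order of magnitude below
the Monte Carlo band.

All randomness flows from a single integer seed through named
substreams (ages, enrollment, one per outcome), so identical
configuration and seed give byte-identical panels and pipeline outputs.

## Problem sizes in the test suite

Cohort-scale checks run 200 replicates at 3416×240 (parameter recovery,
bias < 3 Monte Carlo SEs and < 0.02 absolute on the log-jump) and 500
replicates at 1000×240 (95% CI coverage within [92%, 98%]); the
robust-SE-vs-empirical-SD comparison uses 400 replicates at 800 users;
bandwidth validation uses 150–500 replicates of 240-day rate series at
cohort-scale binomial noise. These sizes make each Monte Carlo band sharp
enough to detect the failure mode the test targets while keeping the full
suite in the tens of seconds.

## Known limitations

- No triangular-kernel local-polynomial estimation, bias-corrected robust
  (CCT-style) inference, fuzzy designs, or covariate adjustment.
- No inference on recovery times (a bootstrap would be natural but is out
  of scope); crossing times are point estimates only.
- The IK selector, being regularized, cannot select the full window on
  (near-)linear data even though the full window is MSE-optimal there;
  see the bandwidth section.
- Overdispersion modelling is intentionally absent: for binary outcomes
  the sandwich variance already covers the misspecification.
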