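# Methods

## Model

Weight `y` (kg) of calf *i* on farm *j* under veterinary practice *k*
at age `t` days (0–138) follows a three-level linear mixed model with a
quadratic fixed age effect and a farm-level random slope:

    y = α + β₁ t + β₂ t² + v_k + u0_jk + u1_jk t + e
    v_k ~ N(0, σ_v²),  (u0, u1)_jk ~ N₂(0, Ω_u),  e ~ N(0, σ_e²)

Ages enter in raw days (no centering), so α is interpretable as mean
birth weight and β₁ as growth rate at birth. The calf level carries no
random intercept: repeated measures on a calf are exchangeable given
its farm, and the calf-level variance is the residual σ_e². Strict
nesting is assumed and enforced (a calf belongs to one farm, a farm to
one practice).

Derived quantities follow from the fitted components. The farm-level
variance at age `t` is `σ_u0² + 2t σ_u01 + t² σ_u1²` (positive for all
`t` when Ω_u is positive definite); practice and calf variances are
constant in age. The variance partition coefficient (VPC) of a level at
age `t` is its variance over the total at `t`; the three VPCs sum to
one by construction, per draw and age. Instantaneous growth rate is
`β₁ + 2β₂ t`; cumulative growth rate from birth to horizon `h` is the
chord slope `β₁ + β₂ h`. Cluster-specific mean birth weight is
`α + v_k + u0_jk ~ N(α, σ_v² + σ_u0²)` across practice-farm
combinations, giving the Gaussian form of the 0.025–0.975 cluster
coverage interval `α ± 1.96 √(σ_v² + σ_u0²)`; for the cumulative rate
the only random contribution is the farm slope, `(β₁ + β₂h) ± 1.96
σ_u1`. An empirical alternative takes quantiles of the realised
cluster means across sampled farms per draw (it requires a chain run
with `store_random_effects=True`); it is provided because coverage of
realised clusters and coverage under the Gaussian model can differ
materially when the number of farms is modest, and the distinction is
not always recoverable from a published interval.

## Priors and sampler

Priors are the conventional noninformative choices for this model
class: flat on (α, β), Gamma(0.001, 0.001) on the precisions 1/σ_v²
and 1/σ_e², and Wishart(2, (2 S_u)⁻¹) on the farm precision matrix
Ω_u⁻¹, where S_u is the initialiser's frequentist estimate of Ω_u —
under this parameterisation E[Ω_u⁻¹] = S_u⁻¹. The notation
"Wishart₂(2S_u, 2)" admits more than one reading of the degrees of
freedom; we use df = 2 (the smallest proper value for a 2×2 precision)
with the scale chosen so the prior expectation matches the estimate,
which is the standard default-prior convention behind that notation.
With dozens of farms the posterior is dominated by the likelihood
(prior df 2 against one unit per farm), so the reading is not
consequential at the fitted scales.

The sampler is a systematic-scan Gibbs sampler; every update is an
exact conjugate conditional draw, in fixed order: (1) fixed effects
jointly from N((X'X)⁻¹X'r, σ_e²(X'X)⁻¹) with r the response net of
random effects; (2) practice intercepts from their shrunken-mean
normals; (3) per-farm (intercept, slope) pairs from bivariate normals
with precision Ω_u⁻¹ + Z_j'Z_j/σ_e² (2×2 algebra vectorised across
farms; Cholesky factors in closed form); (4) practice precision from
Gamma(a + K/2, b + Σv²/2); (5) residual precision from
Gamma(a + n/2, b + SSE/2); (6) farm precision from
Wishart(2 + J, (2S_u + ΣU_jU_j')⁻¹) via a 2×2 Bartlett decomposition.
With zero farms the Wishart conditional reduces exactly to the prior.
One seeded `numpy` Generator drives the run; draws are consumed in the
order above, so chains are bit-reproducible given the seed.

Initialisation: OLS for the fixed effects, then per-farm regressions of
the residuals on (1, age). The farm intercept estimates absorb both the
practice effect and the farm intercept; practice effects are recovered
as per-practice means of the farm intercepts, and farm effects as the
centred remainders. (Estimating practice effects directly from
practice-mean residuals is biased here: with a mean weighing age near
60 days a farm slope of u1 shifts its practice's mean residual by
roughly 60·u1, leaking slope variance into the practice level.)
Moment estimates of the variance components subtract the sampling
noise of the cluster estimates (var_e·(Z'Z)⁻¹ per farm) and correct
the within-practice centering factor (1 − 1/m) for m farms per
practice; all variance estimates are floored at 10⁻⁶ kg² so the chain
always starts from a valid state. Because the burn-in is long relative
to the chain's mixing time, the start point (and hence the exactness
of these corrections) only matters for the Wishart prior scale S_u.

Schedules: the production profile replicates the original analysis
(burn-in 100,000; 1,000,000 post-burn-in iterations; thinning 100;
10,000 stored draws — the iteration count is treated as post-burn-in,
which is what makes the stored sample come out at exactly 10,000). The
desk profile (5,000 / 50,000 / 10; 5,000 stored draws) completes in
under a minute at desk scale and is used throughout the tests and
analysis scripts; Monte Carlo tolerances in the tests are set for this
profile. Random-effect vectors are summarised by default (per-cluster
posterior means plus per-draw 0.025/0.975 quantiles of cluster birth
weight and cumulative rate); full per-draw storage is behind a flag to
bound memory.

## Diagnostics

* **Effective sample size**: N / (1 + 2 Σ ρ_k) with Geyer's
  initial-positive-sequence truncation (autocorrelations summed in lag
  pairs while the pair sums stay positive), computed via FFT,
  capped at N; a constant series is reported as N with a warning. The
  AR(1) closed form ESS/N = (1−φ)/(1+φ) is the test oracle.
* **Raftery–Lewis**: the two-state Markov chain method for a quantile
  q to accuracy r with probability s. The series is binarised at its
  empirical q-quantile; the smallest thinning at which a first-order
  chain is preferred to a second-order one (G² statistic against a
  BIC penalty, 2 df) gives the working chain, whose transition
  probabilities yield the burn-in and run length;
  n_min = ⌈z²q(1−q)/r²⌉ depends only on (q, r, s) and equals 3,746
  for (0.025, 0.005, 0.95). Convergence tolerance ε = 0.001.
* **DIC** with the conditional (given random effects) deviance focus —
  the convention of standard multilevel software:
  D(θ) = −2 log N(y | fitted mean, σ_e²), p_D = mean deviance minus
  deviance at the posterior means (including the cluster posterior
  means, which the chain stores and persists), DIC = mean deviance +
  p_D. The marginal focus is out of scope.

## Synthetic populations

The generator emulates the recording-service structure: practices get
farms (exact totals allocated evenly, or shifted negative-binomial
counts), farms get calves, calves get a per-calf total measurement
count distributed 1 + NegativeBinomial(r = 30, mean 1.7). That
distribution was calibrated once against the reported summary (median
3, IQR 2–3) and then frozen; its theoretical quartiles are (2, 3, 3)
with P(total ≤ 2) = 0.499, i.e. the reported median sits essentially
on the distribution's boundary, so *sample* medians of moderate-sized
populations can print 2 — tests therefore check the theoretical
quantiles and the empirical IQR and mean. The reported maximum of 17
measurements is in the tail but rare at this calibration.

Follow-up ages are uniform on 1–138 days with linear thinning towards
older ages (acceptance probability 1 − rate·(t−1)/137, default rate
0.5), emulating attrition without changing the per-calf count; the
biological causes of attrition are not modelled. Farm calendars span
550–1,800 days inside a ~5.7-year service window; calf birth dates are
uniform within the farm window, recording date = birth date + age. A
configurable fraction of calves (default 0.75, matching the ratio in
the source selection table) carries a confirmed birth weight, emitted
as an age-0 record.

Corruption emulates the defects the selection cascade removes —
implausible ages (drawn above 138), weights outside (30, 225] kg,
estimate flags, and short-window farms (birth window compressed so the
farm's recording span stays under a year). The classes are applied to
disjoint record sets, never to birth rows or short-window farms'
records, so each selection stage removes an exactly predictable count;
per-record flags and tallies ship in the ground-truth object.

One property worth stating plainly: under the realistic generating
variances a *clean* day-0 weight is N(41.26, 98.06) and falls at or
below the 30 kg bound with probability ≈ 0.13, so clean data do not
pass the weight filter untouched — exactly as in the real data, where
the bounds exist to remove implausible values at the cost of clipping
a light tail. The "clean data pass the cascade unchanged" test
therefore uses a reduced-variance configuration; parameter-recovery
experiments fit the raw simulated records (no selection) so that the
recovery question isolates the sampler rather than the truncation.

## Selection cascade

Filters run in the order: age window (1–138 days inclusive; the
lower/upper bounds are configurable, and we note the source material
prints both 138 and 139 as the upper bound — the methods text's 138 is
the default), farm activity (recording span strictly greater than 365
days), estimate removal, birth-weight injection (age-0 records for
calves still present; calves whose *only* measurement is a confirmed
birth weight are retained when their farm passed the activity filter,
which both matches the reported minimum of one measurement per calf
and makes the cascade idempotent), and finally weight bounds
(30, 225] — last, so injected birth weights are themselves
range-checked. The per-stage report counts distinct practices, farms
and calves plus records; counts are non-increasing except at the
birth-injection stage, where records grow and birth-weight-only calves
enter.

## Scales, tolerances, limitations

Desk-scale defaults (10 practices / 60 farms / 3,000 calves; desk MCMC
profile) are used for recovery experiments: large enough that every
variance component is likelihood-identified, small enough that a fit
takes tens of seconds. At this scale the posterior for α is dominated
by the realised practice draws (10 practices give the realised mean
practice effect a standard deviation above 1 kg), so single-replicate
point estimates of α scatter accordingly; replicate-averaged estimates
are the meaningful recovery summary for the intercept. Posterior
intervals from a correctly specified fit are expected to cover
generating values at the nominal rate; the recovery study checks
per-parameter coverage across 10 seeded replicates.

What passing tests do and do not show: the generator draws from
exactly the model the sampler fits, so recovery tests validate the
inference machinery, not the model's adequacy for real calf data
(where growth is not exactly quadratic, attrition is informative —
calves must survive to be weighed — and breed/sex labels can err).
Results derived from the published posterior means are deterministic
arithmetic and carry no such caveat.

Numerical details: conditional covariances are formed in closed 2×2
form; a numerically non-positive-definite case is jittered once
(10⁻¹⁰ on the diagonal) and otherwise raised with the farm index.
Posterior predictive quantiles invert the draw-averaged normal mixture
CDF on a 4,001-point grid spanning ±8 posterior SDs. Farms with no age
spread fall back to intercept-only moment estimates at initialisation;
an entirely age-degenerate design is rejected with a collinearity
error when fitting is attempted.
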