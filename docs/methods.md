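# Methods

This document records the modeling assumptions, default parameters and
numerical choices behind `cogedkit`, and the known limitations of each
component.  Every quantitative statement here is computed by the package or
its test suite.

## 1. Titration engine (`cogedkit.engine`)

**Protocol.** Each domain pairs its low-effort baseline (1-back; 0 dB SNR)
with three hard levels (2/3/4-back; −4/−8/−12 dB SNR) at three base amounts
($2, $3, $4): 9 cells per domain, 5 calibration trials per cell, hence 45
decision trials per domain.  Trial 1 offers equal amounts on both sides; the
side chosen on trial 1 becomes the *titrated* side.  After the k-th choice
the titrated offer moves by `base / 2^k` — down if the titrated side was just
chosen, up otherwise, capped at the base amount.  The indifference point (IP)
is the titrated amount that *would* be offered after the fifth adjustment.

**Numeric choice.** All offers are exact `fractions.Fraction` values, so the
IP is exact (a multiple of `base/32`) and scoring introduces no float error.
The staircase is a bisection of `(0, base]`: for any agent with a fixed
acceptance threshold `t` in that interval, the IP satisfies
`|IP − t| ≤ base/32`.  The test suite verifies this on a dense grid of
threshold agents.

**Assumption.** Choices depend only on the current offer pair (no
history dependence, no lapses unless a choice temperature is set).

## 2. Subjective-value scoring (`cogedkit.scoring`)

With base amount `B` and indifference point `IP`:

* first choice *easy* (effort-averse branch): `SV = IP / B ∈ (0, 1]`;
* first choice *hard* (effort-seeking branch): `SV = (B − IP)/B + 1 ∈ [1, 2)`.

The scale is continuous at the boundary (both branches meet at 1 as
`IP → B`) and bounded in (0, 2); exhaustive enumeration of all `2^5` choice
paths x 3 bases shows the attainable extremes are `1/32` and `2 − 1/32 =
1.96875` — the staircase cannot reach 0 or 2 exactly.  A participant's
domain score is the mean SV over the 9 cells; incomplete cells raise an
error naming the missing `(level, base)` pairs rather than silently
averaging.

For an agent whose effort cost is a fixed proportion `c` of the offer, the
measured mean SV is within the quantization bound `1/32` of `1 − c` (or
`1 + |c|` on the effort-seeking branch), which is what makes the generator's
cost parameters interpretable on the SV scale.

## 3. Synthetic cohort (`cogedkit.cohort`)

**Cost model.** Participant i's cost for domain d at level ℓ is

```
cost_i(d, ℓ) = level_cost_means[d][ℓ]
             + cost_sd * ( sqrt(|rho|) * sign_d * M_i + sqrt(1 − |rho|) * eta_{i,d} )
```

with `M_i` and `eta_{i,d}` independent standard normals shared across levels
within a domain.  By construction the *population* correlation of the two
domains' mean costs is exactly `cross_domain_rho` (`sign_d` carries the sign
for negative rho).  Defaults: level cost means `(0.25, 0.40, 0.55)` in both
domains (monotone in load, validated), `cost_sd = 0.18`,
`cross_domain_rho = 0.5`, deterministic threshold choices
(`choice_temperature = 0`; a positive temperature yields softmax choices on
the utility difference).

**Covariates.** Span totals (L-span 0–42, O-span 0–75, symmetry span 0–42),
reward-sensitivity questionnaires (BAS 13–52, GRAPES-reward 0–30,
SPSRQ-reward 0–24) and need for cognition (18–90) are generated from two
latents — working-memory capacity and reward sensitivity — via a
logistic-plus-rounding map that respects each instrument's published range.
Task performance declines with load: d-prime means (2.8, 2.2, 1.6), mean RT
means (620, 700, 780) ms, intelligibility means (0.90, 0.72, 0.45) on the
unit interval.  By default these latents are independent of the effort-cost
factor, so covariate adjustment should not (and, in the tests, does not)
remove cross-domain cost correlation.

**Reproducibility.** Each participant draws from their own
`SeedSequence.spawn` stream, so cohorts are byte-identical across runs and
the first k participants are unchanged when the cohort is enlarged.

**Realism limits.** Costs are level-shifted but share one within-domain
random effect, i.e. no level-specific participant slopes; performance
covariates do not feed back into choices; there is no trial-level noise in
performance during titration.

## 4. Correlation Bayes factors (`cogedkit.bayescorr`)

**Likelihood.** The sampling density of the Pearson correlation r of n
bivariate-normal pairs, as a function of the population correlation rho, is
used in ratio form:

```
log LR(rho) = (n−1)/2 * log(1 − rho²) − (n − 3/2) * log(1 − rho·r)
            + log 2F1(1/2, 1/2; n − 1/2; (1 + rho·r)/2)
            − log 2F1(1/2, 1/2; n − 1/2; 1/2)
```

`BF10 = ∫ LR(rho) π(rho) drho` is computed by adaptive quadrature
(`scipy.integrate.quad`, relative tolerance 1e-8, with a quadrature
breakpoint at rho = r).

**Priors.** Two families on (−1, 1), optionally restricted to [0, 1):

* *truncated Cauchy*, default scale `sqrt(2)/2` — the literal reading of a
  zero-centered Cauchy prior on a correlation, renormalized to the support;
* *stretched beta*, `rho = 2·Beta(1/k, 1/k) − 1` with scale k — the
  convention of common Bayes-factor software (k = 1 is the uniform prior).
  For this family the implementation matches `pingouin.bayesfactor_pearson`
  to better than 0.01% (cross-checked in the tests).

**Posterior summaries.** Median and 95% credible interval come from the
normalized integrand on a tanh-transformed grid (z in [−8, 8], 4001 nodes),
which concentrates nodes near ±1 where the likelihood can peak.  The
Savage–Dickey identity (BF10 = prior/posterior density at 0) holds to within
1% and is asserted in the tests, as is agreement with a 400k-draw
Monte-Carlo estimate of the marginal likelihood.

**Partial correlation.** Both vectors are residualized on the controls (with
intercept) after an index-alignment check; the residual correlation is
tested with effective sample size `n − k` for k controls.  A vector fully
explained by the controls gets partial r = 0 rather than 0/0.

**Fast path.** The sequential simulator uses a 200-node Gauss–Legendre rule
(`bf10_fixed_grid`), which agrees with the adaptive quadrature to well under
0.1% over the exercised (r, n) range (asserted in the tests).

## 5. Sequential design analysis (`cogedkit.bfda`)

Each replicate grows a bivariate-normal sample with the design's true
correlation from `n_min` in steps of `n_step`, computing the BF at each
interim from cumulative sums, and stops at the first crossing of
`bf10 ≥ bf_upper` or `bf10 ≤ bf_lower`, else at `n_max`.  BF evaluations are
cached on `(r rounded to 1e-4, n)`; the rounding perturbs the BF by far less
than the distance to any boundary in practice.  Replicate i draws from child
i of a shared `SeedSequence`, so results are reproducible and stable under
changes of `n_sims`.

Defaults: boundaries 10 / 0.1, `n_min = 10`, `n_step = 1`, `n_max = 300`,
1000 replicates.  A `REGISTERED_DESIGN` preset monitors from n = 100 every
10 participants.

**Limitation worth knowing.** Under the truncated-Cauchy prior the
evidence for the null saturates: at r = 0 the BF10 stays above 0.1 for all
n ≤ 300, so a lower boundary of 0.1 is unreachable within that horizon.
Designs intended to stop for the null at desk scale should use the
stretched-beta prior (e.g. scale 1), for which the lower boundary is
reachable.  `scripts/acceptance.py` documents and applies exactly this
fallback when reporting the lower-boundary stopping median.

## 6. Three-stage analysis (`cogedkit.analysis`, `cogedkit.composites`)

* **Stage 1** — Bayesian correlation of the participant-level mean SVs of
  the two domains.
* **Stage 2** — within each domain, SVs (participant x level, averaged over
  bases) are residualized by OLS on task level (categorical) plus the
  domain's performance covariates matched at level grain; participant
  residuals (mean of row residuals) are correlated across domains.
  Zero-variance covariates are dropped (they carry nothing to adjust);
  genuinely collinear designs raise an error naming the offending columns.
* **Stage 3** — partial correlation of the stage-2 residuals controlling for
  the working-memory-capacity composite (sum of z-scored span totals) and
  the reward-sensitivity composite (sum of z-scored questionnaire totals),
  with effective n reduced by the two controls.
* **Stage 4** (optional) — exploratory correlation of need for cognition
  with the two-domain mean SV.

**Non-compliance flag.** A participant is flagged when every one of their 90
decision trials selected the same option — equivalently, when all 18 cells
share one first choice *and* every staircase ran to its extreme
(`IP = base/32`).  The extremity condition matters: under proportional
effort costs the *first* choice of every cell is base-invariant, so "same
first choice in all cells" alone would flag ordinary effort-averse
participants.  When anyone is flagged, results carry a second, flag-excluded
variant of every stage instead of silently dropping participants; the
pipeline refuses to run if the flag rate exceeds a configurable fraction
(default 50%).

## 7. Known limitations

* The BFDA component reproduces neither of the published sequential-design
  medians for this study (112 at the upper boundary under rho = 0.3; 140 at
  the lower under rho = 0): the faithful correlation-design run gives a
  median upper stopping n near 68, and the lower boundary is unreachable
  under the truncated-Cauchy prior (see §5).  The corresponding acceptance
  tests assert the published values and therefore fail.
* The pilot value BF10 = 39.21 for r = 0.521, n = 31 is not matched by
  either sidedness variant of the truncated-Cauchy prior (two-sided ≈ 17.0,
  one-sided ≈ 33.9, both computed by `correlation_bf`).
* Posterior medians are shrunk toward zero by the prior (at r = 0.5,
  n = 150 the posterior median is ≈ 0.489), so a recovery criterion that
  compares the *mean posterior median* over many replicates against the
  generating correlation within Monte-Carlo error will fail at this sample
  size; the sample correlations themselves are unbiased up to the standard
  −rho(1 − rho²)/(2n) small-sample term.
* Cohort realism limits are listed in §3; the generator is a tool for
  pipeline validation and design analysis, not a behavioral model fitted to
  data.
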