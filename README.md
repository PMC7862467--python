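# cogedkit

Simulation and Bayesian analysis toolkit for **cognitive-effort discounting
(COG-ED)** studies that compare effort costs across task domains.

In a COG-ED experiment, participants repeatedly choose between a low-effort
task for a smaller reward and a high-effort task for a larger one.  An
adaptive staircase titrates one offer toward the **indifference point** — the
amount at which the two options are equally attractive — and the resulting
**subjective value** (SV) expresses the cost of effort as a fraction of the
fixed offer.  `cogedkit` implements the complete computational core of such a
study with two effort domains:

* **working memory** — N-back task; 1-back baseline vs. 2/3/4-back, with
  d-prime and mean reaction time as performance covariates;
* **speech comprehension** — speech in noise; 0 dB SNR baseline vs.
  −4/−8/−12 dB, with intelligibility as the performance covariate.

The package provides:

1. **Titration engine** (`cogedkit.engine`) — the exact staircase protocol:
   3 base amounts ($2, $3, $4) x 3 effort levels per domain, 5 calibration
   trials per cell (45 decision trials per domain), stepwise-halved offer
   adjustments in exact `Fraction` arithmetic.
2. **SV scoring** (`cogedkit.scoring`) — indifference points mapped to a
   (0, 2) subjective-value scale; values above 1 indicate effort seeking.
3. **Synthetic cohorts** (`cogedkit.cohort`) — a latent-trait generator with
   a configurable cross-domain correlation of effort costs, plus realistic
   bounded covariates (span tasks, reward-sensitivity questionnaires,
   need for cognition, task performance).
4. **Bayesian correlation tests** (`cogedkit.bayescorr`) — exact Bayes
   factors for Pearson and partial correlations from the sampling density of
   r, with truncated-Cauchy and stretched-beta priors, posterior medians and
   95% credible intervals.
5. **Sequential design analysis** (`cogedkit.bfda`) — Monte-Carlo Bayes
   Factor Design Analysis with evidence boundaries and stopping-n summaries.
6. **Three-stage analysis pipeline** (`cogedkit.analysis`,
   `cogedkit.pipeline`, `cogedkit.cli`) — zero-order, performance-residualized
   and trait-partialed cross-domain correlations, with artifact output.

## Worked example: one staircase cell

Titrate the $2 cell of 1-back vs. 2-back for a participant who plays a fixed
choice sequence:

```python
from fractions import Fraction
from cogedkit import WORKING_MEMORY, run_cell, subjective_value

choices = iter(["easy", "hard", "easy", "easy", "hard"])
rec = run_cell(lambda pair: next(choices), WORKING_MEMORY, "2back", Fraction(2))
for i, (pair, choice) in enumerate(rec.trial_log, 1):
    print(f"trial {i}: easy ${float(pair.amount('easy')):.4f} "
          f"vs hard ${float(pair.amount('hard')):.4f} -> chose {choice}")
print("indifference point:", rec.indifference_point)
print("subjective value:", float(subjective_value(rec)))
```

Output:

```
trial 1: easy $2.0000 vs hard $2.0000 -> chose easy
trial 2: easy $1.0000 vs hard $2.0000 -> chose hard
trial 3: easy $1.5000 vs hard $2.0000 -> chose easy
trial 4: easy $1.2500 vs hard $2.0000 -> chose easy
trial 5: easy $1.1250 vs hard $2.0000 -> chose hard
indifference point: 19/16
subjective value: 0.59375
```

The first choice fixes which side is titrated (here the low-effort offer,
which immediately halves from $2.00 to $1.00); each subsequent step halves
again, moving toward the chooser's indifference point.

## Worked example: full simulated study

```python
from cogedkit import AnalysisConfig, CohortConfig, run_pipeline

cfg = AnalysisConfig(cohort=CohortConfig(n_participants=60, seed=11), seed=4)
results = run_pipeline(cfg)
print(results.summary())
```

Output:

```
Cross-domain cognitive-effort analysis
  participants analyzed: 60 (0 flagged non-compliant)
  prior: truncated-cauchy scale=0.7071 (two-sided)
  [all participants]
    stage 1  zero-order correlation of domain-mean SVs:
      r = 0.4816 (n = 60): BF10 = 276.4, posterior median rho = 0.4531 [0.2308, 0.6314]
    stage 2  correlation of performance-residualized SVs:
      r = 0.4702 (n = 60): BF10 = 188.9, posterior median rho = 0.4417 [0.2175, 0.6226]
    stage 3  partial correlation given trait composites:
      r = 0.4645 (n = 58): BF10 = 125.5, posterior median rho = 0.4351 [0.2057, 0.6202]
```

The default cohort is generated with a true cross-domain cost correlation of
0.5; all three stages recover it.  `cogedkit.analysis` follows a
statsmodels-style model/results split: `CrossDomainModel(sv_table,
covariates).fit()` returns a `CrossDomainResults` with `summary()`,
`to_frame()` and `plot()`.

A standalone Bayes factor:

```python
from cogedkit import correlation_bf
print(correlation_bf(0.45, 80))
```

```
r = 0.4500 (n = 80): BF10 = 823.6, posterior median rho = 0.4287 [0.2346, 0.5905]
```

## Worked example: sequential design analysis

```python
from cogedkit import DesignSpec, simulate_sequential_design, summarize_design

spec = DesignSpec(true_rho=0.3, n_sims=500, seed=7)
print(summarize_design(simulate_sequential_design(spec)).to_string(index=False))
```

Output:

```
boundary  proportion  n_replicates   q05   q25   q75   q95  median_stopping_n  misleading
   upper       0.998           499  12.0  34.0 115.0 200.0               63.0       False
   lower       0.000             0   NaN   NaN   NaN   NaN                NaN        True
 ceiling       0.002             1 300.0 300.0 300.0 300.0              300.0       False
```

## Command line

```bash
cogedkit simulate --seed 1 --out out/          # cohort + covariate tables
cogedkit discount --seed 1 --out out/          # decision-phase trial log
cogedkit score    --seed 1 --out out/          # scored SV tables
cogedkit analyze  --config config.yaml --seed 1 --out out/   # full pipeline
cogedkit bfda     --config design.yaml --seed 1 --out out/   # design analysis
```

All artifacts are tab-delimited text plus a JSON report; reruns with the same
configuration and seed are byte-identical.

## Reproduction

Run the test suite (unit, property-based and acceptance tests):

```bash
python -m pytest -q tests/
```

Recompute the headline target quantities from scratch and write them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This reports: decision trials per domain (45), the post-choice low-effort
offer in the $2 titration example ($1.00), the maximum attainable subjective
value (1.96875 = 2 − 1/32), and the median sequential-design stopping sample
sizes at the upper (true rho = 0.3) and lower (true rho = 0) evidence
boundaries.

Three tests in `tests/test_acceptance.py` assert published values from the
registered study that this package simulates, and fail by design under this
implementation: the printed BFDA medians (112 upper / 140 lower) are not
reproduced by the prescribed correlation design (this implementation obtains
~68, and under the prescribed truncated-Cauchy prior the lower boundary is
unreachable within n = 300); the pilot BF10 = 39.21 is not bracketed by
one-/two-sided variants of the prior; and the parameter-recovery criterion on
posterior medians is blocked by prior shrinkage (about −0.011 at n = 150),
which exceeds the ±3 Monte-Carlo-SE band.  `docs/methods.md` details the
models, numeric choices and these limitations.
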