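# gapdecomp

Decomposition of wealth-based gaps in binary health-service outcomes on
complex-survey micro-data. The package provides:

- **`gapdecomp.synthetic`** — a generator for DHS-like birth-level micro-data
  (stratified two-stage cluster structure, asset indicators driven by a latent
  household wealth score, a PCA asset index, wealth-dependent covariate laws,
  group-specific logistic outcome processes, optional PSU random intercepts),
  plus a Monte-Carlo oracle that evaluates the expected coverages and
  explained portions under the *true* coefficient vectors.
- **`gapdecomp.survey`** — CSV micro-data I/O with validation, weighted
  wealth-quintile grouping (poor = bottom two quintiles), dummy coding of
  covariate blocks with listwise deletion and a missing-partner-indicator
  policy.
- **`gapdecomp.estimation`** — survey-weighted logit (Newton-Raphson) and
  linear-probability models with PSU-cluster-robust sandwich covariances
  (small-sample correction `G/(G-1) * (N-1)/(N-K)`; with singleton clusters
  this reduces exactly to HC1), odds ratios, and two-sided weighted
  proportion-difference tests with 10/5/1% significance stars.
- **`gapdecomp.decomposition`** — the aggregate nonlinear Blinder-Oaxaca-type
  decomposition of the outcome-mean gap into explained/unexplained portions
  under poor, non-poor or pooled benchmark coefficients, and the Fairlie-style
  detailed decomposition: one-to-one rank matching on predicted probability,
  subsampling of the larger group, sequential block switching, and replication
  over random subsamples and random covariate orderings.
- **`gapdecomp.reporting` / `gapdecomp.cli`** — descriptive and decomposition
  table rendering and a `gapdecomp` command-line tool.

## CLI

```sh
# generate synthetic micro-data (and the matching model spec)
gapdecomp simulate --config config.yaml --seed 42 --out data.csv --spec-out spec.yaml

# descriptive statistics by wealth group
gapdecomp describe --input data.csv --spec spec.yaml --outdir out/

# aggregate + detailed decomposition, all benchmarks, 100 replications
gapdecomp decompose --input data.csv --spec spec.yaml --benchmark all \
    --replications 100 --seed 7 --outdir out/
```

Logs (seeds, sample sizes, dropped-row counts) go to stderr; results go to
files (`decomposition.csv`, `decomposition.json`, `descriptive.csv/.txt`).
Exit codes: 0 success, 1 stage error, 2 usage error. One root seed fixes
every reported number.

A ready-made generator configuration is available programmatically:

```python
from gapdecomp import example_config, generate_population, run_decomposition

cfg = example_config(seed=1)
micro = generate_population(cfg)
result = run_decomposition(micro, cfg.model_spec(), R=100, seed=1)
print(result.report.to_frame())
```

## Conventions worth knowing

- Wealth quintiles use weighted-CDF quantiles over households; ties share a
  quintile; `group = poor` iff quintile ≤ 2.
- Weights are normalized to sum to N within each estimation sample; point
  estimates are invariant to rescaling all weights.
- In the detailed decomposition the larger group — whichever it is — is
  subsampled to the smaller group's size; pairs are formed ignoring weights
  and contribution means use the poor record's normalized weight; ties in
  predicted-probability ranks are broken by a seeded shuffle; reported
  standard errors are across-replication standard deviations.
- The explained + unexplained = gap identity holds to machine precision for
  every benchmark; per-replication block contributions telescope exactly to
  the matched-sample explained portion.
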