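# ecodbn

Conditional linear Gaussian **dynamic Bayesian networks** for short annual
ecosystem time series — structure learning with edge confidence, EM fitting
with hidden regime chains, bootstrap one-step predictive model comparison,
and temperature press-perturbation scenarios.

## The problem

Marine ecosystem indicators (climate indices, regional sea-surface
temperature, nutrient loads, dissolved oxygen, plankton, recruitment
deviations of exploited stocks) are observed once a year for a few decades.
Managers want to know (i) which interactions among these components the
data actually support, (ii) how well competing structural hypotheses
predict each biological component one year ahead, and (iii) how the system
would respond to sustained warming. `ecodbn` implements that workflow for
anyone with a years × components table; it was designed around a 32-year,
28-component Gulf of Mexico table (see `ecodbn.study.study_schema`), and
ships a ground-truth synthetic generator of the same shape so every stage
can be validated against known structure.

## The model

Each observed component is a scalar Gaussian node in a two-slice network.
With continuous parents *x* and discrete (binary hidden) parents in
configuration *i*:

```
Y | X = x, Q = i  ~  N( mu_i + W_i · x , sigma2_i )
```

Component→component dependencies are lag-1 (parents act from year *t−1*);
each hidden variable is a persistent binary Markov chain (initial law π,
transition matrix A) acting on the current year, capturing regime shifts in
the drivers. Inference (filtering, smoothing, likelihood) is exact over the
product of hidden chains, and missing observations are marginalized rather
than imputed.

Three structures are compared:

* **ARHMM** — one shared hidden regime; every component depends only on its
  own previous value and the regime.
* **ARDBN** — two hidden regimes (AMO-type index; regional SST series);
  every component keeps its autoregressive link and gains its single
  highest-confidence learned parent.
* **DDDBN** — same regimes; autoregressive links only for hidden, climate
  and physiochemical nodes; every predicted component gets its
  top-confidence learned parents, at most three in total.

Edges are learned by greedy hill-climb (add/delete/reverse, node-wise
Gaussian BIC, ≤3 parents) with random restarts over a sliding window of
years; an edge's **confidence** is the fraction of window × restart runs
whose local optimum contains it. Parameters are fitted by EM maximizing
`L(θ) = log Σ_H P(X, H | θ)`. Predictive skill is scored by the sum of
squared one-step errors `Σ (predicted − actual)²` on out-of-bag years of a
250-iteration non-parametric bootstrap. A press scenario adds +Δ°C to the
SST series only (training unchanged) and reports each component's mean
predicted shift.

## Worked example

```python
import ecodbn as e

spec = e.SyntheticSpec(seed=7)                     # 32 years x 28 components
_, truth = e.generate_structure(spec)
table, std, _ = e.simulate_table(truth, spec)

conf = e.learn_confidence(table, e.HillClimbConfig(seed=0), e.EMConfig(seed=0))
cmp_table, _, fitted = e.compare_models(
    table, conf, n_boot=50, em_config=e.EMConfig(seed=1), seed=2
)
print(cmp_table.frame.round(2).head(6))
print("best-model counts:", cmp_table.best_counts())

res = e.run_scenario(fitted["DDDBN"], table, std, e.ScenarioSpec(1.5), n_boot=0)
print(res.mean_difference.abs().sort_values(ascending=False).head(3).round(3))
```

prints

```
         ARHMM  ARDBN  DDDBN   best
biota 1  15.05  14.35  13.04  DDDBN
biota 2   5.34   3.50   3.51  ARDBN
biota 3  11.09  11.90  12.20  ARHMM
biota 4   9.54   3.21   2.92  DDDBN
biota 5  13.71   7.69   7.18  DDDBN
biota 6  18.97  14.96  13.54  DDDBN
best-model counts: {'DDDBN': 13, 'ARDBN': 4, 'ARHMM': 1}
variable
biota 10    0.367
biota 14    0.214
biota 15    0.000
Name: mean, dtype: float64
```

Each row is one predicted component's bootstrap-mean SSE under the three
structures (lower is better; ties break toward the simpler model). Here the
data-driven structure wins for 13 of 18 biological components — expected,
since the generating process contains real cross-component links. The
scenario line shows the largest standardized mean shifts under a sustained
+1.5 °C press: components downstream of an SST series respond, the rest
are exactly zero.

The same pipeline is available from a shell:

```
ecodbn synth --seed 5 --out table.csv --truth truth.json
ecodbn learn-structure --table table.csv --window 10 --restarts 10 --seed 0 --out conf.csv
ecodbn compare --table table.csv --confidence conf.csv --n-boot 250 --seed 1 --out cmp.csv
ecodbn fit --table table.csv --structure dddbn --confidence conf.csv --out dddbn.json
ecodbn scenario --table table.csv --model dddbn.json --std-params table.csv.std.json \
    --delta 1.0 --delta 1.5 --delta 3.0 --out-prefix scen
```

## Documentation

`docs/methods.md` describes the model and its assumptions, the numerical
choices (initialization, variance floor, missing-data handling, bootstrap
protocol), what the synthetic generator does and does not emulate, and
known limitations.
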