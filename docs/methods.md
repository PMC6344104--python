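# Methods

## Model

The system is a two-slice dynamic Bayesian network over scalar observed
components and binary hidden regime variables.

**Observed nodes.** Each component `Y` follows a conditional linear
Gaussian (CLG) law: given its continuous parents `x` and the configuration
`i` of its discrete parents, `Y ~ N(mu_i + W_i·x, sigma2_i)`. Variances are
per-node scalars; the joint covariance of the system is induced by the
graph. All component→component edges are realized at lag 1 (parent value at
year t−1 drives the child at year t). This is forced by the prediction
protocol: forecasts condition on the previous year's evidence only, so a
same-year component→component edge would never be usable at prediction
time. Hidden→observed edges are within-slice: the current regime switches
the current year's parameters.

**Hidden nodes.** Each hidden variable is a binary first-order Markov
chain (initial distribution π, transition matrix A) with no parents other
than its own past. Regimes model non-stationarity: a persistent chain whose
state shifts the mean (and can alter slopes and variances) of its observed
children. Exact inference runs on the product of all chains — with at most
two binary chains in the comparison models the joint state space has four
states, so filtering and smoothing are exact and cheap.

**Time boundary.** A node with lag-1 parents has no well-defined
conditional at the first year; its first-year emission is omitted (the
likelihood conditions on the initial slice). Hidden chains start from π at
the first year.

**Missing data.** Missing observations are marginalized exactly: the
affected emission factor is simply dropped from the likelihood. When a
*parent* value needed by a child's emission is missing, that child-year
emission is dropped as well (pairwise deletion). Exact marginalization over
a missing continuous parent would require joint-Gaussian message passing
across the slice; with the near-complete annual tables this package
targets, the dropped-factor approximation affects isolated node-years only.
Nothing is ever imputed.

## Structure learning

Dependencies are learned on the lag-1 design: child values at t regressed
on candidate parent values at t−1.

* **Score.** Node-decomposable Gaussian BIC: per family, the maximized OLS
  log-likelihood minus `(k/2)·log n`, with `k` counting intercept, weights
  and variance. A family with fewer effective rows than regression
  parameters scores −∞ (rejected). BIC is the standard
  consistency-oriented default for this search.
* **Search.** Greedy hill-climb over single-edge additions, deletions and
  reversals on the parent→child projection digraph, keeping it acyclic and
  parent counts ≤ 3, from random sparse restarts. Family scores are cached
  on precomputed Gram matrices, so a move evaluation is one small linear
  solve.
* **Sliding window.** The search repeats on every window of consecutive
  years (default: 10-year windows, stride 1, 10 restarts — 230 runs on a
  32-year series). An edge's confidence is the fraction of runs whose local
  optimum contains it. Windowing probes stability under subsetting in time;
  restarts probe sensitivity to the search path.
* **Hidden column.** Before the hill-climb, the single-regime ARHMM is
  fitted and the smoothed posterior probability of regime state 1 enters
  the data matrix as a continuous column (`HV`), so regime↔component
  dependencies can be discovered alongside measured ones. (Hard Viterbi
  states are a possible alternative; the soft posterior preserves
  uncertainty.)

**Builders.** The three comparison structures are deterministic functions
of the confidences and the variable metadata:

* ARHMM: shared regime → every component; autoregressive self-links
  everywhere.
* ARDBN: two regimes with mandated links (AMO-regime → non-SST climate
  indices, SST-regime → every SST series); every component keeps its
  self-link; every predicted component gains exactly its top-confidence
  learned parent (ties broken by lexicographically smaller parent name, for
  reproducibility). A learned edge from the `HV` column is allocated to the
  SST regime chain, except for non-SST climate children, which get the AMO
  chain — the SST chain is the broader temperature-linked driver, and no
  principled per-edge attribution is available from a single learned
  column.
* DDDBN: self-links only for hidden, climate and physiochemical nodes;
  predicted components receive their learned parents in confidence order,
  at most three in total, candidates filtered at confidence ≥ 0.5. When no
  candidate clears 0.5 (common on short windows, where confidence mass
  spreads), the child keeps its single top-confidence parent so that every
  predicted component remains connected. Lag-1 edges cannot create cycles
  in the unrolled graph, so no edges need to be skipped for acyclicity.

## EM fitting

Parameters are estimated by maximum likelihood, `L(θ) = log Σ_H P(X,H|θ)`,
via EM:

* **E-step.** Exact forward-backward smoothing on the product chain gives
  per-year configuration responsibilities and pairwise transition
  expectations; responsibility-weighted moments (`Σ r z zᵀ`, `Σ r z y`,
  `Σ r y²` with `z = [1, x]`) accumulate per node and configuration.
* **M-step.** Closed form: weighted least-squares normal equations per
  configuration (1e-8 ridge if singular); the variance is the weighted
  residual variance, floored at 1e-6 (standardized units²) to prevent
  degenerate likelihoods; transition rows and π are normalized expected
  counts. A configuration with no responsibility keeps its previous
  parameters, and an empty transition row is regularized by a 1e-3
  pseudocount — both guards bind only in degenerate cases, so the exact
  M-step property (monotone non-decreasing likelihood, slack 1e-8) holds on
  healthy runs and is asserted by the trace container.
* **Initialization.** Five seeded random starts by default; the best final
  likelihood wins. Random per-year responsibilities are a poor start for
  regime models — temporally uncorrelated assignments give both states
  nearly identical data, and every run collapses into a variance-split
  local optimum. Starts are instead anchored in time: with probability 0.7
  the years are split by thresholding the mean of the chain's observed
  children at a random quantile (0.3–0.7), otherwise a sticky random path
  (persistence 0.9) is sampled; either path is softened to 0.85/0.15
  responsibilities and turned into parameters by one weighted
  least-squares pass.
* **Convergence.** Relative likelihood change < 1e-6 or 200 iterations.

States are identified only up to permutation; comparisons align them by
ascending mean of a designated observed child.

## Bootstrap evaluation

Year indices are resampled with replacement (training multiset, size n);
the never-drawn years are the test set (expected fraction
`(1−1/n)^n ≈ 0.362` at n = 32; an all-drawn resample is redrawn). The
published protocol does not say how a chain model is fitted to a multiset
of years; this package uses a weighted-likelihood bootstrap that preserves
the chain: each year's emission terms are raised to its resample
multiplicity (zero for out-of-bag years, which the missing-data machinery
then marginalizes), while the transition structure stays contiguous. EM
monotonicity holds for this weighted objective exactly.

Structure is learned once on the full series; only parameters are re-fit
per bootstrap iteration (re-learning per iteration is available via the
builders if wanted). Refits warm-start from the full-data fit — the
resample perturbs the objective only mildly, so a handful of EM iterations
suffices and the 250 × 3-model comparison runs in minutes on one CPU.

Each out-of-bag year t (with some observed data at t−1) is predicted from
the *observed* evidence at t−1; the hidden belief at t−1 comes from
filtering the training evidence only. Prediction moments are the exact
mixture moments over the propagated hidden belief (law of total variance);
within-slice observed parents, if present, resolve in topological order via
their predicted means. A missing individual parent value contributes its
standardized mean (0); a fully missing predecessor year skips the test
year.

Reported per variable: the mean over iterations of the per-iteration
out-of-bag SSE (the pooled total over all out-of-bag predictions is also
computed; the aggregation is a parameter since either convention is
plausible), and per-year bootstrap mean ± 1.96·sd bands. Ties in the
best-model marking break toward the simpler structure.

## Press scenarios

A press adds a sustained shift to the SST columns only. Deltas are physical
(°C) by default and convert per series by its original standard deviation
(`delta_scale="standardized"` bypasses the conversion). Training is always
on the original data. Baseline and scenario one-step predictions both roll
the predicted components forward — each predicted component's evidence at
t−1 is its own prediction, while driver evidence comes from the (original
or perturbed) data — so a press propagates down directed chains of
predicted components, one edge per year, instead of being clamped away by
observed intermediaries. Hidden-state filtering under the scenario uses the
perturbed evidence, letting the SST regime chain respond to the press. For
a linear model this makes the mean response equal the sum of directed
path-weight products from the SST nodes (diluted only by the spin-up
years), exactly proportional to the delta, and identically zero for
components unreachable from an SST node. Both a per-year difference series
and the across-year mean difference are reported, with bootstrap standard
deviations from parameter refits.

## Synthetic generator

The generator emulates the shape of the target data: `n_years=32` annual
observations of 4 climate series (an AMO-like index plus three SST series)
driven by one persistent binary regime (persistence 0.9, i.e. roughly one
shift per decade; regime shift 1.0 in units of the observation scale —
comparable to the noise so regimes are detectable but not trivial), 6
physiochemical series with AR(0.5) persistence, and 18 biological series
with 1–3 planted lag-1 parents among drivers and earlier biological series
(climate drives biology, never conversely). Planted weights are uniform in
±[0.4, 0.8): strong enough for a 32-year series to carry signal, weak
enough for stability. Observation noise sd is 0.5. Tables are sampled with
a 50-year discarded burn-in (so lag-1 parents exist at the first reported
year and the series are near-stationary) and standardized column-wise
(sample sd, n−1), exactly as measured tables are before modeling.

What the generator does **not** emulate: measurement error distinct from
process noise, serially correlated observation gaps, nonlinear (threshold)
responses, contemporaneous same-year interactions, or drivers with trends
rather than regimes. Passing tests therefore demonstrate correctness of
the machinery and adequate power under a plausible linear-Gaussian regime
world, not that the real ecosystem satisfies these assumptions.

## Numerical choices and edge cases

* Standardization uses each full series' own moments; train/test splits
  never re-estimate them.
* Forward recursions are scaled per year with log-normalizers accumulated
  in log space; emission matrices are shifted by their row maximum before
  exponentiation. Zero-probability evidence raises rather than returning
  NaN.
* Constant columns cannot be standardized and are rejected with the
  column name.
* The bootstrap evaluation logs and skips an EM failure in an iteration
  and aborts if more than 10% of iterations fail.
* Sampling, splits, restarts and EM starts all derive from explicit seeds
  (`numpy` `SeedSequence` spawning); identical seeds give identical
  results.

## Limitations

* Lag-1 only; no higher-order or seasonal structure.
* Hidden states are binary and chains are a priori independent; coupled or
  many-state regimes are out of scope.
* Exact marginalization of missing *parent* values is approximated by
  dropping the affected emission (see above).
* The hill-climb explores single-edge moves; it can miss equivalence-class
  moves a full equivalence-search would find.
* Confidence values from short windows are diluted across correlated
  candidate parents; they rank edges well but their absolute scale depends
  on the window/restart configuration.
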