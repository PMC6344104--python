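"""One-step-ahead predictive evaluation by non-parametric bootstrap.

Protocol: year indices are resampled with replacement to form a training
multiset; years never drawn (out-of-bag) are the test set.  Parameters are
re-fit on each resample (the structure stays fixed), each out-of-bag year
is predicted from the observed evidence of its preceding year, and squared
errors accumulate per predicted variable.  The whole cycle is repeated
(250 iterations by default) to give mean SSEs and per-year bootstrap
uncertainty bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dbn_core import FittedModel, NetworkStructure, forward_filter, predict_one_step
from .em_training import EMConfig, fit_em
from .structure_learning import EdgeConfidenceTable, build_ardbn, build_arhmm, build_dddbn
from .timeseries_io import EcosystemTable


@dataclass(frozen=True)
class BootstrapSplit:
    """Training multiset (size n, with replacement) and out-of-bag test set."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        train = np.asarray(self.train_indices)
        test = np.asarray(self.test_indices)
        if len(test) == 0:
            raise ValueError("empty test set")
        if set(test) & set(train):
            raise ValueError("test indices overlap the training multiset")
        object.__setattr__(self, "train_indices", train)
        object.__setattr__(self, "test_indices", test)

    def weights(self, n_years: int) -> np.ndarray:
        """Per-year resample multiplicity (0 for out-of-bag years)."""
        return np.bincount(self.train_indices, minlength=n_years).astype(float)


@dataclass(frozen=True)
class PredictionSeries:
    """Tidy per-variable, per-year predictions with bootstrap uncertainty.

    Columns: variable, year, observed, boot_mean, boot_sd, lo95, hi95,
    n_boot.  The 95% band is boot_mean ± 1.96·boot_sd.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"variable", "year", "observed", "boot_mean", "boot_sd", "lo95", "hi95"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"missing columns {required - set(self.frame.columns)}")
        bad = self.frame["lo95"] > self.frame["hi95"]
        if bad.any():
            raise ValueError("interval bounds out of order")

    def for_variable(self, name: str) -> pd.DataFrame:
        return self.frame[self.frame["variable"] == name].reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class ModelComparisonTable:
    """Per-variable SSE of each model, with the best model marked.

    Ties break toward the simpler model (ARHMM < ARDBN < DDDBN order).
    """

    frame: pd.DataFrame  # index: variable; columns: one per model + "best"

    @property
    def model_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != "best"]

    def best_counts(self) -> dict[str, int]:
        return self.frame["best"].value_counts().to_dict()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="variable")


def sse(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Sum of squared prediction errors; missing actuals excluded pairwise."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    ok = ~np.isnan(a) & ~np.isnan(p)
    return float(np.sum((p[ok] - a[ok]) ** 2))


def bootstrap_split(n_years: int, seed) -> BootstrapSplit:
    """Uniform resample of year indices; complement is the test set.

    Resamples (deterministically) in the rare event every year is drawn.
    """
    if n_years < 3:
        raise ValueError("need at least 3 years")
    rng = np.random.default_rng(seed)
    while True:
        train = rng.integers(0, n_years, size=n_years)
        test = np.setdiff1d(np.arange(n_years), train)
        if len(test) > 0:
            return BootstrapSplit(train_indices=train, test_indices=test)


def _predict_test_years(
    model: FittedModel,
    data: EcosystemTable,
    test_idx: np.ndarray,
    predicted_vars: Sequence[str],
    row_weights: np.ndarray | None = None,
) -> dict[int, dict[str, float]]:
    """One-step predictions for each test year from its observed predecessor.

    The hidden belief at t−1 comes from filtering the training evidence
    (``row_weights`` masks out-of-bag years); the regression evidence at
    t−1 uses the actually observed values, per the prediction protocol.
    """
    values = data.values
    col_of = {c: i for i, c in enumerate(data.columns)}
    _, _, alpha = forward_filter(model, data, row_weights=row_weights)
    out: dict[int, dict[str, float]] = {}
    for t in sorted(int(t) for t in test_idx):
        if t == 0:
            continue  # no preceding year to condition on
        prev = values[t - 1]
        if np.all(np.isnan(prev)):
            continue  # predecessor entirely missing: skip
        evidence = {c: float(prev[col_of[c]]) for c in data.columns}
        pred = predict_one_step(model, evidence, hidden_prior=alpha[t - 1])
        out[t] = {v: pred[v][0] for v in predicted_vars if v in pred}
    return out


def evaluate_model(
    structure: NetworkStructure,
    data: EcosystemTable,
    n_boot: int = 250,
    em_config: EMConfig | None = None,
    seed: int = 0,
    base_model: FittedModel | None = None,
    aggregation: str = "mean",
    max_failure_fraction: float = 0.1,
) -> tuple[pd.Series, PredictionSeries]:
    """Bootstrap evaluation of one structure.

    Fits the structure once on the full series (random initializations),
    then per bootstrap iteration warm-starts EM from that fit with the
    resample's year multiplicities as emission weights, predicts the
    out-of-bag years, and scores the predicted variables.

    Returns per-variable SSE (mean over iterations by default,
    ``aggregation="pooled"`` for the total over all out-of-bag predictions)
    and the tidy bootstrap prediction series.
    """
    if aggregation not in ("mean", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    em_config = em_config or EMConfig()
    predicted_vars = data.predicted_variables or data.columns
    if base_model is None:
        base_model, _ = fit_em(structure, data, em_config)
    T = data.n_years
    values = data.values
    col_of = {c: i for i, c in enumerate(data.columns)}

    ss = np.random.SeedSequence(seed)
    boot_seeds = ss.spawn(n_boot)
    per_iter_sse: list[dict[str, float]] = []
    sq_err_sums = {v: 0.0 for v in predicted_vars}
    preds_by_var_year: dict[str, dict[int, list[float]]] = {
        v: {} for v in predicted_vars
    }
    n_failures = 0
    for b in range(n_boot):
        split = bootstrap_split(T, boot_seeds[b])
        w = split.weights(T)
        try:
            model_b, _ = fit_em(
                structure, data, em_config, init_model=base_model, row_weights=w
            )
            preds = _predict_test_years(
                model_b, data, split.test_indices, predicted_vars, row_weights=w
            )
        except (FloatingPointError, np.linalg.LinAlgError):
            n_failures += 1
            if n_failures > max_failure_fraction * n_boot:
                raise RuntimeError(
                    f"more than {max_failure_fraction:.0%} of bootstrap "
                    "iterations failed"
                )
            continue
        it_sse = {v: 0.0 for v in predicted_vars}
        for t, by_var in preds.items():
            for v, p in by_var.items():
                a = values[t, col_of[v]]
                if np.isnan(a):
                    continue
                e2 = (p - a) ** 2
                it_sse[v] += e2
                sq_err_sums[v] += e2
                preds_by_var_year[v].setdefault(t, []).append(p)
        per_iter_sse.append(it_sse)

    n_ok = len(per_iter_sse)
    if aggregation == "mean":
        sse_out = pd.Series(
            {
                v: float(np.mean([it[v] for it in per_iter_sse])) if n_ok else np.nan
                for v in predicted_vars
            }
        )
    else:
        sse_out = pd.Series({v: sq_err_sums[v] for v in predicted_vars})

    rows = []
    years = data.years
    for v in predicted_vars:
        for t, ps in sorted(preds_by_var_year[v].items()):
            arr = np.asarray(ps)
            m = float(arr.mean())
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            rows.append(
                {
                    "variable": v,
                    "year": int(years[t]),
                    "observed": float(values[t, col_of[v]]),
                    "boot_mean": m,
                    "boot_sd": sd,
                    "lo95": m - 1.96 * sd,
                    "hi95": m + 1.96 * sd,
                    "n_boot": len(arr),
                }
            )
    series = PredictionSeries(
        frame=pd.DataFrame(
            rows,
            columns=[
                "variable", "year", "observed", "boot_mean", "boot_sd",
                "lo95", "hi95", "n_boot",
            ],
        )
    )
    return sse_out, series


#: comparison order — ties in SSE break toward the simpler model
MODEL_ORDER = ("ARHMM", "ARDBN", "DDDBN")


def compare_models(
    data: EcosystemTable,
    confidence: EdgeConfidenceTable,
    n_boot: int = 250,
    em_config: EMConfig | None = None,
    seed: int = 0,
    models: Sequence[str] = MODEL_ORDER,
    aggregation: str = "mean",
) -> tuple[ModelComparisonTable, dict[str, PredictionSeries], dict[str, FittedModel]]:
    """Build ARHMM/ARDBN/DDDBN, evaluate each with shared bootstrap seeds,
    and mark the per-variable best (lowest-SSE) model."""
    builders = {
        "ARHMM": lambda: build_arhmm(data.descriptors),
        "ARDBN": lambda: build_ardbn(confidence, data.descriptors),
        "DDDBN": lambda: build_dddbn(confidence, data.descriptors),
    }
    unknown = [m for m in models if m not in builders]
    if unknown:
        raise ValueError(f"unknown models {unknown}")
    sses: dict[str, pd.Series] = {}
    series: dict[str, PredictionSeries] = {}
    fitted: dict[str, FittedModel] = {}
    em_config = em_config or EMConfig()
    for name in models:
        structure = builders[name]()
        base, _ = fit_em(structure, data, em_config)
        fitted[name] = base
        s, ps = evaluate_model(
            structure,
            data,
            n_boot=n_boot,
            em_config=em_config,
            seed=seed,  # shared across models: same splits
            base_model=base,
            aggregation=aggregation,
        )
        sses[name] = s
        series[name] = ps
    frame = pd.DataFrame(sses)
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    cols = sorted(frame.columns, key=lambda m: order.get(m, 99))
    frame = frame[cols]
    best = []
    for _, row in frame.iterrows():
        lo = row.min()
        winners = [m for m in cols if row[m] == lo]
        best.append(min(winners, key=lambda m: order.get(m, 99)))
    frame["best"] = best
    return ModelComparisonTable(frame=frame), series, fitted
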