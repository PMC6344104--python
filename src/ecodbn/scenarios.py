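"""Temperature press-perturbation scenarios.

A press is a sustained +Δ°C shift applied to the regional SST series only;
every other component's evidence is left untouched, and training is always
on the original measured data.  Because modeling happens on the
standardized scale, a physical delta converts to Δ / sd(SST series) model
units per series.  Baseline and scenario one-step predictions are then
compared year by year; the mean difference (scenario − baseline) per
predicted component is the press response, with uncertainty from the same
bootstrap parameter refits used in model evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dbn_core import FittedModel, forward_filter, predict_one_step
from .em_training import EMConfig, fit_em
from .evaluation import bootstrap_split
from .timeseries_io import EcosystemTable, StandardizationParams


@dataclass(frozen=True)
class ScenarioSpec:
    """One press: a temperature delta applied to the SST series.

    ``delta_scale`` is ``"raw"`` (Δ in °C, converted per series by its
    original standard deviation) or ``"standardized"`` (Δ already in model
    units).
    """

    delta_celsius: float
    target_variables: tuple[str, ...] = ()
    label: str = ""
    delta_scale: str = "raw"

    def __post_init__(self) -> None:
        if self.delta_celsius < 0:
            raise ValueError("delta must be >= 0")
        if self.delta_scale not in ("raw", "standardized"):
            raise ValueError(f"unknown delta_scale {self.delta_scale!r}")
        if not self.label:
            object.__setattr__(self, "label", f"+{self.delta_celsius:g}C")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            delta_celsius=float(doc["delta_celsius"]),
            target_variables=tuple(doc.get("targets", ())),
            label=str(doc.get("label", "")),
            delta_scale=str(doc.get("delta_scale", "raw")),
        )


@dataclass(frozen=True)
class ScenarioResult:
    """Baseline vs scenario predictions and their per-variable mean shift.

    ``series`` is tidy (variable, year, baseline, scenario, diff, boot_sd);
    ``mean_difference`` averages diff over all predicted years (standardized
    scale); ``mean_difference_sd`` is its bootstrap standard deviation.
    """

    label: str
    delta_celsius: float
    series: pd.DataFrame
    mean_difference: pd.Series
    mean_difference_sd: pd.Series

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_difference": self.mean_difference,
                "boot_sd": self.mean_difference_sd,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.series.to_csv(path, index=False)


def _resolve_targets(table: EcosystemTable, spec: ScenarioSpec) -> list[str]:
    targets = list(spec.target_variables) or table.sst_variables
    if not targets:
        raise ValueError("no SST target variables in spec or table")
    for t in targets:
        d = table.descriptor(t)  # raises KeyError for unknown names
        if not d.sst_region_flag:
            raise ValueError(f"target {t!r} is not an SST series")
    return targets


def perturb_sst(
    table: EcosystemTable,
    params: StandardizationParams,
    spec: ScenarioSpec,
) -> EcosystemTable:
    """Shift the SST columns by the press delta; all others bit-identical.

    On the standardized scale a physical +Δ°C press adds Δ/sd_original to
    each target column (sd in °C from the standardization params).
    """
    targets = _resolve_targets(table, spec)
    out = table.data.copy()
    for t in targets:
        if spec.delta_scale == "raw":
            if t not in params.sd:
                raise ValueError(f"no standardization params for SST series {t!r}")
            shift = spec.delta_celsius / params.sd[t]
        else:
            shift = spec.delta_celsius
        out[t] = table.data[t] + shift
    return table.with_data(out)


def _one_step_series(
    model: FittedModel,
    data: EcosystemTable,
    predicted_vars: Sequence[str],
    roll_predicted: bool = False,
) -> pd.DataFrame:
    """Predict every year from its predecessor's evidence.

    With ``roll_predicted`` the previous-year evidence of each *predicted*
    variable is its own prediction (driver variables stay at their values
    in ``data``), so a press on a driver propagates down directed chains of
    predicted components — one edge per year — instead of being clamped
    away by observed intermediaries.  Hidden-state filtering always uses
    ``data``.
    """
    values = data.values
    col_of = {c: i for i, c in enumerate(data.columns)}
    _, _, alpha = forward_filter(model, data)
    rows = []
    years = data.years
    predicted_set = set(predicted_vars)
    prev_pred: dict[str, float] | None = None
    for t in range(1, data.n_years):
        prev = values[t - 1]
        if np.all(np.isnan(prev)):
            prev_pred = None
            continue
        evidence = {c: float(prev[col_of[c]]) for c in data.columns}
        if roll_predicted and prev_pred is not None:
            for v in predicted_set:
                evidence[v] = prev_pred[v]
        pred = predict_one_step(model, evidence, hidden_prior=alpha[t - 1])
        prev_pred = {v: pred[v][0] for v in predicted_set}
        for v in predicted_vars:
            rows.append({"variable": v, "year": int(years[t]), "mean": pred[v][0]})
    return pd.DataFrame(rows)


def mean_difference(baseline: pd.DataFrame, scenario: pd.DataFrame) -> pd.Series:
    """Average over years of (scenario mean − baseline mean) per variable."""
    b = baseline.set_index(["variable", "year"])["mean"]
    s = scenario.set_index(["variable", "year"])["mean"]
    if not b.index.equals(s.index):
        raise ValueError("baseline and scenario years are misaligned")
    return (s - b).groupby("variable").mean()


def run_scenario(
    model: FittedModel,
    data: EcosystemTable,
    params: StandardizationParams,
    spec: ScenarioSpec,
    n_boot: int = 100,
    em_config: EMConfig | None = None,
    seed: int = 0,
) -> ScenarioResult:
    """Propagate one SST press through a fitted model.

    Training stays on the original data: each bootstrap iteration re-fits
    parameters on a resample of the original series (warm-started from the
    given model), then produces baseline predictions from the original
    evidence and scenario predictions from the perturbed evidence (hidden-
    state filtering uses the perturbed evidence too, so the SST regime
    chain responds to the press).  Reported are the point predictions from
    the given model and bootstrap standard deviations of the differences.
    """
    em_config = em_config or EMConfig()
    predicted_vars = data.predicted_variables or data.columns
    perturbed = perturb_sst(data, params, spec)

    base_pt = _one_step_series(model, data, predicted_vars, roll_predicted=True)
    scen_pt = _one_step_series(model, perturbed, predicted_vars, roll_predicted=True)
    diff_pt = mean_difference(base_pt, scen_pt)

    ss = np.random.SeedSequence(seed)
    boot_seeds = ss.spawn(n_boot)
    diffs: list[pd.Series] = []
    per_year_diffs: dict[tuple[str, int], list[float]] = {}
    for b in range(n_boot):
        split = bootstrap_split(data.n_years, boot_seeds[b])
        w = split.weights(data.n_years)
        model_b, _ = fit_em(
            model.structure, data, em_config, init_model=model, row_weights=w
        )
        base_b = _one_step_series(model_b, data, predicted_vars, roll_predicted=True)
        scen_b = _one_step_series(model_b, perturbed, predicted_vars, roll_predicted=True)
        diffs.append(mean_difference(base_b, scen_b))
        d = scen_b.set_index(["variable", "year"])["mean"] - base_b.set_index(
            ["variable", "year"]
        )["mean"]
        for key, val in d.items():
            per_year_diffs.setdefault(key, []).append(float(val))

    if diffs:
        diff_frame = pd.DataFrame(diffs)
        diff_sd = diff_frame.std(ddof=1) if len(diffs) > 1 else diff_frame.iloc[0] * 0.0
    else:
        diff_sd = diff_pt * 0.0

    b_idx = base_pt.set_index(["variable", "year"])
    s_idx = scen_pt.set_index(["variable", "year"])
    rows = []
    for (v, yr), brow in b_idx.iterrows():
        dlist = per_year_diffs.get((v, yr), [])
        rows.append(
            {
                "variable": v,
                "year": yr,
                "baseline": float(brow["mean"]),
                "scenario": float(s_idx.loc[(v, yr), "mean"]),
                "diff": float(s_idx.loc[(v, yr), "mean"] - brow["mean"]),
                "boot_sd": float(np.std(dlist, ddof=1)) if len(dlist) > 1 else 0.0,
            }
        )
    series = pd.DataFrame(
        rows, columns=["variable", "year", "baseline", "scenario", "diff", "boot_sd"]
    )
    return ScenarioResult(
        label=spec.label,
        delta_celsius=spec.delta_celsius,
        series=series,
        mean_difference=diff_pt,
        mean_difference_sd=diff_sd.reindex(diff_pt.index).fillna(0.0),
    )
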