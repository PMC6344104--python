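"""Dependency discovery and construction of the three model structures.

Dependencies among components are learned as a sparse directed graph by a
greedy hill-climb (single-edge additions, deletions, reversals) over a
node-decomposable Gaussian BIC score, restarted from random graphs and
repeated over a sliding window of years.  The fraction of window×restart
runs in which an edge appears in the locally optimal graph is its
confidence.  Learned parent→child relations are realized as lag-1 edges in
the two-slice network, because one-step prediction conditions on the
previous year's evidence only.

Three structures are built from the confidences:

* ARHMM   — one shared binary hidden regime; every component depends on the
            regime and its own previous value, nothing else.
* ARDBN   — two hidden regimes (one over the AMO-type index, one over the
            regional SST series); every component keeps its autoregressive
            link and gains its single highest-confidence learned parent.
* DDDBN   — same hidden regimes; autoregressive links only for hidden,
            climate and physiochemical nodes; every predicted component
            gets its top-confidence learned parents, at most three parents
            in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

from .dbn_core import HIDDEN, OBSERVED, NetworkStructure, NodeSpec
from .timeseries_io import EcosystemTable, VariableDescriptor

#: name of the hidden-regime posterior column added to the hill-climb data
HIDDEN_COLUMN = "HV"

#: hidden chain names of the two-regime models
HV_AMO = "HV AMO"
HV_SST = "HV SST"

#: minimum confidence for an edge to be a DDDBN candidate
CONFIDENCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class HillClimbConfig:
    """Sliding-window hill-climb settings.

    Defaults target a ~32-year annual series: 10-year windows, stride 1,
    10 restarts per window → 230 runs, enough for stable confidences.
    """

    window_length: int = 10
    window_stride: int = 1
    n_restarts: int = 10
    score: str = "bic"
    max_parents: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.window_length < 3:
            raise ValueError("window_length must be >= 3")
        if self.score != "bic":
            raise ValueError(f"unknown score {self.score!r}")


@dataclass(frozen=True)
class EdgeConfidenceTable:
    """Confidence per directed parent→child edge, in [0, 1]."""

    confidence: pd.DataFrame  # columns: parent, child, confidence
    n_runs: int

    def __post_init__(self) -> None:
        cols = list(self.confidence.columns)
        if cols != ["parent", "child", "confidence"]:
            raise ValueError(f"bad columns {cols}")
        c = self.confidence["confidence"]
        if len(c) and (c.min() < 0 or c.max() > 1):
            raise ValueError("confidence outside [0, 1]")

    def lookup(self, parent: str, child: str) -> float:
        m = self.confidence[
            (self.confidence["parent"] == parent) & (self.confidence["child"] == child)
        ]
        return float(m["confidence"].iloc[0]) if len(m) else 0.0

    def candidates_for(self, child: str) -> pd.DataFrame:
        """Scored parents of a child, best first (ties: lexicographic name)."""
        m = self.confidence[self.confidence["child"] == child]
        return m.sort_values(
            ["confidence", "parent"], ascending=[False, True]
        ).reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.confidence.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class _FamilyScorer:
    """Cached per-child BIC on the lag-1 design of one data window.

    Rows pair each year's value with the previous year's values of the
    candidate parents; the family score is the maximized Gaussian
    log-likelihood minus (k/2)·log n.  Gram matrices are precomputed so a
    family evaluation is a small linear solve.
    """

    def __init__(self, values: np.ndarray, names: Sequence[str]):
        self.names = list(names)
        self.index = {n: i for i, n in enumerate(self.names)}
        Y = values[1:]          # child values at t
        Xlag = values[:-1]      # parent values at t-1
        self.row_ok = ~np.isnan(Y).any(axis=1) & ~np.isnan(Xlag).any(axis=1)
        self.Y = Y[self.row_ok]
        self.Z = np.concatenate(
            [np.ones((self.row_ok.sum(), 1)), Xlag[self.row_ok]], axis=1
        )
        self.n = self.Y.shape[0]
        self.G = self.Z.T @ self.Z                  # Gram over [1, x_lag]
        self.Gy = self.Z.T @ self.Y                 # cross-products per child
        self.yy = np.einsum("ij,ij->j", self.Y, self.Y)
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def family_score(self, child: str, parents: Iterable[str]) -> float:
        ci = self.index[child]
        pidx = frozenset(self.index[p] for p in parents)
        key = (ci, pidx)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        k = len(pidx) + 2  # intercept + weights + variance
        n = self.n
        if n <= k - 1:
            score = -np.inf
        else:
            cols = [0] + [j + 1 for j in sorted(pidx)]
            G = self.G[np.ix_(cols, cols)]
            gy = self.Gy[cols, ci]
            try:
                beta = np.linalg.solve(G, gy)
            except np.linalg.LinAlgError:
                beta = np.linalg.solve(G + 1e-10 * np.eye(len(cols)), gy)
            rss = self.yy[ci] - 2 * beta @ gy + beta @ G @ beta
            s2 = max(rss / n, 1e-12)
            loglik = -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)
            score = loglik - 0.5 * k * math.log(n)
        self._cache[key] = score
        return score


def score_structure(structure: NetworkStructure, data: EcosystemTable) -> float:
    """Node-decomposable BIC of a structure's observed families.

    Each observed node is scored by OLS of its value at t on its lag-1
    parents (inter-slice edges); the total is the sum of family scores.
    Hidden nodes carry no data column and contribute nothing here.
    """
    scorer = _FamilyScorer(data.values, data.columns)
    total = 0.0
    for name in structure.observed_names:
        if name not in scorer.index:
            raise ValueError(f"no data column for node {name!r}")
        parents = [
            p for p, lag in structure.cont_parents(name) if lag == 1 and p in scorer.index
        ]
        total += scorer.family_score(name, parents)
    return total


# ---------------------------------------------------------------------------
# hill-climb
# ---------------------------------------------------------------------------

def _random_projection(
    names: Sequence[str], max_parents: int, rng: np.random.Generator
) -> dict[str, set[str]]:
    """Random sparse parent sets (the search's restart point)."""
    parents: dict[str, set[str]] = {n: set() for n in names}
    n = len(names)
    n_seed_edges = rng.integers(0, max(n // 2, 1) + 1)
    for _ in range(n_seed_edges):
        u, v = rng.choice(n, size=2, replace=False)
        pu, pv = names[u], names[v]
        if len(parents[pv]) < max_parents and pu not in parents[pv] and pv not in parents[pu]:
            parents[pv].add(pu)
    return parents


def _hill_climb_projection(
    scorer: _FamilyScorer,
    config: HillClimbConfig,
    rng: np.random.Generator,
) -> dict[str, set[str]]:
    """Greedy local search over the parent→child projection digraph.

    Moves: add, delete or reverse one edge, keeping the projection acyclic
    and parent counts ≤ max_parents.  (Edges are realized as lag-1 links in
    the two-slice model; the acyclicity constraint on the projection keeps
    the learned relations interpretable as a DAG, as in a static network.)
    """
    names = scorer.names
    parents = _random_projection(names, config.max_parents, rng)

    def creates_cycle(parents_map, u, v) -> bool:
        # would u→v close a directed cycle? (search ancestors of u)
        stack, seen = [u], set()
        while stack:
            x = stack.pop()
            if x == v:
                return True
            for p in parents_map[x]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return False

    current = {c: scorer.family_score(c, parents[c]) for c in names}
    improved = True
    while improved:
        improved = False
        best_delta = 1e-10
        best_move = None
        for child in names:
            base = current[child]
            pset = parents[child]
            # deletions
            for p in list(pset):
                delta = scorer.family_score(child, pset - {p}) - base
                if delta > best_delta:
                    best_delta, best_move = delta, ("del", p, child)
            # additions
            if len(pset) < config.max_parents:
                for p in names:
                    if p == child or p in pset:
                        continue
                    if creates_cycle(parents, p, child):
                        continue
                    delta = scorer.family_score(child, pset | {p}) - base
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", p, child)
            # reversals: p→child becomes child→p
            for p in list(pset):
                if len(parents[p]) >= config.max_parents:
                    continue
                trial = {c: set(s) for c, s in parents.items()}
                trial[child].discard(p)
                if creates_cycle(trial, child, p):
                    continue
                delta = (
                    scorer.family_score(child, pset - {p})
                    - base
                    + scorer.family_score(p, parents[p] | {child})
                    - current[p]
                )
                if delta > best_delta:
                    best_delta, best_move = delta, ("rev", p, child)
        if best_move is not None:
            op, p, child = best_move
            if op == "del":
                parents[child].discard(p)
            elif op == "add":
                parents[child].add(p)
            else:
                parents[child].discard(p)
                parents[p].add(child)
                current[p] = scorer.family_score(p, parents[p])
            current[child] = scorer.family_score(child, parents[child])
            improved = True
    return parents


def _projection_to_structure(parents: dict[str, set[str]]) -> NetworkStructure:
    names = sorted(parents)
    nodes = tuple(NodeSpec(name=n, kind=OBSERVED) for n in names)
    inter = tuple(
        sorted((p, c) for c, ps in parents.items() for p in ps)
    )
    return NetworkStructure(nodes=nodes, intra_edges=(), inter_edges=inter)


def hill_climb(
    data: EcosystemTable | pd.DataFrame,
    config: HillClimbConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> NetworkStructure:
    """One hill-climb run on a data window; deterministic given the seed."""
    values = data.values if isinstance(data, EcosystemTable) else data.to_numpy(float)
    names = data.columns if isinstance(data, EcosystemTable) else list(data.columns)
    scorer = _FamilyScorer(values, names)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    parents = _hill_climb_projection(scorer, config, rng)
    return _projection_to_structure(parents)


def edge_confidence(
    data: EcosystemTable,
    config: HillClimbConfig,
    hidden_posterior: np.ndarray | None = None,
) -> EdgeConfidenceTable:
    """Edge frequencies over every window × restart hill-climb run.

    ``hidden_posterior`` (per-year probability of regime state 1, from the
    ARHMM's smoothed inference) is appended to the data matrix as a
    continuous column named ``HV`` so hidden↔observed relations can be
    learned alongside the measured components.
    """
    df = data.data.copy()
    if hidden_posterior is not None:
        hp = np.asarray(hidden_posterior, dtype=float)
        if hp.shape != (data.n_years,):
            raise ValueError("hidden_posterior length mismatch")
        df[HIDDEN_COLUMN] = hp
    T = len(df)
    if T < config.window_length:
        raise ValueError("series shorter than window_length")
    # deterministic column order regardless of input ordering
    df = df[sorted(df.columns)]
    starts = list(range(0, T - config.window_length + 1, config.window_stride))
    ss = np.random.SeedSequence(config.seed)
    run_seeds = ss.spawn(len(starts) * config.n_restarts)
    counts: dict[tuple[str, str], int] = {}
    n_runs = 0
    for wi, start in enumerate(starts):
        window = df.iloc[start : start + config.window_length]
        scorer = _FamilyScorer(window.to_numpy(float), list(window.columns))
        for ri in range(config.n_restarts):
            rng = np.random.default_rng(run_seeds[wi * config.n_restarts + ri])
            parents = _hill_climb_projection(scorer, config, rng)
            n_runs += 1
            for child, ps in parents.items():
                for p in ps:
                    counts[(p, child)] = counts.get((p, child), 0) + 1
    rows = [
        {"parent": p, "child": c, "confidence": n / n_runs}
        for (p, c), n in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["parent", "child", "confidence"])
    return EdgeConfidenceTable(confidence=table, n_runs=n_runs)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _observed_nodes(variables: Sequence[VariableDescriptor]) -> tuple[NodeSpec, ...]:
    return tuple(NodeSpec(name=d.name, kind=OBSERVED) for d in variables)


def build_arhmm(variables: Sequence[VariableDescriptor]) -> NetworkStructure:
    """Shared binary regime + autoregressive link for every component."""
    if not variables:
        raise ValueError("need at least one observed variable")
    hidden = NodeSpec(name=HIDDEN_COLUMN, kind=HIDDEN, cardinality=2)
    nodes = _observed_nodes(variables) + (hidden,)
    intra = tuple((HIDDEN_COLUMN, d.name) for d in variables)
    inter = tuple((d.name, d.name) for d in variables) + ((HIDDEN_COLUMN, HIDDEN_COLUMN),)
    return NetworkStructure(nodes=nodes, intra_edges=intra, inter_edges=inter)


def _two_hidden_nodes(
    variables: Sequence[VariableDescriptor],
) -> tuple[tuple[NodeSpec, NodeSpec], tuple[tuple[str, str], ...], tuple[tuple[str, str], ...]]:
    """The two regime chains and their mandated links.

    The AMO regime drives the non-SST climate indices; the SST regime
    drives every regional SST series.
    """
    amo_children = [
        d.name for d in variables if d.category == "climate" and not d.sst_region_flag
    ]
    sst_children = [d.name for d in variables if d.sst_region_flag]
    hv_amo = NodeSpec(name=HV_AMO, kind=HIDDEN, cardinality=2)
    hv_sst = NodeSpec(name=HV_SST, kind=HIDDEN, cardinality=2)
    intra = tuple((HV_AMO, c) for c in amo_children) + tuple(
        (HV_SST, c) for c in sst_children
    )
    inter = ((HV_AMO, HV_AMO), (HV_SST, HV_SST))
    return (hv_amo, hv_sst), intra, inter


def _allocate_hidden_parent(child: VariableDescriptor) -> str:
    # learned HV→child edges are split between the two chains: non-SST
    # climate children belong to the AMO regime, everything else to the
    # broader SST regime
    if child.category == "climate" and not child.sst_region_flag:
        return HV_AMO
    return HV_SST


def build_ardbn(
    confidence: EdgeConfidenceTable,
    variables: Sequence[VariableDescriptor],
) -> NetworkStructure:
    """Autoregressive DBN: AR links + one learned parent per predicted node."""
    by_name = {d.name: d for d in variables}
    (hv_amo, hv_sst), intra, inter = _two_hidden_nodes(variables)
    nodes = _observed_nodes(variables) + (hv_amo, hv_sst)
    intra_edges = list(intra)
    inter_edges = list(inter) + [(d.name, d.name) for d in variables]
    for d in variables:
        if not d.predicted_flag:
            continue
        cands = confidence.candidates_for(d.name)
        cands = cands[cands["parent"] != d.name]  # self link already present
        if len(cands) == 0:
            raise ValueError(f"no scored candidate parent for child {d.name!r}")
        top = str(cands["parent"].iloc[0])
        if top == HIDDEN_COLUMN:
            intra_edges.append((_allocate_hidden_parent(d), d.name))
        else:
            inter_edges.append((top, d.name))
    return NetworkStructure(
        nodes=nodes,
        intra_edges=tuple(dict.fromkeys(intra_edges)),
        inter_edges=tuple(dict.fromkeys(inter_edges)),
    )


def learn_confidence(
    data: EcosystemTable,
    config: HillClimbConfig,
    em_config=None,
) -> EdgeConfidenceTable:
    """Full dependency-learning pipeline.

    Fits the ARHMM by EM, takes the smoothed posterior probability of
    regime state 1 as a continuous ``HV`` column, and runs the sliding-
    window hill-climb over the augmented data matrix.
    """
    from .dbn_core import infer_hidden
    from .em_training import fit_em

    arhmm = build_arhmm(data.descriptors)
    model, _ = fit_em(arhmm, data, em_config)
    posterior = infer_hidden(model, data)[HIDDEN_COLUMN][:, 1]
    return edge_confidence(data, config, hidden_posterior=posterior)


def build_dddbn(
    confidence: EdgeConfidenceTable,
    variables: Sequence[VariableDescriptor],
    max_parents: int = 3,
    threshold: float = CONFIDENCE_THRESHOLD,
) -> NetworkStructure:
    """Data-driven DBN: learned parents (≤ max_parents), AR only for drivers."""
    (hv_amo, hv_sst), intra, inter = _two_hidden_nodes(variables)
    nodes = _observed_nodes(variables) + (hv_amo, hv_sst)
    intra_edges = list(intra)
    inter_edges = list(inter)
    driver_categories = ("climate", "physiochemical")
    for d in variables:
        if d.category in driver_categories:
            inter_edges.append((d.name, d.name))
    for d in variables:
        if not d.predicted_flag:
            continue
        cands = confidence.candidates_for(d.name)
        cands = cands[cands["parent"] != d.name]
        if len(cands) == 0:
            raise ValueError(f"no scored candidate parent for child {d.name!r}")
        above = cands[cands["confidence"] >= threshold]
        # every predicted node needs at least one parent: when nothing
        # clears the bar, keep the single highest-confidence candidate
        cands = above if len(above) else cands.iloc[:1]
        n_parents = 0
        for _, row in cands.iterrows():
            if n_parents >= max_parents:
                break
            p = str(row["parent"])
            if p == HIDDEN_COLUMN:
                edge = (_allocate_hidden_parent(d), d.name)
                if edge not in intra_edges:
                    intra_edges.append(edge)
                    n_parents += 1
            else:
                edge = (p, d.name)
                if edge not in inter_edges:
                    # lag-1 edges cannot close a cycle in the unrolled
                    # two-slice graph, so no acyclicity skip is needed here
                    inter_edges.append(edge)
                    n_parents += 1
    return NetworkStructure(
        nodes=nodes,
        intra_edges=tuple(dict.fromkeys(intra_edges)),
        inter_edges=tuple(dict.fromkeys(inter_edges)),
    )
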