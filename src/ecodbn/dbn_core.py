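"""Two-slice conditional linear Gaussian DBNs with binary hidden chains.

The model class: observed ecosystem components are scalar Gaussian nodes
whose mean is linear in their continuous parents, with parameters switched
by the states of discrete (binary) hidden parents,

    Y | X = x, Q = i  ~  N(mu_i + W_i · x, sigma2_i).

Temporal structure is a two-slice network: observed→observed dependencies
are lag-1 inter-slice edges (a child at year t depends on its parents'
values at year t−1), hidden→observed edges are intra-slice (the current
regime switches the current year's parameters), and each hidden node is a
first-order Markov chain via its inter-slice self-link.  Prediction at year
t therefore needs only the observed evidence at t−1 plus a belief over the
hidden states.

Inference is exact: with at most a handful of binary chains the joint
hidden state space is tiny, and filtering/smoothing run on the product
chain.  Missing observations are marginalized exactly — a missing entry
simply contributes no emission factor.  A year where a node's continuous
parent value is unavailable likewise contributes no emission for that node.
Nodes with lag-1 parents contribute emissions from the second year onward
(the model conditions on the first slice).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .timeseries_io import EcosystemTable, VariableDescriptor

OBSERVED = "observed_continuous"
HIDDEN = "hidden_discrete"

_LOG2PI = math.log(2.0 * math.pi)

#: lower bound on emission variances (standardized units squared)
VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class NodeSpec:
    """One node of the two-slice network."""

    name: str
    kind: str = OBSERVED
    cardinality: int = 1
    autoregressive_allowed: bool = True

    def __post_init__(self) -> None:
        if self.kind not in (OBSERVED, HIDDEN):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == HIDDEN and self.cardinality != 2:
            raise ValueError(
                f"hidden node {self.name!r} must be binary (got cardinality "
                f"{self.cardinality})"
            )
        if self.kind == OBSERVED and self.cardinality != 1:
            raise ValueError(f"observed node {self.name!r} must be scalar")


@dataclass(frozen=True)
class NetworkStructure:
    """Directed two-slice structure over observed and hidden nodes.

    ``intra_edges`` live within a time slice (used for hidden→observed
    regime switching); ``inter_edges`` go from slice t−1 to slice t (lag-1
    dependencies and the hidden chains' self-links).
    """

    nodes: tuple[NodeSpec, ...]
    intra_edges: tuple[tuple[str, str], ...] = ()
    inter_edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        kind = {n.name: n.kind for n in self.nodes}
        for u, v in self.intra_edges + self.inter_edges:
            if u not in kind or v not in kind:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
        for u, v in self.intra_edges:
            if kind[v] == HIDDEN:
                raise ValueError(
                    f"intra-slice edge into hidden node {v!r} not allowed"
                )
        for u, v in self.inter_edges:
            if kind[u] == HIDDEN and u != v:
                raise ValueError(
                    f"hidden node {u!r} may only have an inter-slice self-link"
                )
            if kind[v] == HIDDEN and u != v:
                raise ValueError(f"observed→hidden edge ({u!r}, {v!r}) not allowed")
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(self.intra_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("intra-slice graph has a cycle")
        # inter-slice edges always point forward in time, so the unrolled
        # two-slice graph is acyclic iff the intra-slice graph is.

    # -- accessors --------------------------------------------------------
    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def observed_names(self) -> list[str]:
        return [n.name for n in self.nodes if n.kind == OBSERVED]

    @property
    def hidden_names(self) -> list[str]:
        return [n.name for n in self.nodes if n.kind == HIDDEN]

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def cont_parents(self, name: str) -> tuple[tuple[str, int], ...]:
        """Continuous parents of an observed node as (name, lag) pairs.

        lag 0 for intra-slice parents, 1 for inter-slice (previous-year)
        parents.  Order is canonical: intra first, then inter, each sorted
        by name — parameter weight vectors follow this order.
        """
        kind = {n.name: n.kind for n in self.nodes}
        intra = sorted(u for u, v in self.intra_edges if v == name and kind[u] == OBSERVED)
        inter = sorted(u for u, v in self.inter_edges if v == name and kind[u] == OBSERVED)
        return tuple((p, 0) for p in intra) + tuple((p, 1) for p in inter)

    def disc_parents(self, name: str) -> tuple[str, ...]:
        kind = {n.name: n.kind for n in self.nodes}
        return tuple(
            sorted(u for u, v in self.intra_edges if v == name and kind[u] == HIDDEN)
        )

    def n_parents(self, name: str) -> int:
        return len(self.cont_parents(name)) + len(self.disc_parents(name))

    def intra_topo_order(self) -> list[str]:
        """Observed nodes ordered so intra-slice parents precede children."""
        g = nx.DiGraph()
        g.add_nodes_from(self.observed_names)
        kind = {n.name: n.kind for n in self.nodes}
        for u, v in self.intra_edges:
            if kind[u] == OBSERVED and kind[v] == OBSERVED:
                g.add_edge(u, v)
        return list(nx.lexicographical_topological_sort(g))

    def to_dot(self) -> str:
        lines = ["digraph two_slice {", "  rankdir=LR;"]
        for n in self.nodes:
            shape = "box" if n.kind == HIDDEN else "ellipse"
            lines.append(f'  "{n.name}" [shape={shape}];')
        for u, v in self.intra_edges:
            lines.append(f'  "{u}" -> "{v}";')
        for u, v in self.inter_edges:
            lines.append(f'  "{u}" -> "{v}" [style=dashed, label="t-1"];')
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class CLGNodeParams:
    """Per-configuration CLG parameters of one observed node.

    ``mu``, ``W`` and ``sigma2`` are indexed by the discrete-parent
    configuration (row-major over ``cards``); ``W`` columns follow the
    canonical continuous-parent order of :meth:`NetworkStructure.cont_parents`.
    """

    node: str
    cont_parents: tuple[tuple[str, int], ...]
    disc_parents: tuple[str, ...]
    cards: tuple[int, ...]
    mu: np.ndarray
    W: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        n_cfg = int(np.prod(self.cards)) if self.cards else 1
        mu = np.asarray(self.mu, dtype=float)
        W = np.asarray(self.W, dtype=float).reshape(n_cfg, len(self.cont_parents))
        s2 = np.asarray(self.sigma2, dtype=float)
        if mu.shape != (n_cfg,) or s2.shape != (n_cfg,):
            raise ValueError(
                f"node {self.node!r}: expected {n_cfg} configurations, got "
                f"mu {mu.shape}, sigma2 {s2.shape}"
            )
        if np.any(s2 <= 0):
            raise ValueError(f"node {self.node!r}: non-positive variance")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "sigma2", s2)

    @property
    def n_configs(self) -> int:
        return len(self.mu)


@dataclass(frozen=True)
class HiddenChainParams:
    """Initial distribution and transition matrix of one hidden chain."""

    pi: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if pi.ndim != 1 or A.shape != (len(pi), len(pi)):
            raise ValueError("pi/A shape mismatch")
        if np.any(pi < 0) or np.any(A < 0):
            raise ValueError("negative probabilities")
        if not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("pi must sum to 1")
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of A must sum to 1")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "A", A)


@dataclass(frozen=True)
class FittedModel:
    """A structure together with all CLG and hidden-chain parameters."""

    structure: NetworkStructure
    node_params: Mapping[str, CLGNodeParams]
    chain_params: Mapping[str, HiddenChainParams]

    def __post_init__(self) -> None:
        s = self.structure
        for name in s.observed_names:
            if name not in self.node_params:
                raise ValueError(f"missing parameters for observed node {name!r}")
            p = self.node_params[name]
            if p.cont_parents != s.cont_parents(name) or p.disc_parents != s.disc_parents(name):
                raise ValueError(
                    f"parameters of {name!r} reference parents not matching the structure"
                )
        for name in s.hidden_names:
            if name not in self.chain_params:
                raise ValueError(f"missing chain parameters for hidden node {name!r}")

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format": "ecodbn-model",
            "version": 1,
            "nodes": [
                {
                    "name": n.name,
                    "kind": n.kind,
                    "cardinality": n.cardinality,
                    "autoregressive_allowed": n.autoregressive_allowed,
                }
                for n in self.structure.nodes
            ],
            "intra_edges": [list(e) for e in self.structure.intra_edges],
            "inter_edges": [list(e) for e in self.structure.inter_edges],
            "node_params": {
                k: {
                    "cont_parents": [list(p) for p in v.cont_parents],
                    "disc_parents": list(v.disc_parents),
                    "cards": list(v.cards),
                    "mu": v.mu.tolist(),
                    "W": v.W.tolist(),
                    "sigma2": v.sigma2.tolist(),
                }
                for k, v in self.node_params.items()
            },
            "chain_params": {
                k: {"pi": v.pi.tolist(), "A": v.A.tolist()}
                for k, v in self.chain_params.items()
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        if doc.get("format") != "ecodbn-model":
            raise ValueError("not an ecodbn model document")
        structure = NetworkStructure(
            nodes=tuple(NodeSpec(**n) for n in doc["nodes"]),
            intra_edges=tuple(tuple(e) for e in doc["intra_edges"]),
            inter_edges=tuple(tuple(e) for e in doc["inter_edges"]),
        )
        node_params = {
            k: CLGNodeParams(
                node=k,
                cont_parents=tuple((p, int(l)) for p, l in v["cont_parents"]),
                disc_parents=tuple(v["disc_parents"]),
                cards=tuple(v["cards"]),
                mu=np.array(v["mu"]),
                W=np.array(v["W"]),
                sigma2=np.array(v["sigma2"]),
            )
            for k, v in doc["node_params"].items()
        }
        chain_params = {
            k: HiddenChainParams(pi=np.array(v["pi"]), A=np.array(v["A"]))
            for k, v in doc["chain_params"].items()
        }
        return cls(structure=structure, node_params=node_params, chain_params=chain_params)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def clg_logdensity(
    y: float,
    x: Sequence[float],
    q: int,
    params: CLGNodeParams,
) -> float:
    """log N(y; mu_q + W_q·x, sigma2_q) for one node and configuration."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(params.cont_parents),):
        raise ValueError(
            f"expected {len(params.cont_parents)} continuous parent values, got {x.shape}"
        )
    if not 0 <= q < params.n_configs:
        raise ValueError(f"configuration {q} out of range [0, {params.n_configs})")
    s2 = params.sigma2[q]
    mean = params.mu[q] + float(params.W[q] @ x)
    return -0.5 * (_LOG2PI + math.log(s2) + (y - mean) ** 2 / s2)


# ---------------------------------------------------------------------------
# joint hidden chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointChain:
    """Product chain over all hidden nodes (exact inference support)."""

    names: tuple[str, ...]
    cards: tuple[int, ...]
    states: np.ndarray  # (K, n_hidden) state of each chain per joint state
    pi: np.ndarray      # (K,)
    A: np.ndarray       # (K, K)

    @property
    def K(self) -> int:
        return len(self.pi)

    def marginalize(self, dist: np.ndarray, name: str) -> np.ndarray:
        """Marginal distribution of one chain from a 1-d joint distribution."""
        i = self.names.index(name)
        return np.array(
            [dist[self.states[:, i] == s].sum() for s in range(self.cards[i])]
        )

    def config_index(self, params: CLGNodeParams) -> np.ndarray:
        """Map each joint state to the node's discrete-parent configuration."""
        if not params.disc_parents:
            return np.zeros(self.K, dtype=int)
        idx = [self.names.index(h) for h in params.disc_parents]
        sub = self.states[:, idx]
        return np.ravel_multi_index(sub.T, params.cards)


def joint_chain(model: FittedModel) -> JointChain:
    names = tuple(model.structure.hidden_names)
    if not names:
        return JointChain(
            names=(), cards=(), states=np.zeros((1, 0), dtype=int),
            pi=np.ones(1), A=np.ones((1, 1)),
        )
    cards = tuple(model.structure.node(n).cardinality for n in names)
    states = np.array(list(itertools.product(*(range(c) for c in cards))), dtype=int)
    K = len(states)
    pi = np.ones(K)
    A = np.ones((K, K))
    for i, n in enumerate(names):
        cp = model.chain_params[n]
        pi *= cp.pi[states[:, i]]
        A *= cp.A[states[:, i][:, None], states[:, i][None, :]]
    return JointChain(names=names, cards=cards, states=states, pi=pi, A=A)


def _lagged_value_matrix(
    values: np.ndarray,
    col_of: Mapping[str, int],
    cont_parents: tuple[tuple[str, int], ...],
) -> np.ndarray:
    """(T, n_parents) matrix of parent values; NaN where unavailable."""
    T = values.shape[0]
    X = np.full((T, len(cont_parents)), np.nan)
    for j, (p, lag) in enumerate(cont_parents):
        col = values[:, col_of[p]]
        if lag == 0:
            X[:, j] = col
        else:
            X[1:, j] = col[:-1]
    return X


def emission_log_matrix(
    model: FittedModel,
    data: EcosystemTable,
    row_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, JointChain]:
    """Total emission log-density per (year, joint hidden state).

    Missing observations (or missing parent values) contribute nothing for
    the affected node-year: exact marginalization of missing entries.
    ``row_weights`` raises each year's emission to a power (weighted-
    likelihood bootstrap: a year's resample multiplicity; 0 for out-of-bag
    years, which are thereby marginalized).
    """
    chain = joint_chain(model)
    values = data.values
    col_of = {c: i for i, c in enumerate(data.columns)}
    T = values.shape[0]
    if row_weights is not None:
        w = np.asarray(row_weights, dtype=float)
        if w.shape != (T,):
            raise ValueError("row_weights length mismatch")
    else:
        w = None
    logB = np.zeros((T, chain.K))
    for name in model.structure.observed_names:
        p = model.node_params[name]
        y = values[:, col_of[name]]
        X = _lagged_value_matrix(values, col_of, p.cont_parents)
        valid = ~np.isnan(y)
        if p.cont_parents:
            valid &= ~np.isnan(X).any(axis=1)
        if w is not None:
            valid &= w > 0
        if not valid.any():
            continue
        cfg = chain.config_index(p)
        tt = np.flatnonzero(valid)
        Xv = np.nan_to_num(X[tt])
        yv = y[tt]
        wv = w[tt] if w is not None else 1.0
        for i in np.unique(cfg):
            mean = p.mu[i] + Xv @ p.W[i]
            lp = -0.5 * (_LOG2PI + math.log(p.sigma2[i]) + (yv - mean) ** 2 / p.sigma2[i])
            lp = lp * wv
            cols = np.flatnonzero(cfg == i)
            logB[np.ix_(tt, cols)] += lp[:, None]
    return logB, chain


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _scaled_forward(
    pi: np.ndarray, A: np.ndarray, logB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward recursion; returns (alpha, per-t log-normalizers, loglik)."""
    T, K = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    alpha = np.zeros((T, K))
    logc = np.zeros(T)
    a = pi * B[0]
    c = a.sum()
    if c <= 0:
        return alpha, logc, -np.inf
    alpha[0] = a / c
    logc[0] = math.log(c) + shift[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c = a.sum()
        if c <= 0:
            return alpha, logc, -np.inf
        alpha[t] = a / c
        logc[t] = math.log(c) + shift[t]
    return alpha, logc, float(logc.sum())


def forward_filter(
    model: FittedModel,
    data: EcosystemTable,
    row_weights: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], float, np.ndarray]:
    """Filtered hidden posteriors P(H^t | X^1..X^t) and log P(X | θ).

    Returns per-chain filtered marginals (name → (T, card) array), the
    observed-data log-likelihood, and the joint filtered distribution
    (T, K) over the product chain.
    """
    logB, chain = emission_log_matrix(model, data, row_weights)
    alpha, _, loglik = _scaled_forward(chain.pi, chain.A, logB)
    marg = {
        n: _chain_marginals(alpha, chain, n) for n in chain.names
    }
    return marg, loglik, alpha


def _chain_marginals(joint_t: np.ndarray, chain: JointChain, name: str) -> np.ndarray:
    i = chain.names.index(name)
    card = chain.cards[i]
    T = joint_t.shape[0]
    out = np.zeros((T, card))
    for s in range(card):
        out[:, s] = joint_t[:, chain.states[:, i] == s].sum(axis=1)
    return out


def forward_backward(
    model: FittedModel,
    data: EcosystemTable,
    row_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, JointChain]:
    """Smoothed joint posteriors γ (T, K), pairwise ξ (T−1, K, K), loglik."""
    logB, chain = emission_log_matrix(model, data, row_weights)
    T, K = logB.shape
    alpha, logc, loglik = _scaled_forward(chain.pi, chain.A, logB)
    if not np.isfinite(loglik):
        raise FloatingPointError("zero-probability evidence in forward pass")
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    beta = np.ones((T, K))
    for t in range(T - 2, -1, -1):
        b = chain.A @ (B[t + 1] * beta[t + 1])
        s = b.sum()
        beta[t] = b / s if s > 0 else b
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.zeros((max(T - 1, 0), K, K))
    for t in range(T - 1):
        m = alpha[t][:, None] * chain.A * (B[t + 1] * beta[t + 1])[None, :]
        tot = m.sum()
        if tot > 0:
            xi[t] = m / tot
    return gamma, xi, loglik, chain


def infer_hidden(
    model: FittedModel, data: EcosystemTable
) -> dict[str, np.ndarray]:
    """Per-year smoothed posterior P(H^t | X^1..X^T) for each hidden chain."""
    gamma, _, _, chain = forward_backward(model, data)
    return {n: _chain_marginals(gamma, chain, n) for n in chain.names}


def joint_loglik_complete(
    model: FittedModel,
    data: EcosystemTable,
    hidden_path: Mapping[str, Sequence[int]],
) -> float:
    """Complete-data log P(X, H=h | θ) for a stated hidden path."""
    T = data.n_years
    total = 0.0
    for name in model.structure.hidden_names:
        cp = model.chain_params[name]
        path = np.asarray(hidden_path[name], dtype=int)
        if len(path) != T:
            raise ValueError(f"hidden path for {name!r} has length {len(path)} != {T}")
        card = model.structure.node(name).cardinality
        if path.min() < 0 or path.max() >= card:
            raise ValueError(f"hidden state out of range for {name!r}")
        with np.errstate(divide="ignore"):
            total += float(np.log(cp.pi[path[0]]))
            total += float(np.log(cp.A[path[:-1], path[1:]]).sum())
    values = data.values
    col_of = {c: i for i, c in enumerate(data.columns)}
    for name in model.structure.observed_names:
        p = model.node_params[name]
        y = values[:, col_of[name]]
        X = _lagged_value_matrix(values, col_of, p.cont_parents)
        for t in range(T):
            if np.isnan(y[t]) or (p.cont_parents and np.isnan(X[t]).any()):
                continue
            if p.disc_parents:
                states = tuple(int(hidden_path[h][t]) for h in p.disc_parents)
                q = int(np.ravel_multi_index(states, p.cards))
            else:
                q = 0
            total += clg_logdensity(float(y[t]), X[t], q, p)
    return total


# ---------------------------------------------------------------------------
# prediction and sampling
# ---------------------------------------------------------------------------

def predict_one_step(
    model: FittedModel,
    evidence_prev: Mapping[str, float],
    hidden_prior: Mapping[str, np.ndarray] | np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Predict mean and variance of every observed node one year ahead.

    ``evidence_prev`` holds the observed values at year t−1 (missing or NaN
    values are replaced by 0, the standardized mean).  ``hidden_prior`` is
    the belief over hidden states at t−1: either a dict of per-chain
    distributions, a joint distribution over the product chain (exact), or
    None for the stationary initial distributions.  It is propagated one
    step through the transition matrices; the returned mean and variance
    are the mixture moments over the resulting hidden belief (law of total
    variance).  Intra-slice observed parents are resolved in topological
    order using their predicted means.
    """
    chain = joint_chain(model)
    if hidden_prior is None:
        prior = chain.pi
    elif isinstance(hidden_prior, np.ndarray):
        if hidden_prior.shape != (chain.K,):
            raise ValueError("joint hidden prior has wrong length")
        prior = hidden_prior
    else:
        prior = np.ones(chain.K)
        for i, n in enumerate(chain.names):
            d = np.asarray(hidden_prior[n], dtype=float)
            prior = prior * d[chain.states[:, i]]
    p_t = prior @ chain.A  # belief over joint hidden state at t
    p_t = p_t / p_t.sum()

    out: dict[str, tuple[float, float]] = {}
    for name in model.structure.intra_topo_order():
        params = model.node_params[name]
        x = np.zeros(len(params.cont_parents))
        for j, (parent, lag) in enumerate(params.cont_parents):
            if lag == 1:
                v = evidence_prev.get(parent, 0.0)
                x[j] = 0.0 if v is None or (isinstance(v, float) and math.isnan(v)) else v
            else:
                if parent not in out:
                    raise ValueError(
                        f"intra-slice parent {parent!r} of {name!r} not resolved"
                    )
                x[j] = out[parent][0]
        cfg = chain.config_index(params)
        m_k = params.mu[cfg] + params.W[cfg] @ x
        s2_k = params.sigma2[cfg]
        mean = float(p_t @ m_k)
        var = float(p_t @ (s2_k + m_k**2) - mean**2)
        out[name] = (mean, max(var, 0.0))
    return out


def sample_model(
    model: FittedModel,
    n_years: int,
    seed: int,
    burn_in: int = 50,
    start_year: int = 0,
) -> tuple[EcosystemTable, dict[str, np.ndarray]]:
    """Ancestral sampling of the model; reproducible given ``seed``.

    A burn-in period (discarded) initializes lag-1 parents, so the reported
    years are draws from the (approximately stationary) process.  Returns
    the sampled table and the hidden state path of each chain.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    total = n_years + burn_in
    hidden_names = model.structure.hidden_names
    paths = {n: np.zeros(total, dtype=int) for n in hidden_names}
    for n in hidden_names:
        cp = model.chain_params[n]
        paths[n][0] = rng.choice(len(cp.pi), p=cp.pi)
        for t in range(1, total):
            paths[n][t] = rng.choice(cp.A.shape[1], p=cp.A[paths[n][t - 1]])
    order = model.structure.intra_topo_order()
    cols = {name: np.zeros(total) for name in model.structure.observed_names}
    for t in range(total):
        for name in order:
            p = model.node_params[name]
            x = np.zeros(len(p.cont_parents))
            for j, (parent, lag) in enumerate(p.cont_parents):
                if lag == 0:
                    x[j] = cols[parent][t]
                else:
                    x[j] = cols[parent][t - 1] if t > 0 else 0.0
            if p.disc_parents:
                states = tuple(int(paths[h][t]) for h in p.disc_parents)
                q = int(np.ravel_multi_index(states, p.cards))
            else:
                q = 0
            mean = p.mu[q] + float(p.W[q] @ x)
            cols[name][t] = mean + rng.normal(0.0, math.sqrt(p.sigma2[q]))
    import pandas as pd

    years = np.arange(start_year, start_year + n_years)
    df = pd.DataFrame(
        {name: cols[name][burn_in:] for name in model.structure.observed_names},
        index=pd.Index(years, name="year"),
    )
    descriptors = tuple(
        VariableDescriptor(name=n, category="population_estimate", predicted_flag=True)
        for n in model.structure.observed_names
    )
    table = EcosystemTable(data=df, descriptors=descriptors)
    return table, {n: paths[n][burn_in:] for n in hidden_names}
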