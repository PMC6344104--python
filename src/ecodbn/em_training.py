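"""Maximum-likelihood fitting of CLG DBN parameters by EM.

The observed-data log-likelihood L(θ) = log Σ_H P(X, H | θ) is maximized by
alternating exact forward-backward smoothing of the hidden chains (E-step)
with closed-form weighted least-squares updates of every node's CLG
parameters and the chains' initial/transition distributions (M-step).

The E-step optionally takes per-year weights — used by the bootstrap
protocol to give each year its resample multiplicity (zero for out-of-bag
years) in the emission sufficient statistics, while the chain itself stays
contiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dbn_core import (
    OBSERVED as OBSERVED_KIND,
    CLGNodeParams,
    FittedModel,
    HiddenChainParams,
    JointChain,
    NetworkStructure,
    VARIANCE_FLOOR,
    _lagged_value_matrix,
    forward_backward,
    joint_chain,
)
from .timeseries_io import EcosystemTable

#: pseudocount added to expected transition counts before normalization,
#: so a state that collects no responsibility keeps a proper A row
TRANSITION_PSEUDOCOUNT = 1e-3


@dataclass(frozen=True)
class EMConfig:
    """Knobs of the EM fit.

    rel_tolerance is on the relative change of L(θ) between iterations;
    n_inits random initializations are run and the best final likelihood
    wins.  variance_floor is in standardized units squared.
    """

    max_iterations: int = 200
    rel_tolerance: float = 1e-6
    n_inits: int = 5
    seed: int = 0
    variance_floor: float = VARIANCE_FLOOR

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rel_tolerance <= 0:
            raise ValueError("rel_tolerance must be positive")
        if self.n_inits < 1:
            raise ValueError("n_inits must be >= 1")


@dataclass(frozen=True)
class EMTrace:
    """Per-iteration observed-data log-likelihoods of the winning run."""

    loglik: tuple[float, ...]
    converged: bool
    init_index: int

    def __post_init__(self) -> None:
        lls = np.asarray(self.loglik)
        if len(lls) > 1 and np.any(np.diff(lls) < -1e-8 * np.maximum(1.0, np.abs(lls[:-1]))):
            raise ValueError("EM log-likelihood decreased beyond slack")


@dataclass
class ESuffStats:
    """Expected sufficient statistics from one E-step.

    Per observed node and discrete-parent configuration i, with z = [1, x]:
    Szz[i] = Σ_t r w z zᵀ, Szy[i] = Σ_t r w z y, Syy[i] = Σ_t r w y²,
    Sr[i] = Σ_t r w, where r is the smoothed probability of configuration i
    and w the year weight.  Chains get expected transition counts and the
    initial-state marginal.
    """

    node_stats: dict[str, dict[str, np.ndarray]]
    chain_trans: dict[str, np.ndarray]
    chain_init: dict[str, np.ndarray]
    loglik: float


def e_step(
    model: FittedModel,
    data: EcosystemTable,
    row_weights: np.ndarray | None = None,
) -> ESuffStats:
    """Exact smoothing and accumulation of weighted sufficient statistics.

    With ``row_weights`` the objective is the weighted likelihood (each
    year's emission raised to its weight); the reported loglik is that
    weighted objective, so the EM monotonicity guarantee applies to it.
    """
    gamma, xi, loglik, chain = forward_backward(model, data, row_weights)
    T = data.n_years
    if row_weights is None:
        w = np.ones(T)
    else:
        w = np.asarray(row_weights, dtype=float)
        if w.shape != (T,):
            raise ValueError("row_weights length mismatch")
    values = data.values
    col_of = {c: i for i, c in enumerate(data.columns)}

    node_stats: dict[str, dict[str, np.ndarray]] = {}
    for name in model.structure.observed_names:
        p = model.node_params[name]
        n_cfg = p.n_configs
        d = len(p.cont_parents) + 1
        Szz = np.zeros((n_cfg, d, d))
        Szy = np.zeros((n_cfg, d))
        Syy = np.zeros(n_cfg)
        Sr = np.zeros(n_cfg)
        y = values[:, col_of[name]]
        X = _lagged_value_matrix(values, col_of, p.cont_parents)
        valid = (~np.isnan(y)) & (w > 0)
        if p.cont_parents:
            valid &= ~np.isnan(X).any(axis=1)
        if valid.any():
            cfg = chain.config_index(p)
            tt = np.flatnonzero(valid)
            Z = np.concatenate([np.ones((len(tt), 1)), np.nan_to_num(X[tt])], axis=1)
            yv = y[tt]
            for i in range(n_cfg):
                # responsibility of configuration i at each valid year
                r = gamma[np.ix_(tt, np.flatnonzero(cfg == i))].sum(axis=1) * w[tt]
                Szz[i] = (Z * r[:, None]).T @ Z
                Szy[i] = (Z * r[:, None]).T @ yv
                Syy[i] = float(r @ yv**2)
                Sr[i] = float(r.sum())
        node_stats[name] = {"Szz": Szz, "Szy": Szy, "Syy": Syy, "Sr": Sr}

    chain_trans: dict[str, np.ndarray] = {}
    chain_init: dict[str, np.ndarray] = {}
    for i, name in enumerate(chain.names):
        card = chain.cards[i]
        counts = np.zeros((card, card))
        for a in range(card):
            for b in range(card):
                mask = (chain.states[:, i][:, None] == a) & (
                    chain.states[:, i][None, :] == b
                )
                counts[a, b] = xi[:, mask].sum()
        chain_trans[name] = counts
        chain_init[name] = chain.marginalize(gamma[0], name)
    return ESuffStats(
        node_stats=node_stats,
        chain_trans=chain_trans,
        chain_init=chain_init,
        loglik=loglik,
    )


def m_step(
    stats: ESuffStats,
    structure: NetworkStructure,
    config: EMConfig,
    prev: FittedModel | None = None,
) -> FittedModel:
    """Closed-form maximization given expected sufficient statistics.

    Per configuration, (mu, W) solve the responsibility-weighted normal
    equations; the variance is the weighted residual variance, floored.  A
    configuration with (numerically) no responsibility keeps its previous
    parameters when available.  Singular normal equations get a 1e-8 ridge.
    """
    node_params: dict[str, CLGNodeParams] = {}
    for name in structure.observed_names:
        s = stats.node_stats[name]
        cont = structure.cont_parents(name)
        disc = structure.disc_parents(name)
        cards = tuple(structure.node(h).cardinality for h in disc)
        n_cfg = int(np.prod(cards)) if cards else 1
        d = len(cont) + 1
        mu = np.zeros(n_cfg)
        W = np.zeros((n_cfg, len(cont)))
        s2 = np.ones(n_cfg)
        for i in range(n_cfg):
            if s["Sr"][i] < 1e-10:
                if prev is not None:
                    pp = prev.node_params[name]
                    mu[i], W[i], s2[i] = pp.mu[i], pp.W[i], pp.sigma2[i]
                continue
            Szz = s["Szz"][i]
            try:
                beta = np.linalg.solve(Szz, s["Szy"][i])
            except np.linalg.LinAlgError:
                beta = np.linalg.solve(Szz + 1e-8 * np.eye(d), s["Szy"][i])
            if not np.all(np.isfinite(beta)):
                beta = np.linalg.solve(Szz + 1e-8 * np.eye(d), s["Szy"][i])
            mu[i] = beta[0]
            W[i] = beta[1:]
            resid = s["Syy"][i] - 2 * beta @ s["Szy"][i] + beta @ Szz @ beta
            s2[i] = max(resid / s["Sr"][i], config.variance_floor)
        node_params[name] = CLGNodeParams(
            node=name, cont_parents=cont, disc_parents=disc, cards=cards,
            mu=mu, W=W, sigma2=s2,
        )
    chain_params: dict[str, HiddenChainParams] = {}
    for name in structure.hidden_names:
        counts = stats.chain_trans[name].copy()
        # empty-state guard only: the pseudocount would otherwise bias the
        # maximizer and break EM's monotone-likelihood guarantee
        empty = counts.sum(axis=1) < 1e-10
        counts[empty] += TRANSITION_PSEUDOCOUNT
        A = counts / counts.sum(axis=1, keepdims=True)
        init = stats.chain_init[name].copy()
        if init.sum() < 1e-10:
            init += TRANSITION_PSEUDOCOUNT
        pi = init / init.sum()
        chain_params[name] = HiddenChainParams(pi=pi, A=A)
    return FittedModel(
        structure=structure, node_params=node_params, chain_params=chain_params
    )


def _random_initial_model(
    structure: NetworkStructure, data: EcosystemTable, config: EMConfig, rng
) -> FittedModel:
    """Initialize from a random *persistent* state path per hidden chain.

    Regime chains flip rarely, so temporally uncorrelated random
    responsibilities let every state see essentially the whole series and
    EM starts in a basin where states differ only in variance.  Sampling a
    sticky random path (persistence 0.9) and softening it to 0.85/0.15
    responsibilities gives block-structured starts from which regime means
    can separate.  Parameters follow by one weighted least-squares pass.
    """
    T = data.n_years
    chain_params = {}
    for name in structure.hidden_names:
        card = structure.node(name).cardinality
        A = np.full((card, card), 0.2 / max(card - 1, 1))
        np.fill_diagonal(A, 0.8)
        pi = np.full(card, 1.0 / card)
        chain_params[name] = HiddenChainParams(pi=pi, A=A)
    # provisional parameters: responsibilities → weighted OLS per config
    values = data.values
    col_of = {c: i for i, c in enumerate(data.columns)}
    resp = {}
    kind = {n.name: n.kind for n in structure.nodes}
    for name in structure.hidden_names:
        card = structure.node(name).cardinality
        children = [
            v for h, v in structure.intra_edges if h == name and kind[v] == OBSERVED_KIND
        ]
        child_cols = [col_of[c] for c in children if c in col_of]
        level = (
            np.nanmean(values[:, child_cols], axis=1) if child_cols else None
        )
        if level is not None and np.isfinite(level).sum() >= card and rng.random() < 0.7:
            # level split: regimes are level shifts of their children, so
            # thresholding the children's mean series at a random quantile
            # anchors the states to data blocks
            cut = np.nanquantile(level, rng.uniform(0.3, 0.7))
            path = (level > cut).astype(int)
            path = np.where(np.isfinite(level), path, rng.integers(card, size=T))
        else:
            # sticky random path: block structure without data guidance
            path = np.zeros(T, dtype=int)
            path[0] = rng.integers(card)
            for t in range(1, T):
                if rng.random() < 0.9:
                    path[t] = path[t - 1]
                else:
                    others = [s for s in range(card) if s != path[t - 1]]
                    path[t] = others[rng.integers(len(others))]
        r = np.full((T, card), 0.15 / max(card - 1, 1))
        r[np.arange(T), path.astype(int)] = 0.85
        resp[name] = r
    node_params = {}
    for name in structure.observed_names:
        cont = structure.cont_parents(name)
        disc = structure.disc_parents(name)
        cards = tuple(structure.node(h).cardinality for h in disc)
        n_cfg = int(np.prod(cards)) if cards else 1
        y = values[:, col_of[name]]
        X = _lagged_value_matrix(values, col_of, cont)
        valid = ~np.isnan(y)
        if cont:
            valid &= ~np.isnan(X).any(axis=1)
        tt = np.flatnonzero(valid)
        d = len(cont) + 1
        mu = np.zeros(n_cfg)
        W = np.zeros((n_cfg, len(cont)))
        s2 = np.ones(n_cfg)
        if len(tt) > 0:
            Z = np.concatenate([np.ones((len(tt), 1)), np.nan_to_num(X[tt])], axis=1)
            yv = y[tt]
            for i in range(n_cfg):
                if cards:
                    states = np.unravel_index(i, cards)
                    r = np.ones(len(tt))
                    for h, s in zip(disc, states):
                        r = r * resp[h][tt, s]
                else:
                    r = np.ones(len(tt))
                Szz = (Z * r[:, None]).T @ Z + 1e-6 * np.eye(d)
                beta = np.linalg.solve(Szz, (Z * r[:, None]).T @ yv)
                mu[i] = beta[0]
                W[i] = beta[1:]
                resid = r @ (yv - Z @ beta) ** 2
                s2[i] = max(resid / max(r.sum(), 1e-6), config.variance_floor)
        node_params[name] = CLGNodeParams(
            node=name, cont_parents=cont, disc_parents=disc, cards=cards,
            mu=mu, W=W, sigma2=s2,
        )
    return FittedModel(
        structure=structure, node_params=node_params, chain_params=chain_params
    )


def _em_run(
    model: FittedModel,
    data: EcosystemTable,
    config: EMConfig,
    row_weights: np.ndarray | None,
) -> tuple[FittedModel, list[float], bool]:
    lls: list[float] = []
    converged = False
    for _ in range(config.max_iterations):
        stats = e_step(model, data, row_weights=row_weights)
        lls.append(stats.loglik)
        model = m_step(stats, model.structure, config, prev=model)
        if len(lls) >= 2:
            prev_ll, cur_ll = lls[-2], lls[-1]
            denom = max(abs(prev_ll), 1.0)
            if (cur_ll - prev_ll) / denom < config.rel_tolerance:
                converged = True
                break
    return model, lls, converged


def fit_em(
    structure: NetworkStructure,
    data: EcosystemTable,
    config: EMConfig | None = None,
    init_model: FittedModel | None = None,
    row_weights: np.ndarray | None = None,
) -> tuple[FittedModel, EMTrace]:
    """Fit all parameters of a structure by EM.

    Runs ``config.n_inits`` random initializations (or a single run warm-
    started from ``init_model``) and returns the model with the highest
    final observed-data log-likelihood, together with its trace.
    """
    if data.n_years < 3:
        raise ValueError("need at least 3 years of data")
    config = config or EMConfig()
    runs: list[tuple[FittedModel, list[float], bool, int]] = []
    if init_model is not None:
        model, lls, conv = _em_run(init_model, data, config, row_weights)
        runs.append((model, lls, conv, -1))
    else:
        ss = np.random.SeedSequence(config.seed)
        children = ss.spawn(config.n_inits)
        n_inits = config.n_inits if structure.hidden_names else 1
        for idx in range(n_inits):
            rng = np.random.default_rng(children[idx])
            m0 = _random_initial_model(structure, data, config, rng)
            model, lls, conv = _em_run(m0, data, config, row_weights)
            runs.append((model, lls, conv, idx))
    best = max(runs, key=lambda r: r[1][-1] if r[1] else -np.inf)
    model, lls, conv, idx = best
    return model, EMTrace(loglik=tuple(lls), converged=conv, init_index=idx)
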