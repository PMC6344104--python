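"""Ground-truth synthetic ecosystem tables.

Emulates the shape of the study system: a few climate driver series whose
level is modulated by a persistent two-state hidden regime (an AMO-like
index plus regional SST series), physiochemical drivers with simple
autoregressive persistence, and a larger set of biological series tied to
lagged drivers through a planted sparse DAG (at most three parents each)
with additive Gaussian noise.  The planted structure, weights and hidden
path are returned, so recovery of edges, parameters and regimes can be
checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dbn_core import (
    HIDDEN,
    OBSERVED,
    CLGNodeParams,
    FittedModel,
    HiddenChainParams,
    NetworkStructure,
    NodeSpec,
    sample_model,
)
from .timeseries_io import (
    EcosystemTable,
    StandardizationParams,
    VariableDescriptor,
    standardize,
)

#: name of the planted climate regime chain
REGIME = "HV climate"


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and strength parameters of the generator.

    Defaults mirror the study table: 32 annual observations of 28
    components (4 climate, 6 physiochemical, 18 biological).  The hidden
    regime flips rarely (diagonal persistence 0.9 ≈ one shift per decade)
    and moves the climate means by ``regime_shift`` units, the planted
    lag-1 weights are drawn from ±[0.4, 0.8) (strong enough to matter, weak
    enough to keep the system stable), and every series carries unit-scale
    observation noise of sd 0.5.
    """

    n_years: int = 32
    n_climate: int = 4
    n_physio: int = 6
    n_biota: int = 18
    hidden_persistence: float = 0.9
    regime_shift: float = 1.0
    weight_range: tuple[float, float] = (0.4, 0.8)
    noise_sd: float = 0.5
    max_parents: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 10:
            raise ValueError("n_years must be >= 10")
        if min(self.n_climate, self.n_physio, self.n_biota) < 1:
            raise ValueError("all variable counts must be >= 1")
        if not 0.5 < self.hidden_persistence < 1.0:
            raise ValueError("hidden_persistence must be in (0.5, 1)")
        if not 1 <= self.max_parents <= 3:
            raise ValueError("max_parents must be in 1..3")
        lo, hi = self.weight_range
        if not 0 < lo <= hi:
            raise ValueError("weight_range must be a positive interval")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    # -- variable naming --------------------------------------------------
    @property
    def climate_names(self) -> list[str]:
        # first climate series is the AMO-like basin index; the rest are
        # regional SST series (press-perturbation targets)
        names = ["AMO"]
        names += [f"SST {i}" for i in range(1, self.n_climate)]
        return names[: self.n_climate]

    @property
    def physio_names(self) -> list[str]:
        return [f"physio {i}" for i in range(1, self.n_physio + 1)]

    @property
    def biota_names(self) -> list[str]:
        return [f"biota {i}" for i in range(1, self.n_biota + 1)]

    def descriptors(self) -> tuple[VariableDescriptor, ...]:
        out = []
        for i, n in enumerate(self.climate_names):
            out.append(
                VariableDescriptor(
                    name=n, category="climate", sst_region_flag=(i > 0)
                )
            )
        for n in self.physio_names:
            out.append(VariableDescriptor(name=n, category="physiochemical"))
        for n in self.biota_names:
            out.append(
                VariableDescriptor(
                    name=n, category="population_estimate", predicted_flag=True
                )
            )
        return tuple(out)


def generate_structure(spec: SyntheticSpec) -> tuple[NetworkStructure, FittedModel]:
    """Plant a structure and its true parameters; reproducible by seed.

    The hidden regime drives every climate series (intra-slice); climate
    and physiochemical series keep autoregressive self-links; each
    biological series gets 1..max_parents lag-1 parents drawn from the
    drivers and earlier biological series (never the converse, so climate
    drives biology).  Weights are sampled uniformly in ±weight_range.
    """
    rng = np.random.default_rng(spec.seed)
    climate, physio, biota = spec.climate_names, spec.physio_names, spec.biota_names

    nodes = [NodeSpec(name=REGIME, kind=HIDDEN, cardinality=2)]
    nodes += [NodeSpec(name=n) for n in climate + physio + biota]
    intra = [(REGIME, c) for c in climate]
    inter = [(REGIME, REGIME)]
    inter += [(n, n) for n in climate + physio]

    parent_pool = list(climate + physio)
    planted: dict[str, list[str]] = {}
    for b in biota:
        k = int(rng.integers(1, spec.max_parents + 1))
        pool = parent_pool + [x for x in biota if x in planted]  # earlier biota only
        k = min(k, len(pool))
        choice = rng.choice(len(pool), size=k, replace=False)
        ps = sorted(pool[i] for i in choice)
        planted[b] = ps
        inter += [(p, b) for p in ps]

    structure = NetworkStructure(
        nodes=tuple(nodes), intra_edges=tuple(intra), inter_edges=tuple(inter)
    )

    def draw_weight() -> float:
        lo, hi = spec.weight_range
        return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))

    node_params: dict[str, CLGNodeParams] = {}
    for name in structure.observed_names:
        cont = structure.cont_parents(name)
        disc = structure.disc_parents(name)
        cards = tuple(structure.node(h).cardinality for h in disc)
        n_cfg = int(np.prod(cards)) if cards else 1
        if name in climate:
            # regime moves the level; modest persistence keeps it stable
            half = spec.regime_shift / 2.0
            mu = np.array([-half, half])
            W = np.full((2, len(cont)), 0.4)
            s2 = np.full(2, spec.noise_sd**2)
        elif name in physio:
            mu = np.zeros(1)
            W = np.full((1, len(cont)), 0.5)
            s2 = np.array([spec.noise_sd**2])
        else:
            mu = np.zeros(n_cfg)
            W = np.array([[draw_weight() for _ in cont]])
            s2 = np.array([spec.noise_sd**2])
        node_params[name] = CLGNodeParams(
            node=name, cont_parents=cont, disc_parents=disc, cards=cards,
            mu=mu, W=W, sigma2=s2,
        )
    p = spec.hidden_persistence
    chain_params = {
        REGIME: HiddenChainParams(
            pi=np.array([0.5, 0.5]), A=np.array([[p, 1 - p], [1 - p, p]])
        )
    }
    model = FittedModel(
        structure=structure, node_params=node_params, chain_params=chain_params
    )
    return structure, model


def simulate_table(
    model: FittedModel,
    spec: SyntheticSpec,
    seed: int | None = None,
) -> tuple[EcosystemTable, StandardizationParams, dict[str, np.ndarray]]:
    """Sample a table from the planted model and standardize it.

    Returns the standardized table (with proper category descriptors), the
    standardization params (original-scale moments of the sampled series),
    and the true hidden path.
    """
    raw, hidden = sample_model(
        model, spec.n_years, seed if seed is not None else spec.seed, start_year=1984
    )
    df = raw.data[[d.name for d in spec.descriptors()]]
    table = EcosystemTable(data=df, descriptors=spec.descriptors())
    std_table, params = standardize(table)
    return std_table, params, hidden


def planted_edges(model: FittedModel) -> set[tuple[str, str]]:
    """Directed lag-1 observed→observed edges of the planted structure,
    excluding autoregressive self-links."""
    obs = set(model.structure.observed_names)
    return {
        (u, v)
        for u, v in model.structure.inter_edges
        if u in obs and v in obs and u != v
    }
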