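"""Shared fixtures: small hand-set models and synthetic tables."""

import numpy as np
import pandas as pd
import pytest

from ecodbn.dbn_core import (
    HIDDEN,
    CLGNodeParams,
    FittedModel,
    HiddenChainParams,
    NetworkStructure,
    NodeSpec,
)
from ecodbn.timeseries_io import EcosystemTable, VariableDescriptor


def make_table(frame: pd.DataFrame, predicted=True) -> EcosystemTable:
    desc = tuple(
        VariableDescriptor(c, "population_estimate", predicted_flag=predicted)
        for c in frame.columns
    )
    return EcosystemTable(frame, desc)


@pytest.fixture
def toy_model() -> FittedModel:
    """1 binary hidden chain, 2 observed nodes with AR links and a cross link."""
    nodes = (NodeSpec("H", HIDDEN, 2), NodeSpec("a"), NodeSpec("b"))
    s = NetworkStructure(
        nodes=nodes,
        intra_edges=(("H", "a"), ("H", "b")),
        inter_edges=(("H", "H"), ("a", "a"), ("a", "b")),
    )
    node_params = {
        "a": CLGNodeParams(
            "a", (("a", 1),), ("H",), (2,),
            mu=[-1.0, 1.0], W=[[0.5], [0.3]], sigma2=[0.5, 0.8],
        ),
        "b": CLGNodeParams(
            "b", (("a", 1),), ("H",), (2,),
            mu=[0.2, -0.4], W=[[0.9], [-0.2]], sigma2=[1.0, 0.3],
        ),
    }
    chain = {"H": HiddenChainParams(pi=[0.6, 0.4], A=[[0.8, 0.2], [0.3, 0.7]])}
    return FittedModel(s, node_params, chain)


@pytest.fixture
def toy_data() -> EcosystemTable:
    rng = np.random.default_rng(0)
    T = 5
    df = pd.DataFrame(
        {"a": rng.normal(size=T), "b": rng.normal(size=T)},
        index=pd.Index(range(T), name="year"),
    )
    df.iloc[2, 1] = np.nan  # one missing entry exercises marginalization
    return make_table(df)


def enumerate_paths(model: FittedModel, data: EcosystemTable):
    """Brute-force hidden-path enumeration oracle (single binary chain)."""
    import itertools

    from ecodbn.dbn_core import joint_loglik_complete

    (name,) = model.structure.hidden_names
    T = data.n_years
    paths = list(itertools.product([0, 1], repeat=T))
    lls = np.array([joint_loglik_complete(model, data, {name: p}) for p in paths])
    total = np.logaddexp.reduce(lls)
    w = np.exp(lls - total)
    arr = np.array(paths)
    post = np.array([[w[arr[:, t] == k].sum() for k in (0, 1)] for t in range(T)])
    return total, post
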