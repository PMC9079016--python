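"""Shared fixtures: random-network factories for oracle comparisons."""

from __future__ import annotations

import numpy as np
import pytest

from nadopt.bn import CPT, BeliefNetwork, NetworkStructure, Variable


def random_network(rng: np.random.Generator, n_nodes: int = 5,
                   max_states: int = 4, edge_prob: float = 0.4) -> BeliefNetwork:
    """A random DAG over v0..v{n-1} (edges only forward) with Dirichlet CPTs."""
    names = [f"v{i}" for i in range(n_nodes)]
    variables = [
        Variable(n, tuple(f"s{k}" for k in range(rng.integers(2, max_states + 1))))
        for n in names
    ]
    edges = [(names[i], names[j]) for i in range(n_nodes) for j in range(i + 1, n_nodes)
             if rng.random() < edge_prob]
    structure = NetworkStructure(variables, edges)
    cpts = {}
    for v in variables:
        parents = [structure[p] for p in structure.parents(v.name)]
        n_rows = int(np.prod([p.n_states for p in parents])) if parents else 1
        raw = rng.gamma(1.0, size=(n_rows, v.n_states)) + 1e-3
        cpts[v.name] = CPT(v, parents, raw / raw.sum(axis=1, keepdims=True))
    return BeliefNetwork(structure, cpts)


def random_evidence(rng: np.random.Generator, net: BeliefNetwork,
                    max_vars: int = 2, allow_subset: bool = True) -> dict:
    names = list(net.structure.names)
    k = int(rng.integers(0, min(max_vars, len(names) - 1) + 1))
    chosen = rng.choice(len(names), size=k, replace=False)
    evidence = {}
    for i in chosen:
        var = net.structure[names[i]]
        if allow_subset and var.n_states > 2 and rng.random() < 0.3:
            m = int(rng.integers(2, var.n_states))
            idx = rng.choice(var.n_states, size=m, replace=False)
            evidence[var.name] = tuple(var.states[j] for j in sorted(idx))
        else:
            evidence[var.name] = var.states[int(rng.integers(var.n_states))]
    return evidence


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_node_income_net() -> BeliefNetwork:
    """farm_size -> income with P(income=high|large)=0.6, |small)=0.3."""
    size = Variable("farm_size", ("small", "large"))
    income = Variable("income", ("low", "high"))
    structure = NetworkStructure([size, income], [("farm_size", "income")])
    cpts = {
        "farm_size": CPT(size, (), [[0.5, 0.5]]),
        "income": CPT(income, (size,), [[0.7, 0.3], [0.4, 0.6]]),
    }
    return BeliefNetwork(structure, cpts)
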