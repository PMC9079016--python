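"""Discrete Bayesian belief networks: representation, exact inference, interventions.

A belief network is a directed acyclic graph over discrete variables together
with one conditional probability table (CPT) per variable; the joint
distribution is the product of the tables.  This module is the substrate for
everything else in the package: survey models are built as
:class:`BeliefNetwork` objects, EM learning re-estimates their CPTs, and
validation / sensitivity / policy analyses query them through
:func:`posterior_marginal` and :func:`do_intervention`.

Inference is exact (variable elimination over table factors).  Evidence may be
hard (one observed state) or a restriction to a subset of states, which is the
exact conditioning on the event "the variable is one of these states" — needed
e.g. to condition on "farm size is not large".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Variable",
    "NetworkStructure",
    "CPT",
    "BeliefNetwork",
    "Distribution",
    "NetworkError",
    "ImpossibleEvidenceError",
    "joint_probability",
    "posterior_marginal",
    "joint_marginal",
    "most_likely_state",
    "do_intervention",
]

ROLES = ("predictor", "intermediate", "target")

#: tolerance for "rows sum to one" checks
NORM_TOL = 1e-9


class NetworkError(ValueError):
    """Invalid network component (structure, CPT, evidence, assignment)."""


class ImpossibleEvidenceError(RuntimeError):
    """Evidence has probability zero under the network."""


@dataclass(frozen=True)
class Variable:
    """A discrete variable with an ordered set of mutually exclusive states.

    State order is meaningful: it defines CPT column order, the tie-break in
    :func:`most_likely_state`, and the low-to-high ordering used when labelling
    influence directions.
    """

    name: str
    states: tuple[str, ...]
    role: str = "predictor"

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if not self.name:
            raise NetworkError("variable name must be non-empty")
        if len(self.states) < 2:
            raise NetworkError(f"{self.name}: a variable needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise NetworkError(f"{self.name}: duplicate state labels")
        if self.role not in ROLES:
            raise NetworkError(f"{self.name}: unknown role {self.role!r}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise NetworkError(f"{self.name}: unknown state {state!r}") from None


class NetworkStructure:
    """Directed acyclic graph over a set of :class:`Variable`.

    Parent order is the order in which edges were declared; CPT rows follow it.
    Target-role variables must be sinks (no outgoing edges).
    """

    def __init__(self, variables: Iterable[Variable], edges: Iterable[tuple[str, str]]):
        self._vars: dict[str, Variable] = {}
        for v in variables:
            if v.name in self._vars:
                raise NetworkError(f"duplicate variable {v.name!r}")
            self._vars[v.name] = v
        self._edges: list[tuple[str, str]] = []
        seen = set()
        for p, c in edges:
            if p not in self._vars or c not in self._vars:
                raise NetworkError(f"edge ({p!r}, {c!r}) references undeclared variable")
            if (p, c) in seen:
                continue
            seen.add((p, c))
            self._edges.append((p, c))
        g = nx.DiGraph()
        g.add_nodes_from(self._vars)
        g.add_edges_from(self._edges)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise NetworkError(f"structure contains a cycle: {cyc}")
        self._graph = g
        for v in self._vars.values():
            if v.role == "target" and g.out_degree(v.name) > 0:
                raise NetworkError(f"target variable {v.name!r} has outgoing edges")

    @property
    def variables(self) -> dict[str, Variable]:
        return dict(self._vars)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._edges)

    @property
    def names(self) -> list[str]:
        return list(self._vars)

    def __contains__(self, name: str) -> bool:
        return name in self._vars

    def __getitem__(self, name: str) -> Variable:
        try:
            return self._vars[name]
        except KeyError:
            raise NetworkError(f"unknown variable {name!r}") from None

    def parents(self, name: str) -> tuple[str, ...]:
        self[name]
        return tuple(p for p, c in self._edges if c == name)

    def children(self, name: str) -> tuple[str, ...]:
        self[name]
        return tuple(c for p, c in self._edges if p == name)

    def topological_order(self) -> list[str]:
        # stable: break ties by declaration order
        order = list(nx.lexicographical_topological_sort(
            self._graph, key=lambda n: list(self._vars).index(n)))
        return order

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkStructure):
            return NotImplemented
        return self._vars == other._vars and set(self._edges) == set(other._edges)


def _parent_radices(parent_sizes: Sequence[int]) -> np.ndarray:
    """Mixed-radix weights: first parent most significant."""
    r = np.ones(len(parent_sizes), dtype=np.int64)
    for i in range(len(parent_sizes) - 2, -1, -1):
        r[i] = r[i + 1] * parent_sizes[i + 1]
    return r


class CPT:
    """Conditional probability table P(child | parents).

    ``table`` has one row per parent-state combination (mixed radix over the
    ordered parents, first parent most significant) and one column per child
    state; every row sums to one.
    """

    def __init__(self, child: Variable, parents: Sequence[Variable], table: np.ndarray):
        self.child = child
        self.parents = tuple(parents)
        table = np.asarray(table, dtype=float)
        n_rows = int(np.prod([p.n_states for p in self.parents])) if self.parents else 1
        if table.ndim == 1:
            table = table.reshape(1, -1)
        if table.shape != (n_rows, child.n_states):
            raise NetworkError(
                f"{child.name}: CPT shape {table.shape} != ({n_rows}, {child.n_states})")
        if np.any(table < -NORM_TOL) or np.any(table > 1 + NORM_TOL):
            raise NetworkError(f"{child.name}: CPT entries outside [0, 1]")
        if np.any(np.abs(table.sum(axis=1) - 1.0) > NORM_TOL):
            raise NetworkError(f"{child.name}: CPT rows do not sum to 1")
        self.table = np.clip(table, 0.0, 1.0)
        self._radices = _parent_radices([p.n_states for p in self.parents])

    @property
    def parent_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parents)

    def row_index(self, parent_states: Mapping[str, str]) -> int:
        idx = 0
        for p, r in zip(self.parents, self._radices):
            idx += p.state_index(parent_states[p.name]) * int(r)
        return idx

    def prob(self, child_state: str, parent_states: Mapping[str, str]) -> float:
        return float(self.table[self.row_index(parent_states),
                                self.child.state_index(child_state)])

    def parent_combination(self, row: int) -> dict[str, str]:
        """Inverse of :meth:`row_index`."""
        out = {}
        for p, r in zip(self.parents, self._radices):
            out[p.name] = p.states[(row // int(r)) % p.n_states]
        return out

    @classmethod
    def uniform(cls, child: Variable, parents: Sequence[Variable] = ()) -> "CPT":
        n_rows = int(np.prod([p.n_states for p in parents])) if parents else 1
        return cls(child, parents, np.full((n_rows, child.n_states), 1.0 / child.n_states))


@dataclass
class Distribution:
    """A probability distribution over one variable's states."""

    variable: Variable
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (self.variable.n_states,):
            raise NetworkError(
                f"{self.variable.name}: distribution length {p.shape} != {self.variable.n_states}")
        if np.any(p < -NORM_TOL):
            raise NetworkError(f"{self.variable.name}: negative probability")
        if abs(p.sum() - 1.0) > NORM_TOL:
            raise NetworkError(f"{self.variable.name}: probabilities sum to {p.sum()}")
        self.probabilities = np.clip(p, 0.0, None)

    def __getitem__(self, state: str) -> float:
        return float(self.probabilities[self.variable.state_index(state)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.variable.states, self.probabilities)}


class BeliefNetwork:
    """A :class:`NetworkStructure` plus one CPT per variable."""

    def __init__(self, structure: NetworkStructure, cpts: Mapping[str, CPT] | Iterable[CPT]):
        if not isinstance(cpts, Mapping):
            cpts = {c.child.name: c for c in cpts}
        self.structure = structure
        self.cpts: dict[str, CPT] = {}
        for name in structure.names:
            if name not in cpts:
                raise NetworkError(f"missing CPT for {name!r}")
            cpt = cpts[name]
            if cpt.child != structure[name]:
                raise NetworkError(f"CPT child mismatch for {name!r}")
            if cpt.parent_names != structure.parents(name):
                raise NetworkError(
                    f"{name!r}: CPT parents {cpt.parent_names} != structural "
                    f"parents {structure.parents(name)}")
            self.cpts[name] = cpt
        extra = set(cpts) - set(structure.names)
        if extra:
            raise NetworkError(f"CPTs for undeclared variables: {sorted(extra)}")

    @property
    def variables(self) -> dict[str, Variable]:
        return self.structure.variables

    def copy_with(self, structure: NetworkStructure | None = None,
                  cpts: Mapping[str, CPT] | None = None) -> "BeliefNetwork":
        new_struct = structure if structure is not None else self.structure
        new_cpts = dict(self.cpts)
        if cpts:
            new_cpts.update(cpts)
        new_cpts = {n: c for n, c in new_cpts.items() if n in new_struct}
        return BeliefNetwork(new_struct, new_cpts)


# ---------------------------------------------------------------------------
# evidence handling
# ---------------------------------------------------------------------------

Evidence = Mapping[str, "str | tuple[str, ...]"]


def _evidence_mask(var: Variable, value: str | Sequence[str]) -> np.ndarray:
    """0/1 indicator over the variable's states for hard or subset evidence."""
    if isinstance(value, str):
        value = (value,)
    mask = np.zeros(var.n_states)
    for s in value:
        mask[var.state_index(s)] = 1.0
    return mask


def validate_evidence(net: BeliefNetwork, evidence: Evidence) -> None:
    for name, value in evidence.items():
        var = net.structure[name]
        states = (value,) if isinstance(value, str) else tuple(value)
        if not states:
            raise NetworkError(f"{name}: empty evidence state set")
        for s in states:
            var.state_index(s)


# ---------------------------------------------------------------------------
# factors and variable elimination
# ---------------------------------------------------------------------------

class _Factor:
    """A nonnegative table over a tuple of variables (one ndarray axis each)."""

    __slots__ = ("names", "values")

    def __init__(self, names: tuple[str, ...], values: np.ndarray):
        self.names = names
        self.values = values

    def multiply(self, other: "_Factor") -> "_Factor":
        names = self.names + tuple(n for n in other.names if n not in self.names)
        a = self._expand(names)
        b = other._expand(names)
        return _Factor(names, a * b)

    def _expand(self, names: tuple[str, ...]) -> np.ndarray:
        # permute own axes into their relative order within `names`,
        # inserting size-1 axes for variables this factor lacks
        perm = [self.names.index(n) for n in names if n in self.names]
        arr = np.transpose(self.values, perm)
        own_sizes = iter(arr.shape)
        shape = [next(own_sizes) if n in self.names else 1 for n in names]
        return arr.reshape(shape)

    def sum_out(self, name: str) -> "_Factor":
        ax = self.names.index(name)
        return _Factor(self.names[:ax] + self.names[ax + 1:], self.values.sum(axis=ax))


def _cpt_factor(net: BeliefNetwork, name: str) -> _Factor:
    cpt = net.cpts[name]
    names = cpt.parent_names + (name,)
    shape = [p.n_states for p in cpt.parents] + [cpt.child.n_states]
    return _Factor(tuple(names), cpt.table.reshape(shape))


def _eliminate(factors: list[_Factor], hidden: set[str],
               sizes: Mapping[str, int]) -> _Factor:
    """Greedy min-size variable elimination; returns product over kept vars."""
    factors = list(factors)
    hidden = set(hidden)
    while hidden:
        best, best_cost = None, None
        for h in hidden:
            scope: set[str] = set()
            for f in factors:
                if h in f.names:
                    scope |= set(f.names)
            scope.discard(h)
            cost = float(np.prod([sizes[s] for s in scope])) if scope else 1.0
            if best_cost is None or cost < best_cost or (cost == best_cost and h < best):
                best, best_cost = h, cost
        touched = [f for f in factors if best in f.names]
        rest = [f for f in factors if best not in f.names]
        prod = touched[0]
        for f in touched[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.sum_out(best)]
        hidden.discard(best)
    prod = factors[0]
    for f in factors[1:]:
        prod = prod.multiply(f)
    return prod


def _query_factor(net: BeliefNetwork, evidence: Evidence,
                  queries: Sequence[str]) -> _Factor:
    validate_evidence(net, evidence)
    for q in queries:
        net.structure[q]
    sizes = {n: v.n_states for n, v in net.variables.items()}
    factors = [_cpt_factor(net, n) for n in net.structure.names]
    for name, value in evidence.items():
        factors.append(_Factor((name,), _evidence_mask(net.structure[name], value)))
    hidden = set(net.structure.names) - set(queries)
    joint = _eliminate(factors, hidden, sizes)
    # order the axes as requested
    order = [joint.names.index(q) for q in queries]
    values = np.transpose(joint.values, order)
    z = values.sum()
    if z <= 0.0:
        raise ImpossibleEvidenceError(f"evidence {dict(evidence)!r} has probability zero")
    return _Factor(tuple(queries), values / z)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def joint_probability(net: BeliefNetwork, assignment: Mapping[str, str]) -> float:
    """Probability of a full assignment: the product of the CPT entries it selects."""
    missing = set(net.structure.names) - set(assignment)
    if missing:
        raise NetworkError(f"assignment misses variables: {sorted(missing)}")
    extra = set(assignment) - set(net.structure.names)
    if extra:
        raise NetworkError(f"assignment names unknown variables: {sorted(extra)}")
    p = 1.0
    for name, cpt in net.cpts.items():
        p *= cpt.prob(assignment[name], assignment)
    return p


def posterior_marginal(net: BeliefNetwork, evidence: Evidence,
                       query: str) -> Distribution:
    """P(query | evidence), computed exactly by variable elimination.

    Raises :class:`ImpossibleEvidenceError` if the evidence has zero
    probability under the network.
    """
    if query in evidence:
        # conditioning on the queried variable itself: posterior is the
        # renormalized evidence mask weighted by the marginal
        f = _query_factor(net, {k: v for k, v in evidence.items() if k != query}, [query])
        mask = _evidence_mask(net.structure[query], evidence[query])
        vals = f.values * mask
        z = vals.sum()
        if z <= 0.0:
            raise ImpossibleEvidenceError(f"evidence {dict(evidence)!r} has probability zero")
        return Distribution(net.structure[query], vals / z)
    f = _query_factor(net, evidence, [query])
    return Distribution(net.structure[query], f.values)


def joint_marginal(net: BeliefNetwork, evidence: Evidence,
                   queries: Sequence[str]) -> np.ndarray:
    """Exact joint P(queries | evidence) as an array with one axis per query."""
    if len(set(queries)) != len(queries):
        raise NetworkError("duplicate query variables")
    return _query_factor(net, evidence, queries).values


def most_likely_state(d: Distribution) -> str:
    """Argmax state; ties go to the earliest state in the declared order."""
    return d.variable.states[int(np.argmax(d.probabilities))]


def do_intervention(net: BeliefNetwork, variable: str,
                    forced_marginal: Distribution | Sequence[float]) -> BeliefNetwork:
    """Graph surgery: sever all edges into ``variable`` and fix its marginal.

    This is the do-operator of causal inference on a discrete network: the
    intervened variable no longer listens to its parents, and its distribution
    is set to ``forced_marginal``.  Intervening on a target-role variable is
    rejected (the analyses only ever manipulate policy levers).
    """
    var = net.structure[variable]
    if var.role == "target":
        raise NetworkError(f"cannot intervene on target variable {variable!r}")
    if not isinstance(forced_marginal, Distribution):
        forced_marginal = Distribution(var, np.asarray(forced_marginal, dtype=float))
    if forced_marginal.variable != var:
        raise NetworkError(f"forced marginal is not over {variable!r}")
    new_edges = [(p, c) for p, c in net.structure.edges if c != variable]
    new_struct = NetworkStructure(net.structure.variables.values(), new_edges)
    new_cpt = CPT(var, (), forced_marginal.probabilities.reshape(1, -1))
    return net.copy_with(structure=new_struct, cpts={variable: new_cpt})


def enumerate_assignments(net: BeliefNetwork) -> Iterable[dict[str, str]]:
    """All full assignments of the network's variables (small nets only)."""
    names = net.structure.names
    state_lists = [net.structure[n].states for n in names]
    for combo in itertools.product(*state_lists):
        yield dict(zip(names, combo))
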