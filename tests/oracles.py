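"""Independent brute-force oracles for exact-inference checks.

Deliberately naive: plain python loops over full assignments and dictionary
CPT lookups, sharing no code with the package's variable-elimination engine.
Usable only on small networks.
"""

from __future__ import annotations

import itertools
import math


def _states(net, name):
    return net.structure[name].states


def brute_joint(net, assignment: dict[str, str]) -> float:
    """Product of CPT entries, coded as an explicit loop."""
    p = 1.0
    for name in net.structure.names:
        cpt = net.cpts[name]
        row = 0
        weight = 1
        for parent in reversed(cpt.parent_names):
            pvar = net.structure[parent]
            row += pvar.states.index(assignment[parent]) * weight
            weight *= pvar.n_states
        col = net.structure[name].states.index(assignment[name])
        p *= float(cpt.table[row][col])
    return p


def _consistent(assignment: dict[str, str], evidence: dict) -> bool:
    for name, value in evidence.items():
        allowed = (value,) if isinstance(value, str) else tuple(value)
        if assignment[name] not in allowed:
            return False
    return True


def brute_posterior(net, evidence: dict, query: str) -> list[float]:
    """P(query | evidence) by summing the joint over all assignments."""
    names = net.structure.names
    totals = [0.0] * len(_states(net, query))
    for combo in itertools.product(*[_states(net, n) for n in names]):
        assignment = dict(zip(names, combo))
        if not _consistent(assignment, evidence):
            continue
        totals[_states(net, query).index(assignment[query])] += brute_joint(net, assignment)
    z = sum(totals)
    if z <= 0.0:
        raise ZeroDivisionError("evidence has probability zero")
    return [t / z for t in totals]


def brute_mutual_information(net, a: str, b: str) -> float:
    """MI(a; b) in bits from the exhaustively enumerated joint table."""
    names = net.structure.names
    joint: dict[tuple[str, str], float] = {}
    for combo in itertools.product(*[_states(net, n) for n in names]):
        assignment = dict(zip(names, combo))
        key = (assignment[a], assignment[b])
        joint[key] = joint.get(key, 0.0) + brute_joint(net, assignment)
    pa: dict[str, float] = {}
    pb: dict[str, float] = {}
    for (sa, sb), p in joint.items():
        pa[sa] = pa.get(sa, 0.0) + p
        pb[sb] = pb.get(sb, 0.0) + p
    mi = 0.0
    for (sa, sb), p in joint.items():
        if p > 0.0:
            mi += p * math.log2(p / (pa[sa] * pb[sb]))
    return mi
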