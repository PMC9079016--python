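"""Mutual-information sensitivity of adoption to each predictor.

Mutual information between the target T and a predictor X,

    MI(T; X) = sum_t sum_x P(t, x) * log2( P(t, x) / (P(t) P(x)) ),

is computed on the *fitted network's* joint distribution (exact inference,
not the empirical contingency table), in bits.  Zero-probability cells
contribute zero.  Querying a variable against itself returns its entropy.

Influence direction compares the adoption probability at the predictor's
highest versus lowest declared state ('+', '-', or '0' for an exact tie); for
three-state predictors the middle state is ignored.  Across practices the
labels aggregate to '+', '-', or '+/-' when the per-practice signs disagree
(ties count as consistent with either sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bn import BeliefNetwork, NetworkError, joint_marginal
from .survey_network import PREDICTORS

__all__ = [
    "mutual_information",
    "entropy",
    "influence_direction",
    "SensitivityTable",
    "sensitivity_ranking",
]


def entropy(net: BeliefNetwork, variable: str) -> float:
    """Shannon entropy of a variable's marginal, in bits."""
    p = joint_marginal(net, {}, [variable])
    nz = p[p > 0.0]
    return float(-(nz * np.log2(nz)).sum())


def mutual_information(net: BeliefNetwork, target: str, predictor: str) -> float:
    """MI(target; predictor) in bits under the network's joint distribution."""
    if target == predictor:
        return entropy(net, target)
    joint = joint_marginal(net, {}, [target, predictor])
    pt = joint.sum(axis=1, keepdims=True)
    px = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0.0, joint / (pt * px), 1.0)
        terms = np.where(joint > 0.0, joint * np.log2(ratio), 0.0)
    return float(max(terms.sum(), 0.0))


def influence_direction(net: BeliefNetwork, target: str, predictor: str,
                        adopt_state: str = "yes") -> str:
    """'+', '-' or '0': sign of P(adopt | X=highest) - P(adopt | X=lowest).

    Relies on the predictor's declared state order being low -> high (true of
    every survey predictor; for crop type the comparison is perennial minus
    annual).
    """
    var = net.structure[predictor]
    tvar = net.structure[target]
    ti = tvar.state_index(adopt_state)
    low, high = var.states[0], var.states[-1]
    p_high = joint_marginal(net, {predictor: high}, [target])[ti]
    p_low = joint_marginal(net, {predictor: low}, [target])[ti]
    diff = float(p_high - p_low)
    if diff > 0.0:
        return "+"
    if diff < 0.0:
        return "-"
    return "0"


@dataclass
class SensitivityTable:
    """Per-practice MI matrix plus cross-practice means and direction labels.

    ``matrix``: DataFrame practices x predictors (bits); ``mean``: Series
    indexed by predictor, sorted descending; ``directions``: predictor ->
    '+', '-', '0' or '+/-'.
    """

    matrix: pd.DataFrame
    mean: pd.Series
    directions: dict[str, str]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_mi_bits": self.mean,
            "direction": pd.Series(self.directions).reindex(self.mean.index),
        }).rename_axis("predictor")


def _aggregate_signs(signs: list[str]) -> str:
    has_plus = "+" in signs
    has_minus = "-" in signs
    if has_plus and has_minus:
        return "+/-"
    if has_plus:
        return "+"
    if has_minus:
        return "-"
    return "0"


def sensitivity_ranking(nets: dict[str, BeliefNetwork],
                        predictors: tuple[str, ...] = PREDICTORS) -> SensitivityTable:
    """MI of each practice's target to each predictor, with means and signs.

    ``nets`` maps practice name -> fitted network whose target is that
    practice (practices already screened for negative PIV upstream).
    """
    if not nets:
        raise NetworkError("no practices supplied")
    rows = {}
    signs: dict[str, list[str]] = {p: [] for p in predictors}
    for practice, net in nets.items():
        rows[practice] = {p: mutual_information(net, practice, p) for p in predictors}
        for p in predictors:
            signs[p].append(influence_direction(net, practice, p))
    matrix = pd.DataFrame.from_dict(rows, orient="index")[list(predictors)]
    mean = matrix.mean(axis=0).sort_values(ascending=False, kind="stable")
    directions = {p: _aggregate_signs(s) for p, s in signs.items()}
    return SensitivityTable(matrix, mean, directions)
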