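"""Engagement-policy experiments: full and normalized interventions by farm type.

A *full* intervention forces every farmer into the engaged state of one
engagement variable (self-certification 'yes', information sources
'above_median', consultant 'yes').  A *normalized* intervention raises the
engaged share by a fixed absolute increment (default 0.10, i.e. 10% of
farmers switch from unengaged to engaged), which makes channels with very
different baseline engagement comparable.

Interventions are implemented as do-operations by default: the engagement
variable's incoming edges are severed and its marginal fixed — the policy
changes behaviour, not beliefs about farm size.  For a root engagement
variable this coincides with evidence-setting; an ``semantics="evidence"``
option is provided for comparison (belief updating instead of surgery).

Heterogeneity across farm types conditions on the three farm-characteristic
variables.  Types use 3-letter codes: size (L = large, S = small/medium
pooled), crop type (P = perennial, A = annual), irrigation (P = pressurized,
N = non-pressurized).  The pooled "S" size is entered as the exact
restriction "farm size is small or medium" (a renormalized two-state event),
the one place non-degenerate evidence on a 3-state node is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import (BeliefNetwork, Distribution, NetworkError, do_intervention,
                 joint_marginal)
from .survey_network import ENGAGED_STATE, ENGAGEMENT_VARIABLES

__all__ = [
    "FarmType",
    "FOCAL_FARM_TYPES",
    "InterventionSpec",
    "InterventionResult",
    "engaged_marginal",
    "apply_policy",
    "heterogeneity_analysis",
    "heterogeneity_summary",
]


@dataclass(frozen=True)
class FarmType:
    """A 3-letter farm-type code, e.g. LPP = large, perennial, pressurized."""

    code: str

    def __post_init__(self) -> None:
        c = self.code.upper()
        if len(c) != 3 or c[0] not in "LS" or c[1] not in "PA" or c[2] not in "PN":
            raise NetworkError(
                f"bad farm-type code {self.code!r}: expected [LS][PA][PN]")
        object.__setattr__(self, "code", c)

    @property
    def size(self) -> str:
        return self.code[0]

    @property
    def crop(self) -> str:
        return self.code[1]

    @property
    def irrigation(self) -> str:
        return self.code[2]

    def evidence(self) -> dict[str, str | tuple[str, ...]]:
        return {
            "farm_size": "large" if self.size == "L" else ("small", "medium"),
            "crop_type": "perennial" if self.crop == "P" else "annual",
            "irrigation_system": ("pressurized" if self.irrigation == "P"
                                  else "non_pressurized"),
        }


#: The four focal groups of the heterogeneity analysis.
FOCAL_FARM_TYPES: tuple[str, ...] = ("LPP", "LAN", "SPP", "SAN")


@dataclass(frozen=True)
class InterventionSpec:
    """One policy experiment: which lever, which mode, optional farm type."""

    variable: str
    mode: str  # full | normalized
    delta: float = 0.10
    farm_type: FarmType | None = None

    def __post_init__(self) -> None:
        if self.variable not in ENGAGEMENT_VARIABLES:
            raise NetworkError(
                f"{self.variable!r} is not an engagement variable "
                f"{ENGAGEMENT_VARIABLES}")
        if self.mode not in ("full", "normalized"):
            raise NetworkError(f"mode must be 'full' or 'normalized', got {self.mode!r}")
        if not 0.0 < self.delta <= 1.0:
            raise NetworkError("delta must be in (0, 1]")


@dataclass
class InterventionResult:
    """Adoption-probability change caused by one intervention, in percentage points."""

    practice: str
    variable: str
    mode: str
    farm_type: str  # 3-letter code or "all"
    baseline: float
    post: float

    @property
    def delta_pp(self) -> float:
        return (self.post - self.baseline) * 100.0


def engaged_marginal(net: BeliefNetwork, variable: str,
                     evidence: Mapping | None = None) -> float:
    """P(variable is in its engaged state | evidence)."""
    engaged = ENGAGED_STATE.get(variable, net.structure[variable].states[-1])
    idx = net.structure[variable].state_index(engaged)
    return float(joint_marginal(net, dict(evidence or {}), [variable])[idx])


def _forced_engaged_marginal(net: BeliefNetwork, spec: InterventionSpec,
                             evidence: Mapping) -> Distribution:
    var = net.structure[spec.variable]
    engaged = ENGAGED_STATE.get(spec.variable, var.states[-1])
    idx = var.state_index(engaged)
    if spec.mode == "full":
        p_new = 1.0
    else:
        current = engaged_marginal(net, spec.variable, evidence)
        p_new = current + spec.delta
        if p_new > 1.0:
            warnings.warn(
                f"{spec.variable}: engaged share {current:.3f} + {spec.delta} "
                "exceeds 1; capped", stacklevel=3)
            p_new = 1.0
    # residual mass keeps the current relative mix of unengaged states
    current_dist = joint_marginal(net, dict(evidence), [spec.variable]).copy()
    current_dist[idx] = 0.0
    rest = current_dist.sum()
    probs = np.zeros(var.n_states)
    probs[idx] = p_new
    if rest > 0.0:
        probs += (1.0 - p_new) * current_dist / rest
    else:
        probs[idx] = 1.0
    return Distribution(var, probs)


def apply_policy(net: BeliefNetwork, spec: InterventionSpec, target: str,
                 adopt_state: str = "yes", semantics: str = "do") -> InterventionResult:
    """Measure the adoption change for one practice under one intervention.

    With farm-type conditioning, the same farm-characteristic evidence is
    entered before and after the intervention, and the normalized increment
    applies to the *conditional* engaged share of that farm type.
    """
    if semantics not in ("do", "evidence"):
        raise NetworkError("semantics must be 'do' or 'evidence'")
    tvar = net.structure[target]
    if tvar.role != "target":
        raise NetworkError(f"{target!r} is not a target variable")
    ti = tvar.state_index(adopt_state)
    evidence = dict(spec.farm_type.evidence()) if spec.farm_type else {}
    baseline = float(joint_marginal(net, evidence, [target])[ti])

    forced = _forced_engaged_marginal(net, spec, evidence)
    if semantics == "do":
        mutilated = do_intervention(net, spec.variable, forced)
        post = float(joint_marginal(mutilated, evidence, [target])[ti])
    else:
        # belief updating: mix the conditionals given each engagement state
        var = net.structure[spec.variable]
        post = 0.0
        for si, state in enumerate(var.states):
            weight = float(forced.probabilities[si])
            if weight == 0.0:
                continue
            ev = dict(evidence)
            ev[spec.variable] = state
            post += weight * float(joint_marginal(net, ev, [target])[ti])
    return InterventionResult(
        practice=target, variable=spec.variable, mode=spec.mode,
        farm_type=spec.farm_type.code if spec.farm_type else "all",
        baseline=baseline, post=post)


def heterogeneity_analysis(nets: Mapping[str, BeliefNetwork],
                           farm_types: Sequence[str] = FOCAL_FARM_TYPES,
                           variables: Sequence[str] = ENGAGEMENT_VARIABLES,
                           modes: Sequence[str] = ("full", "normalized"),
                           delta: float = 0.10,
                           semantics: str = "do") -> list[InterventionResult]:
    """Full cross-product practices x engagement channels x modes x farm types."""
    if not nets:
        raise NetworkError("no practices supplied")
    results = []
    for practice, net in nets.items():
        for code in farm_types:
            ft = FarmType(code)
            for variable in variables:
                for mode in modes:
                    spec = InterventionSpec(variable, mode, delta, ft)
                    results.append(apply_policy(net, spec, practice,
                                                semantics=semantics))
    return results


def results_frame(results: Sequence[InterventionResult]) -> pd.DataFrame:
    """Tidy table: one row per practice x channel x mode x farm type."""
    return pd.DataFrame([
        {
            "practice": r.practice,
            "engagement_variable": r.variable,
            "mode": r.mode,
            "farm_type": r.farm_type,
            "baseline_adoption": r.baseline,
            "post_adoption": r.post,
            "delta_pp": r.delta_pp,
        }
        for r in results
    ])


def heterogeneity_summary(results: Sequence[InterventionResult]) -> pd.DataFrame:
    """Mean delta (pp) per farm type and mode, averaged over practices and channels."""
    frame = results_frame(results)
    return (frame.groupby(["farm_type", "mode"], sort=True)["delta_pp"]
            .mean().unstack("mode"))
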