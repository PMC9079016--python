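"""The survey-specific model: variables, discretization, and layered structure.

The analysis models a farmer survey with nine predictor variables in three
blocks — farm characteristics (farm size, irrigation system, crop type),
farmer characteristics (income, education, years in farming) and engagement
(self-certification, number of information sources, consultant) — and one
binary adoption target per nitrogen best-management practice.

The network is layered: each predictor feeds exactly one of three latent
*intermediate* nodes (one per block), and only the intermediates point at the
target.  The intermediates have no data column; they exist to keep the
target's CPT small (three 3-state parents give 27 rows, against 3456 rows for
nine direct parents), and their CPTs are learned by EM.  Cross-edges between
predictors (by default, farm size influencing income and the three engagement
variables) are declared explicitly and are fully configurable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bn import NetworkError, NetworkStructure, Variable

__all__ = [
    "PRACTICES",
    "PREDICTORS",
    "INTERMEDIATES",
    "ENGAGEMENT_VARIABLES",
    "ENGAGED_STATE",
    "predictor_variables",
    "DiscretizationSpec",
    "DEFAULT_DISCRETIZATION",
    "discretize_survey",
    "LayeredStructureSpec",
    "default_structure_spec",
    "build_structure",
    "retarget",
    "load_structure_spec",
    "save_structure_spec",
]

#: The eleven nitrogen best-management practices (binary adoption targets).
PRACTICES: tuple[str, ...] = (
    "soil_testing",
    "leaf_testing",
    "well_n_testing",
    "moisture_probe",
    "pressure_bomb",
    "et_scheduling",
    "split_application",
    "fertigation",
    "foliar_application",
    "variable_rate_gps",
    "cover_crops",
)

#: Predictor states, ordered low -> high where an ordering exists.
_PREDICTOR_STATES: dict[str, tuple[str, ...]] = {
    "farm_size": ("small", "medium", "large"),
    "irrigation_system": ("non_pressurized", "pressurized"),
    "crop_type": ("annual", "perennial"),
    "income": ("low", "medium", "high"),
    "education": ("no", "yes"),
    "years_in_farming": ("below_median", "above_median"),
    "self_certification": ("no", "yes"),
    "info_sources": ("below_median", "above_median"),
    "consultant": ("no", "yes"),
}

PREDICTORS: tuple[str, ...] = tuple(_PREDICTOR_STATES)

#: Block membership: predictor -> intermediate node.
_DEFAULT_GROUPING: dict[str, str] = {
    "farm_size": "farm_characteristics",
    "irrigation_system": "farm_characteristics",
    "crop_type": "farm_characteristics",
    "income": "farmer_characteristics",
    "education": "farmer_characteristics",
    "years_in_farming": "farmer_characteristics",
    "self_certification": "engagement",
    "info_sources": "engagement",
    "consultant": "engagement",
}

INTERMEDIATES: tuple[str, ...] = (
    "farm_characteristics", "farmer_characteristics", "engagement")

#: The three policy levers and the state counted as "engaged".
ENGAGEMENT_VARIABLES: tuple[str, ...] = (
    "self_certification", "info_sources", "consultant")
ENGAGED_STATE: dict[str, str] = {
    "self_certification": "yes",
    "info_sources": "above_median",
    "consultant": "yes",
}

#: Default cross-edges between predictors: farm size drives income and the
#: engagement variables (large operations are more often self-certified,
#: use more information sources, and differ in consultant use).
_DEFAULT_CROSS_EDGES: tuple[tuple[str, str], ...] = (
    ("farm_size", "income"),
    ("farm_size", "self_certification"),
    ("farm_size", "info_sources"),
    ("farm_size", "consultant"),
)

TARGET_STATES: tuple[str, str] = ("no", "yes")


def predictor_variables() -> dict[str, Variable]:
    return {n: Variable(n, s, "predictor") for n, s in _PREDICTOR_STATES.items()}


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscretizationSpec:
    """How one raw survey column maps to a discrete variable.

    kinds:
      ``binary``       yes/no style answers (accepts yes/no, true/false, 1/0)
      ``threshold2``   two strictly increasing cut points -> 3 states; the
                       middle state is closed on both sides (value == cut
                       falls in the middle state)
      ``median_split`` one cut point -> 2 states; values <= cut fall in the
                       lower state
    """

    variable: str
    raw_column: str
    kind: str  # binary | threshold2 | median_split
    cuts: tuple[float, ...] = ()
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "threshold2", "median_split"):
            raise NetworkError(f"{self.variable}: unknown discretization kind {self.kind!r}")
        if self.kind == "threshold2" and (len(self.cuts) != 2 or self.cuts[0] >= self.cuts[1]):
            raise NetworkError(f"{self.variable}: threshold2 needs 2 increasing cut points")
        if self.kind == "median_split" and len(self.cuts) != 1:
            raise NetworkError(f"{self.variable}: median_split needs 1 cut point")


#: Cut points: farm size 50/200 acres, income 50k/500k $, years in farming
#: median 36, information sources median 4.
DEFAULT_DISCRETIZATION: tuple[DiscretizationSpec, ...] = (
    DiscretizationSpec("farm_size", "farm_size_acres", "threshold2", (50.0, 200.0), "acres"),
    DiscretizationSpec("irrigation_system", "pressurized_irrigation", "binary"),
    DiscretizationSpec("crop_type", "perennial_crops", "binary"),
    DiscretizationSpec("income", "income_usd", "threshold2", (50_000.0, 500_000.0), "USD"),
    DiscretizationSpec("education", "college_degree", "binary"),
    DiscretizationSpec("years_in_farming", "years_in_farming", "median_split", (36.0,), "years"),
    DiscretizationSpec("self_certification", "self_certified", "binary"),
    DiscretizationSpec("info_sources", "n_info_sources", "median_split", (4.0,), "count"),
    DiscretizationSpec("consultant", "hires_consultant", "binary"),
)

_BINARY_TRUE = {"yes", "y", "true", "1", "1.0"}
_BINARY_FALSE = {"no", "n", "false", "0", "0.0"}


def _binary_state(variable: str, raw) -> str:
    states = _PREDICTOR_STATES.get(variable, TARGET_STATES)
    text = str(raw).strip().lower()
    if text in _BINARY_TRUE:
        return states[1]
    if text in _BINARY_FALSE:
        return states[0]
    if text in states:
        return text
    raise ValueError(f"unmappable binary value {raw!r}")


def discretize_survey(raw: pd.DataFrame,
                      specs: Sequence[DiscretizationSpec] = DEFAULT_DISCRETIZATION,
                      ) -> pd.DataFrame:
    """Map raw survey columns to discrete state labels.

    Missing cells stay missing (NaN); unmappable values (e.g. negative
    acreage) are collected and reported in one :class:`NetworkError` listing
    every offending (row, column) cell.  Columns not named by any spec (such
    as the binary practice columns) are passed through ``_binary_state`` when
    they look binary, otherwise copied unchanged.
    """
    out = pd.DataFrame(index=raw.index)
    problems: list[str] = []
    spec_cols = set()
    for spec in specs:
        if spec.raw_column not in raw.columns:
            continue
        spec_cols.add(spec.raw_column)
        col = raw[spec.raw_column]
        states = _PREDICTOR_STATES.get(spec.variable, TARGET_STATES)
        mapped = []
        for idx, value in col.items():
            if pd.isna(value) or (isinstance(value, str) and not value.strip()):
                mapped.append(np.nan)
                continue
            try:
                if spec.kind == "binary":
                    mapped.append(_binary_state(spec.variable, value))
                    continue
                x = float(value)
                if x < 0:
                    raise ValueError(f"negative value {value!r}")
                if spec.kind == "median_split":
                    mapped.append(states[0] if x <= spec.cuts[0] else states[1])
                else:  # threshold2: middle category closed on both sides
                    if x < spec.cuts[0]:
                        mapped.append(states[0])
                    elif x <= spec.cuts[1]:
                        mapped.append(states[1])
                    else:
                        mapped.append(states[2])
            except (TypeError, ValueError) as exc:
                problems.append(f"row {idx}, column {spec.raw_column!r}: {exc}")
                mapped.append(np.nan)
        out[spec.variable] = mapped
    if problems:
        raise NetworkError("unmappable survey values:\n  " + "\n  ".join(problems))
    for col in raw.columns:
        if col in spec_cols:
            continue
        values = []
        for idx, value in raw[col].items():
            if pd.isna(value) or (isinstance(value, str) and not value.strip()):
                values.append(np.nan)
            else:
                try:
                    values.append(_binary_state(col, value))
                except ValueError:
                    values.append(value)
        out[col] = values
    return out


# ---------------------------------------------------------------------------
# layered structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayeredStructureSpec:
    """Declarative description of the layered network for one target practice."""

    target: str
    grouping: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_GROUPING))
    n_latent_states: int = 3
    cross_edges: tuple[tuple[str, str], ...] = _DEFAULT_CROSS_EDGES

    def __post_init__(self) -> None:
        if set(self.grouping) != set(PREDICTORS):
            raise NetworkError("grouping must map exactly the nine predictors")
        if set(self.grouping.values()) - set(INTERMEDIATES):
            raise NetworkError(f"intermediate nodes must be among {INTERMEDIATES}")
        if not 2 <= self.n_latent_states <= 5:
            raise NetworkError("n_latent_states must be in 2..5")
        for p, c in self.cross_edges:
            if p not in PREDICTORS or c not in PREDICTORS:
                raise NetworkError(f"cross-edge ({p!r}, {c!r}) must join predictors")


def default_structure_spec(target: str = "cover_crops") -> LayeredStructureSpec:
    return LayeredStructureSpec(target=target)


_LATENT_STATES = ("low", "medium", "high", "very_high", "top")


def build_structure(spec: LayeredStructureSpec) -> NetworkStructure:
    """9 predictor roots -> 3 latent intermediates -> 1 binary target.

    Raises on cross-edges that would create a cycle (via the acyclicity check
    of :class:`NetworkStructure`).
    """
    variables = list(predictor_variables().values())
    latent_states = _LATENT_STATES[: spec.n_latent_states]
    variables += [Variable(m, latent_states, "intermediate") for m in INTERMEDIATES]
    variables.append(Variable(spec.target, TARGET_STATES, "target"))
    edges: list[tuple[str, str]] = list(spec.cross_edges)
    edges += [(p, spec.grouping[p]) for p in PREDICTORS]
    edges += [(m, spec.target) for m in INTERMEDIATES]
    return NetworkStructure(variables, edges)


def retarget(spec: LayeredStructureSpec, new_target: str) -> LayeredStructureSpec:
    """Same structure, different practice as target."""
    return LayeredStructureSpec(target=new_target, grouping=dict(spec.grouping),
                                n_latent_states=spec.n_latent_states,
                                cross_edges=spec.cross_edges)


# ---------------------------------------------------------------------------
# structure files
# ---------------------------------------------------------------------------

def save_structure_spec(spec: LayeredStructureSpec, path: str | Path) -> None:
    doc = {
        "target": spec.target,
        "n_latent_states": spec.n_latent_states,
        "grouping": dict(spec.grouping),
        "cross_edges": [list(e) for e in spec.cross_edges],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_structure_spec(path: str | Path) -> LayeredStructureSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return LayeredStructureSpec(
        target=doc["target"],
        grouping=doc.get("grouping", dict(_DEFAULT_GROUPING)),
        n_latent_states=doc.get("n_latent_states", 3),
        cross_edges=tuple(tuple(e) for e in doc.get("cross_edges", [])),
    )


def packaged_default_structure_path() -> Path:
    """Path of the structure file shipped with the package."""
    return Path(importlib.resources.files("nadopt") / "data" / "default_structure.yaml")
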