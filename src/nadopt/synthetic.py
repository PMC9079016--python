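"""Synthetic survey generator calibrated to the study's printed margins.

The real 2018 Central Valley survey (967 responses) is not public, so every
stage of the pipeline is exercised on surveys drawn from a fully specified
ground-truth network over the nine predictors and the practice targets (no
latent nodes — the intermediates are a modelling device of the *fitted*
network, not a data-generating claim).

The default ground truth embodies the margins the study prints:

* the eight farm-type counts (size x crop x irrigation; 914 tabulated farms),
  reproduced exactly by the farm-characteristics chain;
* engagement rates by farm size: self-certification 79% (large) vs 47%
  (small/medium), information sources above median 54% vs 36%, consultant
  38% vs 42%;
* the income example: P(income = high) is 60% given a large farm, 30% given
  a small one.

Practice adoption tables are configurable; the defaults are additive and
monotone in income and engagement, with adoption rates spread over roughly
0.05-0.45.  Missingness can be applied completely at random (MCAR) or at
random conditional on farm size (MAR; farm size itself stays observed).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import CPT, BeliefNetwork, NetworkError, NetworkStructure, Variable
from .survey_network import (ENGAGED_STATE, PRACTICES, PREDICTORS, TARGET_STATES,
                             predictor_variables)

__all__ = [
    "FARM_TYPE_COUNTS",
    "PracticeParams",
    "DEFAULT_PRACTICE_PARAMS",
    "default_ground_truth",
    "GeneratorConfig",
    "generate_survey",
    "survey_to_csv",
    "Fixture",
    "SCENARIOS",
    "end_to_end_fixture",
]

#: Tabulated farm counts per 3-letter type (size, crop, irrigation); 914 total.
FARM_TYPE_COUNTS: dict[str, int] = {
    "LPP": 161, "LPN": 5, "LAP": 32, "LAN": 46,
    "SPP": 406, "SPN": 89, "SAP": 76, "SAN": 99,
}

#: Engagement rates conditional on farm size (large vs small/medium pooled).
ENGAGEMENT_BY_SIZE: dict[str, tuple[float, float]] = {
    "self_certification": (0.79, 0.47),
    "info_sources": (0.54, 0.36),
    "consultant": (0.38, 0.42),
}

#: Share of the pooled small/medium mass assigned to "small" (the table pools
#: them; the split itself never affects any printed margin because all CPT
#: rows for small and medium are identical).
_SMALL_SHARE_OF_POOL = 0.6


@dataclass(frozen=True)
class PracticeParams:
    """Additive adoption model for one practice.

    P(adopt | income i, engagement e) = clip(base + income_step * i + gain * e)
    with i in {0, 1, 2} (low/medium/high) and e in {0, 1}.
    """

    engagement_variable: str
    base: float
    income_step: float
    engagement_gain: float

    def prob(self, income_level: int, engaged: int) -> float:
        p = self.base + self.income_step * income_level + self.engagement_gain * engaged
        return float(np.clip(p, 0.02, 0.95))


#: Defaults shape three groups of practices: five with strong, prediction-
#: relevant dependence (testing/application practices whose adoption crosses
#: 0.5 for engaged, higher-income farms), three with moderate dependence, and
#: three niche low-adoption practices whose signal is too weak to beat the
#: base rate — the spread of adoption rates runs from about 0.06 to 0.45.
DEFAULT_PRACTICE_PARAMS: dict[str, PracticeParams] = {
    "soil_testing": PracticeParams("self_certification", 0.05, 0.12, 0.45),
    "leaf_testing": PracticeParams("consultant", 0.05, 0.15, 0.45),
    "well_n_testing": PracticeParams("info_sources", 0.08, 0.10, 0.28),
    "moisture_probe": PracticeParams("info_sources", 0.04, 0.06, 0.60),
    "pressure_bomb": PracticeParams("consultant", 0.02, 0.04, 0.06),
    "et_scheduling": PracticeParams("info_sources", 0.10, 0.09, 0.25),
    "split_application": PracticeParams("self_certification", 0.22, 0.10, 0.15),
    "fertigation": PracticeParams("self_certification", 0.03, 0.12, 0.50),
    "foliar_application": PracticeParams("info_sources", 0.06, 0.08, 0.55),
    "variable_rate_gps": PracticeParams("consultant", 0.02, 0.02, 0.04),
    "cover_crops": PracticeParams("self_certification", 0.05, 0.02, 0.03),
}


def _farm_characteristics_cpts(variables: Mapping[str, Variable]) -> dict[str, CPT]:
    counts = FARM_TYPE_COUNTS
    total = sum(counts.values())
    n_large = sum(v for k, v in counts.items() if k[0] == "L")
    n_pool = total - n_large
    p_large = n_large / total
    p_small = _SMALL_SHARE_OF_POOL * n_pool / total
    p_medium = (1 - _SMALL_SHARE_OF_POOL) * n_pool / total
    farm_size = CPT(variables["farm_size"], (), [[p_small, p_medium, p_large]])

    per_large = (counts["LPP"] + counts["LPN"]) / n_large
    per_pool = (counts["SPP"] + counts["SPN"]) / n_pool
    # rows: farm_size in (small, medium, large); states (annual, perennial)
    crop = CPT(variables["crop_type"], (variables["farm_size"],), [
        [1 - per_pool, per_pool],
        [1 - per_pool, per_pool],
        [1 - per_large, per_large],
    ])

    def press(size: str, crop_letter: str) -> float:
        p = counts[f"{size}{crop_letter}P"]
        n = counts[f"{size}{crop_letter}N"]
        return p / (p + n)

    # parents (farm_size, crop_type); rows small/annual, small/perennial, ...
    rows = []
    for size in ("S", "S", "L"):
        for crop_letter in ("A", "P"):
            q = press(size, crop_letter)
            rows.append([1 - q, q])
    irrigation = CPT(variables["irrigation_system"],
                     (variables["farm_size"], variables["crop_type"]), rows)
    return {"farm_size": farm_size, "crop_type": crop, "irrigation_system": irrigation}


def _engagement_cpts(variables: Mapping[str, Variable]) -> dict[str, CPT]:
    out = {}
    for name, (rate_large, rate_pool) in ENGAGEMENT_BY_SIZE.items():
        # rows: small, medium, large; engaged state is the last state
        rows = [[1 - rate_pool, rate_pool],
                [1 - rate_pool, rate_pool],
                [1 - rate_large, rate_large]]
        out[name] = CPT(variables[name], (variables["farm_size"],), rows)
    return out


def _farmer_cpts(variables: Mapping[str, Variable]) -> dict[str, CPT]:
    income = CPT(variables["income"], (variables["farm_size"],), [
        [0.35, 0.35, 0.30],   # small: P(high | small) = 0.30
        [0.25, 0.35, 0.40],
        [0.20, 0.20, 0.60],   # large: P(high | large) = 0.60
    ])
    education = CPT(variables["education"], (), [[0.45, 0.55]])
    years = CPT(variables["years_in_farming"], (), [[0.5, 0.5]])
    return {"income": income, "education": education, "years_in_farming": years}


def default_ground_truth(
        practices: Sequence[str] = PRACTICES,
        practice_params: Mapping[str, PracticeParams] | None = None,
) -> BeliefNetwork:
    """The calibrated data-generating network (no latent nodes).

    Structure: farm_size -> {crop_type, income, self_certification,
    info_sources, consultant}; (farm_size, crop_type) -> irrigation_system;
    each practice <- (income, its engagement variable).
    """
    params = dict(DEFAULT_PRACTICE_PARAMS)
    if practice_params:
        params.update(practice_params)
    variables = predictor_variables()
    edges: list[tuple[str, str]] = [
        ("farm_size", "crop_type"),
        ("farm_size", "irrigation_system"),
        ("crop_type", "irrigation_system"),
        ("farm_size", "income"),
        ("farm_size", "self_certification"),
        ("farm_size", "info_sources"),
        ("farm_size", "consultant"),
    ]
    cpts = {}
    cpts.update(_farm_characteristics_cpts(variables))
    cpts.update(_farmer_cpts(variables))
    cpts.update(_engagement_cpts(variables))
    all_vars = dict(variables)
    for practice in practices:
        if practice not in params:
            raise NetworkError(f"no adoption parameters for practice {practice!r}")
        pp = params[practice]
        tvar = Variable(practice, TARGET_STATES, "target")
        all_vars[practice] = tvar
        eng = variables[pp.engagement_variable]
        edges += [("income", practice), (pp.engagement_variable, practice)]
        rows = []
        for i in range(3):            # income low/medium/high
            for e in range(2):        # unengaged / engaged (state order)
                engaged = 1 if eng.states[e] == ENGAGED_STATE[eng.name] else 0
                p = pp.prob(i, engaged)
                rows.append([1 - p, p])
        cpts[practice] = CPT(tvar, (variables["income"], eng), rows)
    structure = NetworkStructure(all_vars.values(), edges)
    return BeliefNetwork(structure, cpts)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth + sample size + missingness; the seed is mandatory."""

    network: BeliefNetwork
    n: int
    seed: int
    missingness: Mapping[str, float] = field(default_factory=dict)
    mechanism: str = "MCAR"  # MCAR | MAR_farm_size

    def __post_init__(self) -> None:
        if self.n < 1:
            raise NetworkError("n must be >= 1")
        if self.mechanism not in ("MCAR", "MAR_farm_size"):
            raise NetworkError(f"unknown missingness mechanism {self.mechanism!r}")
        for col, p in self.missingness.items():
            if not 0.0 <= p < 1.0:
                raise NetworkError(f"{col}: missingness probability must be in [0, 1)")
            if col not in self.network.structure:
                raise NetworkError(f"{col}: not a network variable")
        if self.mechanism == "MAR_farm_size" and self.missingness.get("farm_size", 0.0) > 0:
            raise NetworkError("MAR_farm_size requires farm_size to stay observed")


#: Missingness multiplier by farm-size state under the MAR mechanism:
#: smaller operations answer fewer questions.
_MAR_MULTIPLIER = {"small": 1.5, "medium": 1.0, "large": 0.5}


def generate_survey(cfg: GeneratorConfig) -> pd.DataFrame:
    """Ancestral-sample ``cfg.n`` records, then apply missingness.

    Returns a DataFrame of state labels with NaN for missing cells; columns
    follow the network's declaration order (the survey schema).  Same config
    and seed give an identical table.
    """
    rng = np.random.default_rng(cfg.seed)
    net = cfg.network
    order = net.structure.topological_order()
    codes: dict[str, np.ndarray] = {}
    for name in order:
        cpt = net.cpts[name]
        if cpt.parents:
            radix = _parent_radices_arr(cpt)
            config = sum(codes[p.name] * int(r) for p, r in zip(cpt.parents, radix))
        else:
            config = np.zeros(cfg.n, dtype=np.int64)
        cum = np.cumsum(cpt.table, axis=1)
        u = rng.random(cfg.n)
        codes[name] = (cum[config] < u[:, None]).sum(axis=1).astype(np.int64)
    columns = net.structure.names
    frame = pd.DataFrame({
        name: pd.Series(np.asarray(net.structure[name].states, dtype=object)[codes[name]])
        for name in columns
    })
    for col, p in cfg.missingness.items():
        if p == 0.0:
            continue
        if cfg.mechanism == "MCAR":
            drop = rng.random(cfg.n) < p
        else:
            mult = np.array([_MAR_MULTIPLIER[s] for s in frame["farm_size"]])
            drop = rng.random(cfg.n) < np.clip(p * mult, 0.0, 0.99)
        frame.loc[drop, col] = np.nan
    return frame


def _parent_radices_arr(cpt: CPT) -> np.ndarray:
    sizes = [p.n_states for p in cpt.parents]
    radix = np.ones(len(sizes), dtype=np.int64)
    for i in range(len(sizes) - 2, -1, -1):
        radix[i] = radix[i + 1] * sizes[i + 1]
    return radix


def survey_to_csv(frame: pd.DataFrame) -> str:
    """Canonical CSV encoding (missing cells empty); bit-stable across runs."""
    buf = io.StringIO()
    frame.to_csv(buf, index=False, na_rep="", lineterminator="\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# end-to-end scenarios
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A packaged scenario: data + ground truth + checkable expectations."""

    scenario: str
    data: pd.DataFrame
    truth: BeliefNetwork
    practices: list[str]
    expectations: dict[str, object]


def _scenario_calibrated(seed: int, n: int) -> Fixture:
    truth = default_ground_truth()
    missing = {c: 0.05 for c in ("income", "education", "years_in_farming",
                                 "info_sources", "consultant")}
    data = generate_survey(GeneratorConfig(truth, n, seed, missing, "MAR_farm_size"))
    return Fixture("calibrated", data, truth, list(PRACTICES), {
        "selfcert_given_large": 0.79,
        "selfcert_given_small_or_medium": 0.47,
    })


def _scenario_independent(seed: int, n: int) -> Fixture:
    params = {"cover_crops": PracticeParams("self_certification", 0.05, 0.0, 0.0)}
    truth = default_ground_truth(practices=["cover_crops"], practice_params=params)
    data = generate_survey(GeneratorConfig(truth, n, seed))
    return Fixture("independent-target", data, truth, ["cover_crops"],
                   {"adoption_rate": 0.05, "max_mean_piv": 0.0})


def _scenario_strong(seed: int, n: int) -> Fixture:
    variables = predictor_variables()
    truth = default_ground_truth(practices=[])
    tvar = Variable("moisture_probe", TARGET_STATES, "target")
    # near-deterministic in a balanced predictor: adoption ~ 50%, PIV headroom ~0.44
    cpt = CPT(tvar, (variables["years_in_farming"],), [[0.94, 0.06], [0.06, 0.94]])
    all_vars = list(truth.structure.variables.values()) + [tvar]
    edges = truth.structure.edges + [("years_in_farming", "moisture_probe")]
    structure = NetworkStructure(all_vars, edges)
    net = BeliefNetwork(structure, {**truth.cpts, "moisture_probe": cpt})
    data = generate_survey(GeneratorConfig(net, n, seed))
    return Fixture("strong-predictor", data, net, ["moisture_probe"],
                   {"min_mean_piv": 0.10, "tier": "especially_reliable"})


def _scenario_pp_responsive(seed: int, n: int) -> Fixture:
    """Engagement lifts adoption far more on perennial + pressurized farms."""
    focal = {"soil_testing": "self_certification",
             "leaf_testing": "consultant",
             "foliar_application": "info_sources"}
    variables = predictor_variables()
    truth = default_ground_truth(practices=[])
    all_vars = dict(truth.structure.variables)
    edges = list(truth.structure.edges)
    cpts = dict(truth.cpts)
    for practice, eng_name in focal.items():
        tvar = Variable(practice, TARGET_STATES, "target")
        all_vars[practice] = tvar
        eng = variables[eng_name]
        parents = (variables["crop_type"], variables["irrigation_system"], eng)
        edges += [("crop_type", practice), ("irrigation_system", practice),
                  (eng_name, practice)]
        rows = []
        for c in range(2):        # annual, perennial
            for i in range(2):    # non_pressurized, pressurized
                for e in range(2):
                    engaged = 1 if eng.states[e] == ENGAGED_STATE[eng_name] else 0
                    gain = 0.32 if (c == 1 and i == 1) else 0.06
                    p = float(np.clip(0.15 + 0.05 * c + gain * engaged, 0.02, 0.95))
                    rows.append([1 - p, p])
        cpts[practice] = CPT(tvar, parents, rows)
    structure = NetworkStructure(all_vars.values(), edges)
    net = BeliefNetwork(structure, cpts)
    data = generate_survey(GeneratorConfig(net, n, seed))
    return Fixture("pp-responsive", data, net, list(focal), {
        "pp_delta_exceeds_an": True,
        "full_delta_small_exceeds_large": True,
    })


SCENARIOS = {
    "calibrated": (_scenario_calibrated, 967),
    "independent-target": (_scenario_independent, 967),
    "strong-predictor": (_scenario_strong, 2000),
    "pp-responsive": (_scenario_pp_responsive, 2000),
}


def end_to_end_fixture(scenario: str, seed: int, n: int | None = None) -> Fixture:
    """Build a named scenario; unknown names raise with the list of choices."""
    if scenario not in SCENARIOS:
        raise NetworkError(
            f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    builder, default_n = SCENARIOS[scenario]
    return builder(seed, n if n is not None else default_n)
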