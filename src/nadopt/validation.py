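"""Predictive validation: Error Rate, Prediction Improvement Value, tiers.

For each test record, every non-missing predictor value is entered as
evidence, the most likely state of the target is taken as the prediction, and
the Error Rate is the fraction of mispredicted records.  Because the Error
Rate of a trivial base-rate predictor equals min(p, 1-p) for a binary target
with adoption rate p, the Prediction Improvement Value

    PIV = min(AdoptionRate, 1 - AdoptionRate) - ErrorRate

measures how much the network improves on predicting from the adoption rate
alone.  Negative PIV: the model is *worse* than the base rate (not
meaningful); PIV in [0, 0.10]: reliable; PIV > 0.10: especially reliable.

Cross-validation repeats {random 70/30 split, EM fit on the training part,
Error Rate on the held-out part} and averages.  The adoption rate entering
the PIV is, by default, the practice's rate over the full dataset (the
formula's single global quantity); ``adoption_from="train"`` uses the
training split instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bn import BeliefNetwork, NetworkError, NetworkStructure, most_likely_state, posterior_marginal
from .em import EMConfig, em_fit

__all__ = [
    "SplitSpec",
    "SplitDetail",
    "ValidationReport",
    "error_rate",
    "piv",
    "reliability_tier",
    "cross_validate",
]

TIERS = ("not_meaningful", "reliable", "especially_reliable")


@dataclass(frozen=True)
class SplitSpec:
    """Repeated random train/test splitting (default 70% train, 5 repeats)."""

    train_fraction: float = 0.7
    repetitions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise NetworkError("train_fraction must be in (0, 1)")
        if self.repetitions < 1:
            raise NetworkError("repetitions must be >= 1")


@dataclass
class SplitDetail:
    repetition: int
    n_train: int
    n_test: int
    error_rate: float
    piv: float


@dataclass
class ValidationReport:
    practice: str
    adoption_rate: float
    mean_error_rate: float
    mean_piv: float
    tier: str
    splits: list[SplitDetail] = field(default_factory=list)


def error_rate(net: BeliefNetwork, test: pd.DataFrame, target: str) -> float:
    """Fraction of test records whose predicted target state is wrong.

    Records with a missing target value are excluded (with a warning); an
    effectively empty test set raises.  Predictions for identical evidence
    patterns are computed once and cached.
    """
    var = net.structure[target]
    if target not in test.columns:
        raise NetworkError(f"test data lacks target column {target!r}")
    if len(test) == 0:
        raise NetworkError("empty test set")

    evidence_cols = [c for c in test.columns if c != target and c in net.structure]

    def clean(value) -> str | None:
        if pd.isna(value):
            return None
        text = str(value).strip()
        return text if text and text.lower() != "nan" else None

    n_eval = 0
    n_err = 0
    n_missing_target = 0
    cache: dict[tuple, str] = {}
    cols = test[evidence_cols].to_numpy(dtype=object)
    targets = test[target].to_numpy(dtype=object)
    for i in range(len(test)):
        truth = clean(targets[i])
        if truth is None:
            n_missing_target += 1
            continue
        var.state_index(truth)
        key = tuple((c, clean(v)) for c, v in zip(evidence_cols, cols[i])
                    if clean(v) is not None)
        if key not in cache:
            evidence = dict(key)
            cache[key] = most_likely_state(posterior_marginal(net, evidence, target))
        n_eval += 1
        if cache[key] != truth:
            n_err += 1
    if n_missing_target:
        warnings.warn(f"{target}: excluded {n_missing_target} record(s) with "
                      "missing target value", stacklevel=2)
    if n_eval == 0:
        raise NetworkError("no test records with an observed target value")
    return n_err / n_eval


def piv(adoption_rate: float, err: float) -> float:
    """Prediction Improvement Value: min(p, 1-p) - ErrorRate."""
    for name, x in (("adoption_rate", adoption_rate), ("error_rate", err)):
        if not 0.0 <= x <= 1.0:
            raise NetworkError(f"{name} must be in [0, 1], got {x}")
    return min(adoption_rate, 1.0 - adoption_rate) - err


def reliability_tier(piv_value: float) -> str:
    """Tier cut-offs: negative / [0, 0.10] / above 0.10."""
    if not -1.0 <= piv_value <= 0.5:
        raise NetworkError(f"PIV must be in [-1, 0.5], got {piv_value}")
    if piv_value < 0.0:
        return "not_meaningful"
    if piv_value <= 0.10:
        return "reliable"
    return "especially_reliable"


def _adoption_rate(data: pd.DataFrame, target: str, yes_state: str = "yes") -> float:
    col = data[target].astype("string").str.strip()
    observed = col[col.notna() & (col != "")]
    if len(observed) == 0:
        raise NetworkError(f"no observed values for target {target!r}")
    return float((observed == yes_state).mean())


def cross_validate(structure: NetworkStructure, data: pd.DataFrame, target: str,
                   split: SplitSpec = SplitSpec(), em: EMConfig = EMConfig(),
                   adoption_from: str = "full") -> ValidationReport:
    """Repeated random-split validation of one practice's network.

    Splits whose training part lacks one of the target states are redrawn (at
    most 10 times each, then an error is raised).  Each repetition fits with a
    deterministic seed derived from the split seed, so identical inputs give
    identical reports.
    """
    if target not in data.columns:
        raise NetworkError(f"data lacks target column {target!r}")
    if adoption_from not in ("full", "train"):
        raise NetworkError("adoption_from must be 'full' or 'train'")
    rng = np.random.default_rng(np.random.SeedSequence(split.seed))
    n = len(data)
    n_train = int(round(split.train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise NetworkError(f"degenerate split: {n_train} training records of {n}")
    full_rate = _adoption_rate(data, target)
    target_states = set(structure[target].states)

    details: list[SplitDetail] = []
    for rep in range(split.repetitions):
        for attempt in range(10):
            perm = rng.permutation(n)
            train = data.iloc[perm[:n_train]]
            observed = set(train[target].dropna().astype(str).str.strip())
            if target_states <= observed:
                break
            warnings.warn(f"repetition {rep}: training split lacks a target "
                          "state; redrawing", stacklevel=2)
        else:
            raise NetworkError(f"repetition {rep}: could not draw a training "
                               "split containing every target state")
        test = data.iloc[perm[n_train:]]
        rep_seed = int(np.random.SeedSequence(entropy=(split.seed, rep)).generate_state(1)[0]
                       % (2**31))
        fit = em_fit(structure, train, EMConfig(
            max_iter=em.max_iter, tol=em.tol, pseudo_count=em.pseudo_count,
            restarts=em.restarts, seed=rep_seed))
        err = error_rate(fit.network, test, target)
        rate = full_rate if adoption_from == "full" else _adoption_rate(train, target)
        details.append(SplitDetail(rep, len(train), len(test), err, piv(rate, err)))

    mean_err = float(np.mean([d.error_rate for d in details]))
    mean_piv = float(np.mean([d.piv for d in details]))
    return ValidationReport(target, full_rate, mean_err, mean_piv,
                            reliability_tier(mean_piv), details)


def report_frame(reports: list[ValidationReport]) -> pd.DataFrame:
    """One-row-per-practice summary table (adoption rate, Error Rate, PIV, tier)."""
    return pd.DataFrame([
        {
            "practice": r.practice,
            "adoption_rate": r.adoption_rate,
            "mean_error_rate": r.mean_error_rate,
            "mean_piv": r.mean_piv,
            "tier": r.tier,
        }
        for r in reports
    ])
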