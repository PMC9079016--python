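"""EM parameter learning of all CPTs from incomplete survey data.

The learner handles two kinds of unobserved values uniformly: cells missing
from individual records, and *latent* variables (the intermediate nodes) that
have no data column at all.  Each record is expanded into the set of its
possible completions; the E-step weighs completions by their joint probability
under the current parameters (this is exact inference per record), and the
M-step re-estimates every CPT from expected counts plus an optional Dirichlet
pseudo-count.

With a pseudo-count > 0 this is MAP-EM: the monotone quantity is the
penalized log-likelihood (observed-data log-likelihood plus the log-prior of
the parameters), which is asserted non-decreasing every iteration.  With
pseudo-count 0 the raw observed-data log-likelihood itself is monotone, and a
complete-data fit reduces to exact relative-frequency counting in one M-step.

Latent intermediate states have no fixed meaning; different restarts (or
seeds) may recover them in permuted order.  Every downstream quantity used in
the analyses (target posteriors, mutual information, intervention deltas) is
invariant to such relabelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bn import CPT, BeliefNetwork, ImpossibleEvidenceError, NetworkError, NetworkStructure

__all__ = ["EMConfig", "FitResult", "em_fit", "encode_dataset"]

#: refuse to expand a single record into more completions than this
_MAX_COMPLETIONS_PER_ROW = 100_000


@dataclass(frozen=True)
class EMConfig:
    """Tunable knobs of the EM learner.

    max_iter:      hard iteration cap per restart.
    tol:           relative change in the monotone objective that counts as
                   converged.
    pseudo_count:  symmetric Dirichlet pseudo-count added to every expected
                   count (1 = Laplace smoothing; 0 = pure maximum likelihood).
    restarts:      independent random initializations; the restart with the
                   best final observed-data log-likelihood wins.  Randomized
                   initialization is what breaks the symmetry of the latent
                   intermediate states.
    seed:          master seed; restarts draw from spawned child streams, so
                   the whole fit is reproducible bit for bit.
    """

    max_iter: int = 200
    tol: float = 1e-6
    pseudo_count: float = 1.0
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise NetworkError("tol must be > 0")
        if self.pseudo_count < 0:
            raise NetworkError("pseudo_count must be >= 0")
        if self.restarts < 1:
            raise NetworkError("restarts must be >= 1")
        if self.max_iter < 1:
            raise NetworkError("max_iter must be >= 1")


@dataclass
class FitResult:
    """Outcome of :func:`em_fit`."""

    network: BeliefNetwork
    log_likelihood: float
    n_iter: int
    restart: int
    trace: list[float] = field(default_factory=list)


def encode_dataset(data: pd.DataFrame, structure: NetworkStructure,
                   var_order: Sequence[str]) -> np.ndarray:
    """Integer-code a survey table against the structure's state labels.

    Returns an (n_rows, n_vars) int array; -1 marks a missing cell.  Variables
    without a data column (the latent intermediates) are all -1.  Unknown
    state labels raise.
    """
    n = len(data)
    codes = np.full((n, len(var_order)), -1, dtype=np.int64)
    for j, name in enumerate(var_order):
        if name not in data.columns:
            continue
        var = structure[name]
        lookup = {s: i for i, s in enumerate(var.states)}
        col = data[name]
        for i, value in enumerate(col.to_numpy()):
            if pd.isna(value):
                continue
            text = str(value).strip()
            if not text or text.lower() == "nan":
                continue
            if text not in lookup:
                raise NetworkError(f"{name}: unknown state {value!r} in row {col.index[i]}")
            codes[i, j] = lookup[text]
    return codes


def _completion_index(codes: np.ndarray, sizes: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Expand records into all completions of their unobserved cells.

    Returns ``comp`` (M, n_vars) full integer assignments and ``row`` (M,)
    mapping each pseudo-record back to its source record.  Records sharing a
    missingness pattern are expanded together.
    """
    n, V = codes.shape
    miss = codes < 0
    pattern_ids = {}
    row_pattern = np.empty(n, dtype=np.int64)
    for i in range(n):
        key = miss[i].tobytes()
        row_pattern[i] = pattern_ids.setdefault(key, len(pattern_ids))
    comp_blocks, row_blocks = [], []
    for pid in range(len(pattern_ids)):
        rows = np.flatnonzero(row_pattern == pid)
        unobs = np.flatnonzero(miss[rows[0]])
        k = int(np.prod(sizes[unobs])) if unobs.size else 1
        if k > _MAX_COMPLETIONS_PER_ROW:
            raise NetworkError(
                f"a record with {unobs.size} unobserved cells needs {k} completions "
                f"(cap {_MAX_COMPLETIONS_PER_ROW})")
        block = np.repeat(codes[rows], k, axis=0)
        if unobs.size:
            grids = np.meshgrid(*[np.arange(sizes[u]) for u in unobs], indexing="ij")
            fills = np.stack([g.ravel() for g in grids], axis=1)  # (k, |unobs|)
            block[:, unobs] = np.tile(fills, (len(rows), 1))
        comp_blocks.append(block)
        row_blocks.append(np.repeat(rows, k))
    return np.concatenate(comp_blocks, axis=0), np.concatenate(row_blocks)


def _random_tables(structure: NetworkStructure, var_order: Sequence[str],
                   rng: np.random.Generator) -> list[np.ndarray]:
    tables = []
    for name in var_order:
        var = structure[name]
        n_rows = int(np.prod([structure[p].n_states for p in structure.parents(name)]))
        raw = rng.gamma(1.0, size=(max(n_rows, 1), var.n_states))
        tables.append(raw / raw.sum(axis=1, keepdims=True))
    return tables


def em_fit(structure: NetworkStructure, data: pd.DataFrame, cfg: EMConfig = EMConfig(),
           fixed_cpts: Mapping[str, np.ndarray] | None = None) -> FitResult:
    """Learn all CPTs of ``structure`` from ``data`` by (MAP-)EM.

    ``fixed_cpts`` pins selected variables' tables (e.g. a hand-set target
    CPT); they enter inference but are never re-estimated.
    """
    var_order = structure.names
    sizes = np.array([structure[n].n_states for n in var_order], dtype=np.int64)
    codes = encode_dataset(data, structure, var_order)
    if len(codes) == 0:
        raise NetworkError("empty dataset")
    comp, row = _completion_index(codes, sizes)
    n = len(codes)

    # static per-variable flat indices into the raveled CPT: config * size + state
    parent_idx: list[np.ndarray] = []
    flat_idx: list[np.ndarray] = []
    n_rows_v: list[int] = []
    for j, name in enumerate(var_order):
        pcols = np.array([var_order.index(p) for p in structure.parents(name)], dtype=np.int64)
        if pcols.size:
            radix = np.ones(pcols.size, dtype=np.int64)
            for i in range(pcols.size - 2, -1, -1):
                radix[i] = radix[i + 1] * sizes[pcols[i + 1]]
            config = comp[:, pcols] @ radix
            n_rows = int(np.prod(sizes[pcols]))
        else:
            config = np.zeros(len(comp), dtype=np.int64)
            n_rows = 1
        parent_idx.append(config)
        flat_idx.append(config * sizes[j] + comp[:, j])
        n_rows_v.append(n_rows)

    fixed = dict(fixed_cpts or {})
    for name in fixed:
        structure[name]

    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.restarts)
    alpha = cfg.pseudo_count

    def prior_term(tables: list[np.ndarray]) -> float:
        if alpha == 0.0:
            return 0.0
        total = 0.0
        for t in tables:
            total += alpha * np.sum(np.log(np.maximum(t, 1e-300)))
        return total

    best: tuple[float, int, list[np.ndarray], list[float], int] | None = None
    for r, child_seed in enumerate(children):
        rng = np.random.default_rng(child_seed)
        tables = _random_tables(structure, var_order, rng)
        for j, name in enumerate(var_order):
            if name in fixed:
                tables[j] = np.asarray(fixed[name], dtype=float)
        trace: list[float] = []
        objective_prev = -np.inf
        loglik = -np.inf
        it = 0
        for it in range(1, cfg.max_iter + 1):
            # E-step: completion weights under current parameters
            w = np.ones(len(comp))
            for j in range(len(var_order)):
                w *= tables[j].ravel()[flat_idx[j]]
            z = np.bincount(row, weights=w, minlength=n)
            if np.any(z <= 0.0):
                bad = int(np.flatnonzero(z <= 0.0)[0])
                raise ImpossibleEvidenceError(
                    f"record {bad} has probability zero under the current parameters "
                    "(use a positive pseudo_count)")
            loglik = float(np.log(z).sum())
            objective = loglik + prior_term(tables)
            if objective < objective_prev - 1e-7 * max(1.0, abs(objective_prev)):
                raise RuntimeError(
                    f"EM objective decreased ({objective_prev} -> {objective})")
            trace.append(loglik)
            converged = (
                it > 1 and abs(objective - objective_prev)
                <= cfg.tol * max(1.0, abs(objective_prev)))
            objective_prev = objective
            if converged:
                break
            w_norm = w / z[row]
            # M-step
            for j, name in enumerate(var_order):
                if name in fixed:
                    continue
                s = int(sizes[j])
                counts = np.bincount(flat_idx[j], weights=w_norm,
                                     minlength=n_rows_v[j] * s).reshape(n_rows_v[j], s)
                counts += alpha
                rowsums = counts.sum(axis=1, keepdims=True)
                empty = rowsums[:, 0] <= 0.0
                if np.any(empty):
                    warnings.warn(
                        f"{name}: {int(empty.sum())} parent combination(s) never "
                        "visited; rows set to uniform", stacklevel=2)
                    counts[empty] = 1.0
                    rowsums = counts.sum(axis=1, keepdims=True)
                tables[j] = counts / rowsums
        if best is None or loglik > best[0]:
            best = (loglik, r, [t.copy() for t in tables], trace, it)

    loglik, r_best, tables, trace, n_iter = best
    variables = structure.variables
    cpts = {
        name: CPT(variables[name], [variables[p] for p in structure.parents(name)],
                  tables[j])
        for j, name in enumerate(var_order)
    }
    return FitResult(BeliefNetwork(structure, cpts), loglik, n_iter, r_best, trace)
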