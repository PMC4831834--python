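"""Greedy K2 structure search with a BIC score over the CLG likelihood.

K2 fixes a causal node ordering and, for each node in turn, greedily adds
the single predecessor whose addition most increases a decomposable score,
stopping when no addition helps or the parent budget is exhausted. The
classical K2 metric applies only to all-discrete data; here the network is
hybrid, so the score is BIC: the family's available-case maximum log
likelihood minus (free parameters) * log(n)/2. BIC is decomposable and
consistent, which is all the search needs.

Because candidate parents are restricted to predecessors in the ordering,
every structure the search (or the exhaustive oracle) can return is acyclic
by construction; CLG admissibility additionally forbids continuous parents
of discrete nodes.

K2 assumes complete data, so the search first restricts the table to rows
complete for the nodes in the ordering.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import GRADE_COL, GRADE_STATES, T1WC_COL, T1WC_STATES
from .network import VARIANCE_FLOOR, NetworkStructure, NodeSpec

__all__ = [
    "K2Config",
    "score_family",
    "k2_search",
    "exhaustive_best_dag",
    "node_specs_for",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class K2Config:
    node_order: tuple[str, ...]
    max_parents: int = 3
    score: str = "bic"
    allow_edges: frozenset | None = None
    forbid_edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.node_order)) != len(self.node_order):
            raise ValueError("node_order must list each node exactly once")
        if self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")
        if self.score != "bic":
            raise ValueError(f"unknown score {self.score!r}")


def node_specs_for(names) -> dict[str, NodeSpec]:
    """Default node typing: grade and the enhancement category are discrete,
    everything else Gaussian."""
    specs = {}
    for n in names:
        if n == GRADE_COL:
            specs[n] = NodeSpec(n, "discrete", GRADE_STATES)
        elif n == T1WC_COL:
            specs[n] = NodeSpec(n, "discrete", T1WC_STATES)
        else:
            specs[n] = NodeSpec(n, "gaussian")
    return specs


def _admissible(child: NodeSpec, parent: NodeSpec) -> bool:
    return not (parent.kind == "gaussian" and child.kind == "discrete")


def score_family(
    child: str,
    parents,
    table: pd.DataFrame,
    specs: dict[str, NodeSpec],
) -> float:
    """BIC of one family on its available cases.

    Returns ``-inf`` for an un-fittable family (too few complete rows for
    the regression, or no rows at all).
    """
    parents = tuple(parents)
    cspec = specs[child]
    for p in parents:
        if not _admissible(cspec, specs[p]):
            raise ValueError(
                f"{p}->{child} violates CLG admissibility"
            )
    rows = table.dropna(subset=[child, *parents])
    n = len(rows)
    if n == 0:
        return NEG_INF

    dparents = tuple(p for p in parents if specs[p].kind == "discrete")
    cparents = tuple(p for p in parents if specs[p].kind == "gaussian")
    q = 1
    for p in dparents:
        q *= len(specs[p].states)

    if cspec.kind == "discrete":
        loglik = _discrete_loglik(rows, child, dparents, cspec.states)
        k = q * (len(cspec.states) - 1)
    else:
        loglik = _clg_loglik(rows, child, dparents, cparents)
        if loglik is None:
            return NEG_INF
        k = q * (len(cparents) + 2)  # intercept, slopes, variance per config
    return loglik - 0.5 * k * math.log(n)


def _discrete_loglik(rows, child, dparents, states) -> float:
    if dparents:
        grouped = rows.groupby(list(dparents), observed=True)[child]
    else:
        grouped = [((), rows[child])]
        grouped = dict(grouped).items()
    total = 0.0
    for _, sub in grouped:
        counts = sub.value_counts().to_numpy(float)
        nsub = counts.sum()
        probs = counts / nsub
        total += float(np.sum(counts * np.log(probs)))
    return total


def _clg_loglik(rows, child, dparents, cparents):
    y_all = rows[child].to_numpy(float)
    x_all = (rows[list(cparents)].to_numpy(float)
             if cparents else np.empty((len(rows), 0)))
    n_coef = len(cparents) + 1
    if len(rows) < n_coef + 1:
        return None

    def _fit_ll(x, y):
        design = np.column_stack([np.ones(len(y)), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        s2 = max(float(np.mean(resid**2)), VARIANCE_FLOOR)
        m = len(y)
        return (-0.5 * m * math.log(2.0 * math.pi * s2)
                - float(np.sum(resid**2)) / (2.0 * s2)), coef, s2

    pooled_ll, pooled_coef, pooled_s2 = _fit_ll(x_all, y_all)
    if not dparents:
        return pooled_ll

    total = 0.0
    labels = [rows[p].to_numpy() for p in dparents]
    seen = set()
    for combo in zip(*labels):
        seen.add(combo)
    for combo in sorted(seen):
        mask = np.ones(len(rows), dtype=bool)
        for lab, v in zip(labels, combo):
            mask &= lab == v
        y = y_all[mask]
        x = x_all[mask]
        if len(y) < n_coef + 1:
            # stratum too small for its own regression: score it under the
            # pooled fit, mirroring the fallback used at fitting time
            design = np.column_stack([np.ones(len(y)), x])
            resid = y - design @ pooled_coef
            total += (-0.5 * len(y) * math.log(2.0 * math.pi * pooled_s2)
                      - float(np.sum(resid**2)) / (2.0 * pooled_s2))
        else:
            ll, _, _ = _fit_ll(x, y)
            total += ll
    return total


def _candidate_parents(child, predecessors, specs, cfg: K2Config):
    out = []
    for p in predecessors:
        if not _admissible(specs[child], specs[p]):
            continue
        if (p, child) in cfg.forbid_edges:
            continue
        if cfg.allow_edges is not None and (p, child) not in cfg.allow_edges:
            continue
        out.append(p)
    return out


def k2_search(
    table: pd.DataFrame,
    cfg: K2Config,
    specs: dict[str, NodeSpec] | None = None,
) -> NetworkStructure:
    """Greedy K2 over the fixed ordering; deterministic given table and
    config (score ties between candidates go to the earlier node in the
    ordering)."""
    order = cfg.node_order
    if specs is None:
        specs = node_specs_for(order)
    complete = table.dropna(subset=[n for n in order])
    edges: list[tuple[str, str]] = []
    for i, child in enumerate(order):
        parents: list[str] = []
        current = score_family(child, parents, complete, specs)
        candidates = _candidate_parents(child, order[:i], specs, cfg)
        while len(parents) < cfg.max_parents:
            best_gain, best_parent, best_score = 0.0, None, current
            for p in candidates:
                if p in parents:
                    continue
                s = score_family(child, parents + [p], complete, specs)
                if s - current > best_gain + 1e-12:
                    best_gain, best_parent, best_score = s - current, p, s
            if best_parent is None:
                break
            parents.append(best_parent)
            current = best_score
        edges.extend((p, child) for p in parents)
    return NetworkStructure([specs[n] for n in order], edges)


def exhaustive_best_dag(
    table: pd.DataFrame,
    node_order,
    max_parents: int = 3,
    specs: dict[str, NodeSpec] | None = None,
) -> NetworkStructure:
    """Exact argmax of the decomposable score over all order-consistent,
    admissible DAGs. Refuses more than 5 nodes (the search is exponential
    in parent-set count); intended as an oracle for small problems."""
    order = tuple(node_order)
    if len(order) > 5:
        raise ValueError("exhaustive search limited to <= 5 nodes")
    if specs is None:
        specs = node_specs_for(order)
    complete = table.dropna(subset=[n for n in order])
    edges: list[tuple[str, str]] = []
    for i, child in enumerate(order):
        candidates = [p for p in order[:i]
                      if _admissible(specs[child], specs[p])]
        best_score, best_set = NEG_INF, ()
        for size in range(0, min(max_parents, len(candidates)) + 1):
            for subset in itertools.combinations(candidates, size):
                s = score_family(child, subset, complete, specs)
                if s > best_score + 1e-12:
                    best_score, best_set = s, subset
        edges.extend((p, child) for p in best_set)
    return NetworkStructure([specs[n] for n in order], edges)


def total_score(
    structure: NetworkStructure,
    table: pd.DataFrame,
    specs: dict[str, NodeSpec] | None = None,
) -> float:
    """Sum of family scores (BIC is decomposable)."""
    if specs is None:
        specs = {n: s for n, s in structure.nodes.items()}
    complete = table.dropna(subset=[n for n in structure.nodes])
    return sum(
        score_family(child, structure.parents(child), complete, specs)
        for child in structure.nodes
    )
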