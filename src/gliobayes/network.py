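"""Conditional linear Gaussian (CLG) Bayesian networks.

The hybrid network underlying the grading model: discrete nodes (tumor grade,
enhancement category) carry multinomial CPDs conditioned on discrete parents;
each continuous node is Gaussian with mean linear in its continuous parents
and parameters indexed by the joint configuration of its discrete parents.
Admissibility requires that no Gaussian node is a parent of a discrete node,
so for every full discrete configuration the continuous nodes form a joint
multivariate Gaussian that can be compiled in closed form. Inference of the
grade posterior under arbitrary partial evidence is exact: unobserved
continuous nodes are marginalized by dropping their rows/columns of the
compiled joint Gaussian, unobserved discrete nodes are summed out, and all
weights are accumulated in log space.

Parameters are maximum-likelihood: per-configuration relative frequencies
for discrete nodes and per-configuration least-squares regressions with
n-denominator residual variance for Gaussian nodes, each family fitted on
its available cases (rows where child and parents are all observed).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

__all__ = [
    "NodeSpec",
    "NetworkStructure",
    "DiscreteCPD",
    "CLGCPD",
    "FittedNetwork",
    "fit_mle",
    "joint_gaussian_for_config",
    "posterior_grade",
    "predict",
    "log_likelihood",
    "sample",
    "save_network",
    "load_network",
]

FORMAT_VERSION = 1
VARIANCE_FLOOR = 1e-6
TIE_EPS = 1e-12


@dataclass(frozen=True)
class NodeSpec:
    """A typed node: ``discrete`` with >= 2 ordered states, or ``gaussian``."""

    name: str
    kind: str
    states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "gaussian"):
            raise ValueError(f"{self.name}: kind must be discrete|gaussian")
        if self.kind == "discrete" and len(self.states) < 2:
            raise ValueError(f"{self.name}: discrete nodes need >= 2 states")
        if self.kind == "gaussian" and self.states:
            raise ValueError(f"{self.name}: gaussian nodes carry no states")


class NetworkStructure:
    """A DAG over typed nodes with the CLG admissibility constraint."""

    def __init__(self, nodes, edges) -> None:
        self.nodes: dict[str, NodeSpec] = {n.name: n for n in nodes}
        if len(self.nodes) != len(list(nodes)):
            raise ValueError("duplicate node names")
        self.edges: tuple[tuple[str, str], ...] = tuple(
            (str(p), str(c)) for p, c in edges
        )
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise ValueError(f"edge {p}->{c} references undeclared node")
            if (self.nodes[p].kind == "gaussian"
                    and self.nodes[c].kind == "discrete"):
                raise ValueError(
                    f"edge {p}->{c}: a gaussian node cannot parent a "
                    "discrete node (CLG admissibility)"
                )
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structure contains a cycle")
        self._graph = g
        self._topo = tuple(nx.lexicographical_topological_sort(g))

    # -- queries ----------------------------------------------------------
    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._graph.predecessors(node)))

    def discrete_parents(self, node: str) -> tuple[str, ...]:
        return tuple(p for p in self.parents(node)
                     if self.nodes[p].kind == "discrete")

    def continuous_parents(self, node: str) -> tuple[str, ...]:
        return tuple(p for p in self.parents(node)
                     if self.nodes[p].kind == "gaussian")

    def topological_order(self) -> tuple[str, ...]:
        return self._topo

    @property
    def discrete_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self._topo
                     if self.nodes[n].kind == "discrete")

    @property
    def gaussian_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self._topo
                     if self.nodes[n].kind == "gaussian")

    def __eq__(self, other) -> bool:
        return (isinstance(other, NetworkStructure)
                and self.nodes == other.nodes
                and set(self.edges) == set(other.edges))

    def __repr__(self) -> str:
        return (f"NetworkStructure({len(self.nodes)} nodes, "
                f"edges={sorted(self.edges)})")


@dataclass
class DiscreteCPD:
    """Multinomial CPD: parent configuration -> probability vector."""

    child: str
    states: tuple[str, ...]
    parent_names: tuple[str, ...]
    parent_states: tuple[tuple[str, ...], ...]
    table: dict[tuple, np.ndarray]

    def prob(self, state: str, config: tuple) -> float:
        return float(self.table[config][self.states.index(state)])

    def validate(self) -> None:
        for cfg, probs in self.table.items():
            if len(probs) != len(self.states) or np.any(probs < 0):
                raise ValueError(f"{self.child}: malformed probability vector")
            if abs(float(np.sum(probs)) - 1.0) > 1e-10:
                raise ValueError(
                    f"{self.child}: probabilities for config {cfg} do not "
                    "sum to 1"
                )


@dataclass
class CLGCPD:
    """Linear-Gaussian CPD, parameters per discrete-parent configuration.

    For configuration d: child | parents ~ N(beta0 + beta . x_parents, sigma2).
    """

    child: str
    discrete_parents: tuple[str, ...]
    continuous_parents: tuple[str, ...]
    params: dict[tuple, tuple[float, np.ndarray, float]]

    def validate(self) -> None:
        k = len(self.continuous_parents)
        for cfg, (b0, beta, s2) in self.params.items():
            if len(beta) != k:
                raise ValueError(
                    f"{self.child}: coefficient vector length {len(beta)} "
                    f"!= {k} continuous parents"
                )
            if s2 < VARIANCE_FLOOR:
                raise ValueError(f"{self.child}: variance below floor")


@dataclass
class FittedNetwork:
    structure: NetworkStructure
    cpds: dict[str, object]
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.structure.nodes) - set(self.cpds)
        if missing:
            raise ValueError(f"missing CPD for node(s): {sorted(missing)}")
        extra = set(self.cpds) - set(self.structure.nodes)
        if extra:
            raise ValueError(f"CPD for undeclared node(s): {sorted(extra)}")
        self._joint_cache: dict = {}
        self._chol_cache: dict = {}

    def discrete_config_space(self):
        names = self.structure.discrete_nodes
        spaces = [self.structure.nodes[n].states for n in names]
        return names, spaces


# ---------------------------------------------------------------------------
# fitting

def fit_mle(
    structure: NetworkStructure,
    table: pd.DataFrame,
    smoothing: float = 0.0,
    variance_floor: float = VARIANCE_FLOOR,
) -> FittedNetwork:
    """Maximum-likelihood parameters for every family, available-case.

    Discrete CPDs are (optionally add-k smoothed) relative frequencies per
    discrete-parent configuration; Gaussian CPDs are per-configuration
    least-squares fits with n-denominator residual variance, floored at
    ``variance_floor``. A parent configuration with no rows (or too few rows
    for a regression) falls back to the configuration-marginal fit, which is
    recorded in ``fit_metadata``.
    """
    cpds: dict[str, object] = {}
    metadata: dict[str, dict] = {}
    for name in structure.topological_order():
        spec = structure.nodes[name]
        if name not in table.columns:
            raise ValueError(f"table lacks a column for node {name!r}")
        if spec.kind == "discrete":
            cpd, meta = _fit_discrete(structure, name, table, smoothing)
        else:
            cpd, meta = _fit_clg(structure, name, table, variance_floor)
        cpds[name] = cpd
        metadata[name] = meta
    return FittedNetwork(structure, cpds, metadata)


def _observed_rows(table: pd.DataFrame, cols) -> pd.DataFrame:
    return table.dropna(subset=list(cols))


def _fit_discrete(structure, name, table, smoothing):
    spec = structure.nodes[name]
    parents = structure.discrete_parents(name)  # all parents are discrete
    parent_states = tuple(structure.nodes[p].states for p in parents)
    rows = _observed_rows(table, (name, *parents))
    states = spec.states
    k = float(smoothing)

    # child marginal: the fallback for configurations never observed
    marg_counts = np.array(
        [float((rows[name] == s).sum()) for s in states]
    )
    if marg_counts.sum() + k * len(states) == 0:
        raise ValueError(f"family of {name!r}: no observed rows")
    marginal = (marg_counts + k) / (marg_counts.sum() + k * len(states))
    if k == 0 and np.any(marg_counts == 0) and not parents:
        # zero-probability states are legitimate MLE for a root node
        marginal = marg_counts / marg_counts.sum()

    cpd_table: dict[tuple, np.ndarray] = {}
    fallbacks = []
    for cfg in itertools.product(*parent_states) if parents else [()]:
        mask = np.ones(len(rows), dtype=bool)
        for p, v in zip(parents, cfg):
            mask &= (rows[p] == v).to_numpy()
        sub = rows.loc[mask, name]
        counts = np.array([float((sub == s).sum()) for s in states])
        total = counts.sum() + k * len(states)
        if total == 0:
            cpd_table[cfg] = marginal.copy()
            fallbacks.append(cfg)
        else:
            cpd_table[cfg] = (counts + k) / total
    cpd = DiscreteCPD(name, states, parents, parent_states, cpd_table)
    cpd.validate()
    meta = {"n_rows": int(len(rows)), "fallback_configs": fallbacks}
    return cpd, meta


def _fit_clg(structure, name, table, variance_floor):
    dparents = structure.discrete_parents(name)
    cparents = structure.continuous_parents(name)
    parent_states = tuple(structure.nodes[p].states for p in dparents)
    rows = _observed_rows(table, (name, *dparents, *cparents))
    n_coef = len(cparents) + 1  # intercept + slopes
    if len(rows) < n_coef + 1:
        raise ValueError(
            f"family of {name!r}: only {len(rows)} complete rows for "
            f"{n_coef} coefficients"
        )

    y_all = rows[name].to_numpy(float)
    x_all = (rows[list(cparents)].to_numpy(float)
             if cparents else np.empty((len(rows), 0)))

    def _ols(x, y):
        design = np.column_stack([np.ones(len(y)), x])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sigma2 = max(float(np.mean(resid**2)), variance_floor)
        return float(coef[0]), np.asarray(coef[1:], dtype=float), sigma2

    pooled = _ols(x_all, y_all)
    params: dict[tuple, tuple] = {}
    fallbacks = []
    for cfg in itertools.product(*parent_states) if dparents else [()]:
        mask = np.ones(len(rows), dtype=bool)
        for p, v in zip(dparents, cfg):
            mask &= (rows[p] == v).to_numpy()
        if mask.sum() < n_coef + 1:
            params[cfg] = pooled
            fallbacks.append(cfg)
        else:
            params[cfg] = _ols(x_all[mask], y_all[mask])
    cpd = CLGCPD(name, dparents, cparents, params)
    cpd.validate()
    meta = {"n_rows": int(len(rows)), "fallback_configs": fallbacks}
    return cpd, meta


# ---------------------------------------------------------------------------
# compilation and inference

def joint_gaussian_for_config(net: FittedNetwork, config: dict):
    """Compile the joint Gaussian over all gaussian nodes for one full
    discrete configuration.

    Returns ``(names, mean, cov)`` with nodes in topological order. The
    construction walks the DAG: mu_c = b0 + beta . mu_parents, and the
    covariance rows are propagated through the same linear map, adding the
    residual variance on the diagonal.
    """
    names = net.structure.gaussian_nodes
    dnames = net.structure.discrete_nodes
    for d in dnames:
        if d not in config:
            raise ValueError(f"config must assign discrete node {d!r}")
    key = tuple(config[d] for d in dnames)
    cached = net._joint_cache.get(key)
    if cached is not None:
        return cached

    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    mean = np.zeros(k)
    cov = np.zeros((k, k))
    for n in names:
        cpd: CLGCPD = net.cpds[n]
        cfg = tuple(config[d] for d in cpd.discrete_parents)
        b0, beta, s2 = cpd.params[cfg]
        i = idx[n]
        pidx = [idx[p] for p in cpd.continuous_parents]
        mean[i] = b0 + float(beta @ mean[pidx]) if pidx else b0
        if pidx:
            # Cov(c, j) = sum_k beta_k Cov(p_k, j) for previously placed j
            row = beta @ cov[np.ix_(pidx, range(k))]
            cov[i, :] = row
            cov[:, i] = row
            cov[i, i] = float(beta @ cov[np.ix_(pidx, pidx)] @ beta) + s2
        else:
            cov[i, i] = s2
    result = (names, mean, cov)
    net._joint_cache[key] = result
    return result


def _gaussian_logpdf(net, key, names, mean, cov, observed_names, values):
    """Log density of the observed continuous evidence for one config,
    with the unobserved gaussian nodes marginalized out."""
    if not observed_names:
        return 0.0
    cache_key = (key, observed_names)
    cached = net._chol_cache.get(cache_key)
    idx = [names.index(n) for n in observed_names]
    mu = mean[idx]
    if cached is None:
        sub = cov[np.ix_(idx, idx)]
        chol = np.linalg.cholesky(sub)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        net._chol_cache[cache_key] = (chol, logdet)
    else:
        chol, logdet = cached
    dev = np.asarray(values, dtype=float) - mu
    sol = solve_triangular(chol, dev, lower=True)
    quad = float(sol @ sol)
    k = len(idx)
    return -0.5 * (k * math.log(2.0 * math.pi) + logdet + quad)


def _config_log_weights(net: FittedNetwork, evidence: dict):
    """Iterate all full discrete configurations consistent with the evidence,
    yielding (config dict, log weight)."""
    structure = net.structure
    dnames = structure.discrete_nodes
    gnames = structure.gaussian_nodes
    observed_g = tuple(n for n in gnames if n in evidence)
    values = [float(evidence[n]) for n in observed_g]
    for n, v in evidence.items():
        if n not in structure.nodes:
            raise ValueError(f"evidence names unknown node {n!r}")
        spec = structure.nodes[n]
        if spec.kind == "discrete" and v not in spec.states:
            raise ValueError(f"evidence {n}={v!r} is not a valid state")
        if spec.kind == "gaussian" and not np.isfinite(float(v)):
            raise ValueError(f"evidence {n}={v!r} must be finite")

    spaces = [
        (evidence[d],) if d in evidence else structure.nodes[d].states
        for d in dnames
    ]
    for combo in itertools.product(*spaces):
        config = dict(zip(dnames, combo))
        logw = 0.0
        for d in dnames:
            cpd: DiscreteCPD = net.cpds[d]
            cfg = tuple(config[p] for p in cpd.parent_names)
            p = cpd.prob(config[d], cfg)
            if p == 0.0:
                logw = -np.inf
                break
            logw += math.log(p)
        if logw == -np.inf:
            yield config, -np.inf
            continue
        names, mean, cov = joint_gaussian_for_config(net, config)
        logw += _gaussian_logpdf(net, combo, list(names), mean, cov,
                                 observed_g, values)
        yield config, logw


def log_evidence(net: FittedNetwork, evidence: dict) -> float:
    """Log marginal density/probability of the evidence (all discrete
    configurations summed out, unobserved gaussian nodes marginalized)."""
    logws = [w for _, w in _config_log_weights(net, evidence)]
    return float(logsumexp(logws))


def posterior_grade(
    net: FittedNetwork, evidence: dict, grade_node: str = "grade"
):
    """Exact posterior over the grade node given partial evidence.

    Returns a :class:`Posterior` with the normalized distribution and the
    log-evidence of the observed data. Raises if the evidence has zero
    likelihood under every configuration.
    """
    if grade_node in evidence:
        raise ValueError("grade node must not be part of the evidence")
    states = net.structure.nodes[grade_node].states
    per_state = {s: [] for s in states}
    for config, logw in _config_log_weights(net, evidence):
        per_state[config[grade_node]].append(logw)
    logs = np.array([logsumexp(per_state[s]) if per_state[s] else -np.inf
                     for s in states])
    total = float(logsumexp(logs))
    if not np.isfinite(total):
        raise ValueError(
            "evidence has zero likelihood under all configurations"
        )
    probs = np.exp(logs - total)
    probs /= probs.sum()
    return Posterior(dict(zip(states, map(float, probs))), total)


@dataclass(frozen=True)
class Posterior:
    probs: dict[str, float]
    log_evidence: float

    def __getitem__(self, state: str) -> float:
        return self.probs[state]


def predict(
    net: FittedNetwork,
    evidence: dict,
    grade_node: str = "grade",
    positive_state: str = "high",
) -> tuple[str, float]:
    """Argmax grade with the documented tie rule: an exact tie (difference
    below 1e-12) resolves to the positive (high-grade) state, the
    clinically conservative call. Returns (label, P(positive))."""
    post = posterior_grade(net, evidence, grade_node)
    p_pos = post[positive_state]
    best = max(post.probs, key=lambda s: post.probs[s])
    if abs(post.probs[best] - p_pos) < TIE_EPS:
        best = positive_state
    return best, p_pos


def log_likelihood(net: FittedNetwork, table: pd.DataFrame) -> float:
    """Sum over rows of the log joint density of each row's observed nodes."""
    total = 0.0
    node_names = list(net.structure.nodes)
    for _, row in table.iterrows():
        ev = {}
        for n in node_names:
            if n in row.index and not pd.isna(row[n]):
                ev[n] = row[n]
        total += log_evidence(net, ev)
    return float(total)


def sample(
    net: FittedNetwork, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Forward-sample *n* rows from the fitted network."""
    cols: dict[str, np.ndarray] = {}
    for name in net.structure.topological_order():
        spec = net.structure.nodes[name]
        if spec.kind == "discrete":
            cpd: DiscreteCPD = net.cpds[name]
            out = np.empty(n, dtype=object)
            if not cpd.parent_names:
                out[:] = rng.choice(spec.states, size=n, p=cpd.table[()])
            else:
                parent_cols = [cols[p] for p in cpd.parent_names]
                for cfg, probs in cpd.table.items():
                    mask = np.ones(n, dtype=bool)
                    for pc, v in zip(parent_cols, cfg):
                        mask &= pc == v
                    m = int(mask.sum())
                    if m:
                        out[mask] = rng.choice(spec.states, size=m, p=probs)
            cols[name] = out
        else:
            cpd = net.cpds[name]
            mean = np.zeros(n)
            sd = np.zeros(n)
            if cpd.discrete_parents:
                parent_cols = [cols[p] for p in cpd.discrete_parents]
                for cfg, (b0, beta, s2) in cpd.params.items():
                    mask = np.ones(n, dtype=bool)
                    for pc, v in zip(parent_cols, cfg):
                        mask &= pc == v
                    mu = np.full(int(mask.sum()), b0)
                    for b, p in zip(beta, cpd.continuous_parents):
                        mu = mu + b * cols[p][mask]
                    mean[mask] = mu
                    sd[mask] = math.sqrt(s2)
            else:
                b0, beta, s2 = cpd.params[()]
                mu = np.full(n, b0)
                for b, p in zip(beta, cpd.continuous_parents):
                    mu = mu + b * cols[p]
                mean, sd = mu, np.full(n, math.sqrt(s2))
            cols[name] = mean + sd * rng.standard_normal(n)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# serialization (versioned JSON)

def _structure_to_dict(structure: NetworkStructure) -> dict:
    return {
        "nodes": [
            {"name": s.name, "kind": s.kind, "states": list(s.states)}
            for s in structure.nodes.values()
        ],
        "edges": [list(e) for e in structure.edges],
    }


def _structure_from_dict(d: dict) -> NetworkStructure:
    nodes = [
        NodeSpec(x["name"], x["kind"], tuple(x.get("states", ())))
        for x in d["nodes"]
    ]
    return NetworkStructure(nodes, [tuple(e) for e in d["edges"]])


def save_structure(structure: NetworkStructure, path) -> None:
    payload = {"format_version": FORMAT_VERSION}
    payload.update(_structure_to_dict(structure))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_structure(path) -> NetworkStructure:
    with open(path) as fh:
        payload = json.load(fh)
    _check_version(payload)
    return _structure_from_dict(payload)


def save_network(net: FittedNetwork, path) -> None:
    cpds = {}
    for name, cpd in net.cpds.items():
        if isinstance(cpd, DiscreteCPD):
            cpds[name] = {
                "kind": "discrete",
                "states": list(cpd.states),
                "parents": list(cpd.parent_names),
                "table": [
                    {"config": list(cfg), "probs": [float(x) for x in probs]}
                    for cfg, probs in cpd.table.items()
                ],
            }
        else:
            cpds[name] = {
                "kind": "clg",
                "discrete_parents": list(cpd.discrete_parents),
                "continuous_parents": list(cpd.continuous_parents),
                "params": [
                    {
                        "config": list(cfg),
                        "beta0": b0,
                        "beta": [float(x) for x in beta],
                        "sigma2": s2,
                    }
                    for cfg, (b0, beta, s2) in cpd.params.items()
                ],
            }
    payload = {
        "format_version": FORMAT_VERSION,
        "cpds": cpds,
        "fit_metadata": _jsonable(net.fit_metadata),
    }
    payload.update(_structure_to_dict(net.structure))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _check_version(payload: dict) -> None:
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"unsupported format_version {version!r}; this build reads "
            f"version {FORMAT_VERSION}"
        )


def load_network(path) -> FittedNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    _check_version(payload)
    structure = _structure_from_dict(payload)
    cpds: dict[str, object] = {}
    raw_cpds = payload.get("cpds", {})
    for name in structure.nodes:
        if name not in raw_cpds:
            raise ValueError(f"file has no CPD for node {name!r}")
        raw = raw_cpds[name]
        if raw["kind"] == "discrete":
            states = tuple(raw["states"])
            parents = tuple(raw["parents"])
            table = {
                tuple(entry["config"]): np.asarray(entry["probs"], float)
                for entry in raw["table"]
            }
            cpd = DiscreteCPD(
                name, states, parents,
                tuple(structure.nodes[p].states for p in parents), table,
            )
            cpd.validate()
        elif raw["kind"] == "clg":
            params = {
                tuple(entry["config"]): (
                    float(entry["beta0"]),
                    np.asarray(entry["beta"], float),
                    float(entry["sigma2"]),
                )
                for entry in raw["params"]
            }
            cpd = CLGCPD(
                name, tuple(raw["discrete_parents"]),
                tuple(raw["continuous_parents"]), params,
            )
            cpd.validate()
        else:
            raise ValueError(f"node {name!r}: unknown CPD kind {raw['kind']!r}")
        cpds[name] = cpd
    return FittedNetwork(structure, cpds, payload.get("fit_metadata", {}))
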