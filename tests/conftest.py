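import itertools

import numpy as np
import pytest

from gliobayes.network import (
    CLGCPD,
    DiscreteCPD,
    FittedNetwork,
    NetworkStructure,
    NodeSpec,
)


@pytest.fixture(scope="session")
def default_table():
    from gliobayes.cohort import default_cohort_spec, generate_cohort

    return generate_cohort(default_cohort_spec())


def make_net(nodes, edges, cpd_spec):
    """Build a FittedNetwork from a terse description.

    ``cpd_spec[name]`` is either ``{config: probs}`` for discrete nodes or
    ``{config: (beta0, beta, sigma2)}`` for gaussian nodes; configs are
    tuples over the node's discrete parents in sorted-name order.
    """
    structure = NetworkStructure(nodes, edges)
    cpds = {}
    for name, spec in structure.nodes.items():
        raw = cpd_spec[name]
        if spec.kind == "discrete":
            parents = structure.discrete_parents(name)
            cpds[name] = DiscreteCPD(
                name, spec.states, parents,
                tuple(structure.nodes[p].states for p in parents),
                {cfg: np.asarray(v, float) for cfg, v in raw.items()},
            )
        else:
            cpds[name] = CLGCPD(
                name,
                structure.discrete_parents(name),
                structure.continuous_parents(name),
                {cfg: (float(b0), np.asarray(beta, float), float(s2))
                 for cfg, (b0, beta, s2) in raw.items()},
            )
    return FittedNetwork(structure, cpds)


def symmetric_two_node_net():
    """grade -> X with X|high ~ N(1,1), X|low ~ N(-1,1), P(high)=0.5."""
    return make_net(
        [NodeSpec("grade", "discrete", ("low", "high")),
         NodeSpec("X", "gaussian")],
        [("grade", "X")],
        {
            "grade": {(): [0.5, 0.5]},
            "X": {("low",): (-1.0, [], 1.0), ("high",): (1.0, [], 1.0)},
        },
    )


def random_clg_net(rng, max_gaussian=3, extra_discrete=True):
    """A random admissible CLG network of at most 5 nodes.

    Discrete nodes come first in the order (grade always; optionally a
    second discrete node), then 1..max_gaussian gaussian nodes with random
    order-consistent continuous edges and random discrete-parent links.
    """
    nodes = [NodeSpec("grade", "discrete", ("low", "high"))]
    if extra_discrete and rng.random() < 0.5:
        nodes.append(NodeSpec("D", "discrete", ("a", "b", "c")))
    n_gauss = int(rng.integers(1, max_gaussian + 1))
    gauss = [NodeSpec(f"X{i}", "gaussian") for i in range(n_gauss)]
    order = nodes + gauss

    edges = []
    dis_names = [n.name for n in nodes]
    if len(nodes) == 2 and rng.random() < 0.6:
        edges.append(("grade", "D"))
    for i, g in enumerate(gauss):
        for d in dis_names:
            if rng.random() < 0.6:
                edges.append((d, g.name))
        for j in range(i):
            if rng.random() < 0.5:
                edges.append((gauss[j].name, g.name))

    structure = NetworkStructure(order, edges)
    cpds = {}
    for name, spec in structure.nodes.items():
        if spec.kind == "discrete":
            parents = structure.discrete_parents(name)
            spaces = [structure.nodes[p].states for p in parents]
            table = {}
            for cfg in itertools.product(*spaces) if parents else [()]:
                table[cfg] = rng.dirichlet(np.full(len(spec.states), 2.0))
            cpds[name] = DiscreteCPD(
                name, spec.states, parents, tuple(spaces), table
            )
        else:
            dparents = structure.discrete_parents(name)
            cparents = structure.continuous_parents(name)
            spaces = [structure.nodes[p].states for p in dparents]
            params = {}
            for cfg in itertools.product(*spaces) if dparents else [()]:
                params[cfg] = (
                    float(rng.uniform(-2, 2)),
                    rng.uniform(-1.5, 1.5, size=len(cparents)),
                    float(rng.uniform(0.3, 2.0)),
                )
            cpds[name] = CLGCPD(name, dparents, cparents, params)
    return FittedNetwork(structure, cpds)


def random_partial_evidence(net, rng, seed_row=None):
    """Random evidence: values taken from one forward sample so the
    evidence always has positive likelihood; each non-grade node observed
    with probability 1/2 (at least one node observed)."""
    from gliobayes.network import sample

    row = sample(net, 1, rng).iloc[0] if seed_row is None else seed_row
    candidates = [n for n in net.structure.nodes if n != "grade"]
    ev = {}
    for n in candidates:
        if rng.random() < 0.5:
            v = row[n]
            ev[n] = float(v) if net.structure.nodes[n].kind == "gaussian" \
                else v
    if not ev:
        n = candidates[int(rng.integers(len(candidates)))]
        v = row[n]
        ev[n] = float(v) if net.structure.nodes[n].kind == "gaussian" else v
    return ev
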