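"""Independent oracles used only by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
production code: grid integration instead of closed-form Gaussian
marginalization, exhaustive permutation enumeration instead of the
chi-square approximation, concordant-pair counting instead of the
trapezoidal sweep.
"""

from __future__ import annotations

import itertools
import math
from itertools import combinations

import numpy as np

from gliobayes.network import CLGCPD, DiscreteCPD, FittedNetwork


# ---------------------------------------------------------------------------
# grid-discretization posterior oracle

def _gaussian_ancestors(net: FittedNetwork, targets: set[str]) -> set[str]:
    """Ancestors of *targets* through continuous-parent links only."""
    out: set[str] = set()
    frontier = list(targets)
    while frontier:
        node = frontier.pop()
        cpd = net.cpds[node]
        for p in cpd.continuous_parents:
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def _sample_windows(net, config, latents, n_samples, span, rng):
    """Integration window per latent node, from naive forward samples."""
    gnames = net.structure.gaussian_nodes
    cols = {}
    for n in gnames:
        cpd: CLGCPD = net.cpds[n]
        cfg = tuple(config[d] for d in cpd.discrete_parents)
        b0, beta, s2 = cpd.params[cfg]
        mu = np.full(n_samples, b0)
        for b, p in zip(beta, cpd.continuous_parents):
            mu = mu + b * cols[p]
        cols[n] = mu + math.sqrt(s2) * rng.standard_normal(n_samples)
    windows = {}
    for n in latents:
        x = cols[n]
        sd = max(float(x.std()), 1e-6)
        windows[n] = (float(x.min()) - span * sd, float(x.max()) + span * sd)
    return windows


def grid_posterior(
    net: FittedNetwork,
    evidence: dict,
    grade_node: str = "grade",
    n_points: int = 801,
    span: float = 8.0,
    seed: int = 12345,
) -> dict[str, float]:
    """Posterior over the grade node by brute-force grid integration.

    For every full discrete configuration, unobserved gaussian nodes with an
    observed descendant are discretized on a trapezoid grid and the product
    of one-dimensional conditional densities is integrated numerically;
    barren gaussian nodes are simply dropped. No joint-Gaussian compilation
    is involved, making this independent of the production inference path.
    """
    rng = np.random.default_rng(seed)
    structure = net.structure
    dnames = structure.discrete_nodes
    gnames = structure.gaussian_nodes
    observed_g = {n for n in gnames if n in evidence}
    latents = sorted(_gaussian_ancestors(net, observed_g) - observed_g)
    if len(latents) > 3:
        raise ValueError("grid oracle limited to 3 latent dimensions")

    states = structure.nodes[grade_node].states
    totals = {s: 0.0 for s in states}
    spaces = [
        (evidence[d],) if d in evidence else structure.nodes[d].states
        for d in dnames
    ]
    for combo in itertools.product(*spaces):
        config = dict(zip(dnames, combo))
        disc_w = 1.0
        for d in dnames:
            cpd: DiscreteCPD = net.cpds[d]
            cfg = tuple(config[p] for p in cpd.parent_names)
            disc_w *= cpd.prob(config[d], cfg)
        if disc_w == 0.0:
            continue
        windows = _sample_windows(net, config, latents, 4000, span, rng)
        grids = {
            n: np.linspace(*windows[n], n_points) for n in latents
        }
        mesh = (np.meshgrid(*[grids[n] for n in latents], indexing="ij")
                if latents else [])
        value_of = {n: mesh[i] for i, n in enumerate(latents)}
        for n in observed_g:
            value_of[n] = float(evidence[n])

        density = 1.0
        for n in gnames:
            if n not in value_of:
                continue  # barren: contributes a factor integrating to 1
            cpd = net.cpds[n]
            cfg = tuple(config[d] for d in cpd.discrete_parents)
            b0, beta, s2 = cpd.params[cfg]
            mu = b0
            for b, p in zip(beta, cpd.continuous_parents):
                mu = mu + b * value_of[p]
            density = density * (
                np.exp(-0.5 * (value_of[n] - mu) ** 2 / s2)
                / math.sqrt(2.0 * math.pi * s2)
            )
        for axis in reversed(range(len(latents))):
            density = np.trapezoid(density, grids[latents[axis]], axis=axis)
        totals[config[grade_node]] += disc_w * float(density)
    z = sum(totals.values())
    if z <= 0.0:
        raise ValueError("zero total mass in grid oracle")
    return {s: totals[s] / z for s in states}


# ---------------------------------------------------------------------------
# exact permutation distribution of the two-group rank statistic

def exact_permutation_p(group_a, group_b, statistic) -> tuple[float, float]:
    """(standard p, mid-p) of ``statistic(a, b)`` over all group assignments.

    ``statistic`` is a callable returning the test statistic; larger means
    more extreme. Enumerates every C(N, n_a) split of the pooled sample.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    pooled = np.concatenate([a, b])
    n = pooled.size
    h_obs = statistic(a, b)
    stats = []
    for idx in combinations(range(n), a.size):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        stats.append(statistic(pooled[sel], pooled[~sel]))
    stats = np.asarray(stats)
    gt = float(np.mean(stats > h_obs + 1e-9))
    eq = float(np.mean(np.abs(stats - h_obs) <= 1e-9))
    return gt + eq, gt + 0.5 * eq


# ---------------------------------------------------------------------------
# Mann-Whitney pair-count AUC

def pair_count_auc(scores, labels) -> float:
    """AUC as the fraction of concordant positive/negative pairs, ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes")
    diff = pos[:, None] - neg[None, :]
    return float(
        ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size)
    )


# ---------------------------------------------------------------------------
# brute-force tie correction for the rank statistic

def tie_corrected_h(group_a, group_b) -> float:
    """Independent implementation of the tie-corrected statistic, written
    directly from the defining formula with explicit midranks."""
    a = list(map(float, group_a))
    b = list(map(float, group_b))
    pooled = sorted(a + b)
    n = len(pooled)
    # midranks by explicit averaging of positions of equal values
    rank_of = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        rank_of[pooled[i]] = (i + 1 + j) / 2.0
        i = j
    ra = sum(rank_of[x] for x in a) / len(a)
    rb = sum(rank_of[x] for x in b) / len(b)
    expect = (n + 1) / 2.0
    h = (12.0 / (n * (n + 1))) * (
        len(a) * (ra - expect) ** 2 + len(b) * (rb - expect) ** 2
    )
    tie = sum(
        t**3 - t
        for t in (pooled.count(v) for v in set(pooled))
    )
    denom = 1.0 - tie / (n**3 - n)
    return 0.0 if denom <= 0 else h / denom
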