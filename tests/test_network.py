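import json

import numpy as np
import pandas as pd
import pytest

from gliobayes.network import (
    FittedNetwork,
    NetworkStructure,
    NodeSpec,
    fit_mle,
    joint_gaussian_for_config,
    load_network,
    log_evidence,
    log_likelihood,
    posterior_grade,
    predict,
    sample,
    save_network,
)
from conftest import make_net, random_clg_net, random_partial_evidence, \
    symmetric_two_node_net
from oracles import grid_posterior


GRADE = NodeSpec("grade", "discrete", ("low", "high"))


class TestStructureValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            NetworkStructure(
                [NodeSpec("X", "gaussian"), NodeSpec("Y", "gaussian")],
                [("X", "Y"), ("Y", "X")],
            )

    def test_gaussian_parent_of_discrete_rejected(self):
        with pytest.raises(ValueError, match="admissibility"):
            NetworkStructure(
                [GRADE, NodeSpec("X", "gaussian")], [("X", "grade")]
            )

    def test_undeclared_endpoint_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            NetworkStructure([GRADE], [("grade", "X")])

    def test_discrete_needs_two_states(self):
        with pytest.raises(ValueError, match="states"):
            NodeSpec("g", "discrete", ("only",))


class TestFitting:
    def test_grade_marginal_from_cohort(self, default_table):
        net = fit_mle(NetworkStructure([GRADE], []), default_table)
        probs = dict(zip(("low", "high"), net.cpds["grade"].table[()]))
        assert probs["high"] == pytest.approx(30 / 56)
        assert probs["low"] == pytest.approx(26 / 56)

    def test_two_point_closed_form(self):
        t = pd.DataFrame({"X": [1.0, 3.0]})
        net = fit_mle(NetworkStructure([NodeSpec("X", "gaussian")], []), t)
        b0, beta, s2 = net.cpds["X"].params[()]
        assert (b0, len(beta), s2) == (pytest.approx(2.0), 0,
                                       pytest.approx(1.0))

    def test_clg_regression_against_normal_equations(self):
        # oracle: explicit normal-equations solve, MLE variance with /n
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 2.0, 200)
        y = 0.7 - 1.3 * x + rng.normal(0, 0.5, 200)
        t = pd.DataFrame({"X": x, "Y": y})
        structure = NetworkStructure(
            [NodeSpec("X", "gaussian"), NodeSpec("Y", "gaussian")],
            [("X", "Y")],
        )
        net = fit_mle(structure, t)
        b0, beta, s2 = net.cpds["Y"].params[()]
        design = np.column_stack([np.ones(200), x])
        ref = np.linalg.solve(design.T @ design, design.T @ y)
        resid = y - design @ ref
        assert b0 == pytest.approx(ref[0], abs=1e-8)
        assert beta[0] == pytest.approx(ref[1], abs=1e-8)
        assert s2 == pytest.approx(float(np.mean(resid**2)), abs=1e-8)

    def test_zero_count_config_falls_back_to_marginal(self):
        t = pd.DataFrame({
            "grade": ["high"] * 10,  # 'low' configuration never observed
            "X": np.linspace(0, 1, 10),
        })
        structure = NetworkStructure(
            [GRADE, NodeSpec("X", "gaussian")], [("grade", "X")]
        )
        net = fit_mle(structure, t)
        assert ("low",) in net.fit_metadata["X"]["fallback_configs"]
        hi = net.cpds["X"].params[("high",)]
        lo = net.cpds["X"].params[("low",)]
        assert lo[0] == pytest.approx(hi[0])

    def test_too_small_family_errors_with_name(self):
        t = pd.DataFrame({"X": [1.0, 2.0], "Y": [1.0, 2.0]})
        structure = NetworkStructure(
            [NodeSpec("X", "gaussian"), NodeSpec("Y", "gaussian")],
            [("X", "Y")],
        )
        with pytest.raises(ValueError, match="'Y'"):
            fit_mle(structure, t)

    def test_available_case_per_family(self):
        # family of Y uses only rows where X and Y are both observed
        t = pd.DataFrame({
            "X": [1.0, 2.0, 3.0, np.nan, np.nan, 4.0],
            "Y": [2.1, 4.2, 5.9, 1.0, 2.0, 8.1],
        })
        structure = NetworkStructure(
            [NodeSpec("X", "gaussian"), NodeSpec("Y", "gaussian")],
            [("X", "Y")],
        )
        net = fit_mle(structure, t)
        assert net.fit_metadata["Y"]["n_rows"] == 4
        assert net.fit_metadata["X"]["n_rows"] == 4


class TestJointGaussian:
    def test_single_node_base_case(self):
        net = make_net([NodeSpec("X", "gaussian")], [],
                       {"X": {(): (1.5, [], 2.5)}})
        names, mean, cov = joint_gaussian_for_config(net, {})
        assert names == ("X",)
        assert mean[0] == 1.5 and cov[0, 0] == 2.5

    def test_chain_hand_computation(self):
        # Y = 2X + 1 + eps, Var(X)=1, Var(eps)=0.5
        net = make_net(
            [NodeSpec("X", "gaussian"), NodeSpec("Y", "gaussian")],
            [("X", "Y")],
            {"X": {(): (0.0, [], 1.0)}, "Y": {(): (1.0, [2.0], 0.5)}},
        )
        _, mean, cov = joint_gaussian_for_config(net, {})
        assert mean[1] == pytest.approx(1.0)
        assert cov[1, 1] == pytest.approx(4.5)
        assert cov[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("net_seed", [0, 1, 2, 3])
    def test_against_forward_sampling(self, net_seed):
        rng = np.random.default_rng(net_seed)
        net = random_clg_net(rng)
        dnames = net.structure.discrete_nodes
        config = {d: net.structure.nodes[d].states[0] for d in dnames}
        names, mean, cov = joint_gaussian_for_config(net, config)
        # covariance must be symmetric PSD
        assert np.allclose(cov, cov.T, atol=1e-8)
        assert np.linalg.eigvalsh(cov).min() > -1e-8
        # forward-sampling cross-check conditioned on the discrete config
        draws = sample(net, 200_000, np.random.default_rng(net_seed + 100))
        mask = np.ones(len(draws), dtype=bool)
        for d, v in config.items():
            mask &= (draws[d] == v).to_numpy()
        sub = draws.loc[mask, list(names)].to_numpy()
        se = np.sqrt(np.diag(cov) / mask.sum())
        assert np.all(np.abs(sub.mean(axis=0) - mean) < 6 * se)
        emp_cov = np.cov(sub.T).reshape(len(names), len(names))
        assert np.allclose(emp_cov, cov, atol=0.15)


class TestInference:
    def test_empty_evidence_returns_marginal(self):
        net = symmetric_two_node_net()
        post = posterior_grade(net, {})
        assert post["high"] == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_likelihoods(self):
        net = symmetric_two_node_net()
        post = posterior_grade(net, {"X": 0.0})
        assert post["high"] == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_bayes_rule(self):
        # P(high|x) = logistic(2x) for the symmetric unit-variance pair
        net = symmetric_two_node_net()
        for x in (-1.3, -0.2, 0.1, 0.8, 2.5):
            post = posterior_grade(net, {"X": x})
            expected = 1.0 / (1.0 + np.exp(-2.0 * x))
            assert post["high"] == pytest.approx(expected, abs=1e-12)

    def test_posterior_monotone_in_evidence(self):
        net = symmetric_two_node_net()
        xs = np.linspace(-3, 3, 25)
        ps = [posterior_grade(net, {"X": x})["high"] for x in xs]
        assert np.all(np.diff(ps) > 0)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_grid_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        net = random_clg_net(rng)
        ev = random_partial_evidence(net, rng)
        p = posterior_grade(net, ev).probs
        q = grid_posterior(net, ev)
        tv = 0.5 * sum(abs(p[s] - q[s]) for s in p)
        assert tv < 1e-3
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-10)

    def test_marginalization_of_barren_nodes(self):
        # pruning an unobserved leaf must not change the posterior
        rng = np.random.default_rng(55)
        net = random_clg_net(rng, max_gaussian=3)
        # find a gaussian leaf (a node that parents nothing)
        leaves = [n for n in net.structure.gaussian_nodes
                  if all(p != n for p, _ in net.structure.edges)]
        if not leaves:
            pytest.skip("random net has no gaussian leaf")
        leaf = leaves[-1]
        ev = {n: 0.3 for n in net.structure.gaussian_nodes if n != leaf}
        full = posterior_grade(net, ev).probs
        pruned_nodes = [s for n, s in net.structure.nodes.items()
                        if n != leaf]
        pruned_edges = [e for e in net.structure.edges if leaf not in e]
        pruned = FittedNetwork(
            NetworkStructure(pruned_nodes, pruned_edges),
            {n: c for n, c in net.cpds.items() if n != leaf},
        )
        sub = posterior_grade(pruned, ev).probs
        for s in full:
            assert full[s] == pytest.approx(sub[s], abs=1e-12)

    def test_zero_likelihood_raises(self):
        net = make_net(
            [GRADE, NodeSpec("T", "discrete", ("u", "v"))],
            [("grade", "T")],
            {
                "grade": {(): [0.5, 0.5]},
                "T": {("low",): [1.0, 0.0], ("high",): [1.0, 0.0]},
            },
        )
        with pytest.raises(ValueError, match="zero likelihood"):
            posterior_grade(net, {"T": "v"})

    def test_grade_in_evidence_rejected(self):
        net = symmetric_two_node_net()
        with pytest.raises(ValueError, match="grade"):
            posterior_grade(net, {"grade": "high"})


class TestPredict:
    def test_argmax_and_tie_rule(self):
        net = symmetric_two_node_net()
        assert predict(net, {"X": 3.0})[0] == "high"
        assert predict(net, {"X": -3.0})[0] == "low"
        # exact symmetry: documented tie -> high grade
        assert predict(net, {"X": 0.0})[0] == "high"
        assert predict(net, {"X": 0.1})[0] == "high"


class TestLogLikelihood:
    def test_empty_table_is_zero(self, default_table):
        net = symmetric_two_node_net()
        assert log_likelihood(net, pd.DataFrame(columns=["grade", "X"])) \
            == 0.0

    def test_factorization_identity(self):
        # fully observed rows: total equals the sum of local log-CPD terms
        rng = np.random.default_rng(4)
        net = random_clg_net(rng, extra_discrete=False)
        rows = sample(net, 20, rng)
        total = log_likelihood(net, rows)
        local = 0.0
        for _, row in rows.iterrows():
            for name, spec in net.structure.nodes.items():
                cpd = net.cpds[name]
                if spec.kind == "discrete":
                    cfg = tuple(row[p] for p in cpd.parent_names)
                    local += np.log(cpd.prob(row[name], cfg))
                else:
                    cfg = tuple(row[p] for p in cpd.discrete_parents)
                    b0, beta, s2 = cpd.params[cfg]
                    mu = b0 + sum(
                        b * row[p]
                        for b, p in zip(beta, cpd.continuous_parents)
                    )
                    local += (-0.5 * np.log(2 * np.pi * s2)
                              - (row[name] - mu) ** 2 / (2 * s2))
        assert total == pytest.approx(local, rel=1e-10)

    def test_unobserved_leaf_leaves_value_unchanged(self):
        net = symmetric_two_node_net()
        rows = pd.DataFrame({"grade": ["high", "low"], "X": [0.5, -0.2]})
        base = log_likelihood(net, rows)
        bigger = make_net(
            [GRADE, NodeSpec("X", "gaussian"), NodeSpec("Z", "gaussian")],
            [("grade", "X"), ("X", "Z")],
            {
                "grade": {(): [0.5, 0.5]},
                "X": {("low",): (-1.0, [], 1.0), ("high",): (1.0, [], 1.0)},
                "Z": {(): (0.0, [1.0], 1.0)},
            },
        )
        assert log_likelihood(bigger, rows) == pytest.approx(base,
                                                             rel=1e-10)


class TestSerialization:
    def test_roundtrip_bit_for_bit(self, tmp_path):
        rng = np.random.default_rng(9)
        net = random_clg_net(rng)
        p = tmp_path / "net.json"
        save_network(net, p)
        back = load_network(p)
        for name, cpd in net.cpds.items():
            other = back.cpds[name]
            if hasattr(cpd, "table"):
                for cfg, probs in cpd.table.items():
                    assert np.array_equal(other.table[cfg], probs)
            else:
                for cfg, (b0, beta, s2) in cpd.params.items():
                    ob0, obeta, os2 = other.params[cfg]
                    assert (ob0, os2) == (b0, s2)
                    assert np.array_equal(obeta, beta)

    def test_missing_cpd_named(self, tmp_path):
        net = symmetric_two_node_net()
        p = tmp_path / "net.json"
        save_network(net, p)
        payload = json.loads(p.read_text())
        del payload["cpds"]["X"]
        p.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="'X'"):
            load_network(p)

    def test_unknown_version_refused(self, tmp_path):
        net = symmetric_two_node_net()
        p = tmp_path / "net.json"
        save_network(net, p)
        payload = json.loads(p.read_text())
        payload["format_version"] = 999
        p.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="format_version"):
            load_network(p)
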