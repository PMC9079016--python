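"""Core network representation, exact inference, and the do-operator."""

import numpy as np
import pytest

from nadopt.bn import (CPT, BeliefNetwork, Distribution, ImpossibleEvidenceError,
                       NetworkError, NetworkStructure, Variable, do_intervention,
                       enumerate_assignments, joint_marginal, joint_probability,
                       most_likely_state, posterior_marginal)
from nadopt.xmlbif import read_xmlbif, write_xmlbif

from .conftest import random_evidence, random_network
from .oracles import brute_joint, brute_posterior


def chain_ab(p_b_given_a=(1.0, 0.0)):
    a = Variable("A", ("yes", "no"))
    b = Variable("B", ("yes", "no"))
    s = NetworkStructure([a, b], [("A", "B")])
    return BeliefNetwork(s, {
        "A": CPT(a, (), [[0.5, 0.5]]),
        "B": CPT(b, (a,), [[p_b_given_a[0], 1 - p_b_given_a[0]],
                           [p_b_given_a[1], 1 - p_b_given_a[1]]]),
    })


class TestStructureValidation:
    def test_variable_needs_two_unique_states(self):
        with pytest.raises(NetworkError):
            Variable("x", ("only",))
        with pytest.raises(NetworkError):
            Variable("x", ("a", "a"))

    def test_cycle_rejected(self):
        a, b = Variable("a", ("0", "1")), Variable("b", ("0", "1"))
        with pytest.raises(NetworkError, match="cycle"):
            NetworkStructure([a, b], [("a", "b"), ("b", "a")])

    def test_target_must_be_sink(self):
        t = Variable("t", ("no", "yes"), "target")
        b = Variable("b", ("0", "1"))
        with pytest.raises(NetworkError, match="outgoing"):
            NetworkStructure([t, b], [("t", "b")])

    def test_cpt_rows_must_normalize(self):
        v = Variable("v", ("a", "b"))
        with pytest.raises(NetworkError, match="sum"):
            CPT(v, (), [[0.6, 0.5]])

    def test_cpt_parent_mismatch_rejected(self):
        a, b = Variable("a", ("0", "1")), Variable("b", ("0", "1"))
        s = NetworkStructure([a, b], [("a", "b")])
        with pytest.raises(NetworkError, match="parents"):
            BeliefNetwork(s, {"a": CPT(a, (), [[0.5, 0.5]]),
                              "b": CPT(b, (), [[0.5, 0.5]])})


class TestJointProbability:
    def test_two_node_chain_product(self):
        net = chain_ab((1.0, 0.0))
        assert joint_probability(net, {"A": "yes", "B": "yes"}) == pytest.approx(0.5)

    def test_zero_entry_gives_zero(self):
        net = chain_ab((1.0, 0.0))
        assert joint_probability(net, {"A": "yes", "B": "no"}) == 0.0

    def test_incomplete_assignment_rejected(self):
        net = chain_ab()
        with pytest.raises(NetworkError, match="misses"):
            joint_probability(net, {"A": "yes"})

    def test_matches_bruteforce_product_on_random_nets(self, rng):
        for _ in range(25):
            net = random_network(rng, n_nodes=5)
            assignment = {n: net.structure[n].states[
                int(rng.integers(net.structure[n].n_states))]
                for n in net.structure.names}
            assert joint_probability(net, assignment) == pytest.approx(
                brute_joint(net, assignment), abs=1e-12)

    def test_joint_sums_to_one(self, rng):
        net = random_network(rng, n_nodes=4)
        total = sum(joint_probability(net, a) for a in enumerate_assignments(net))
        assert total == pytest.approx(1.0, abs=1e-8)


class TestPosteriorMarginal:
    def test_income_given_farm_size(self, two_node_income_net):
        d = posterior_marginal(two_node_income_net, {"farm_size": "large"}, "income")
        assert d["high"] == pytest.approx(0.60)
        d = posterior_marginal(two_node_income_net, {"farm_size": "small"}, "income")
        assert d["high"] == pytest.approx(0.30)

    def test_empty_evidence_root_prior(self, two_node_income_net):
        d = posterior_marginal(two_node_income_net, {}, "farm_size")
        np.testing.assert_allclose(d.probabilities, [0.5, 0.5])

    def test_impossible_evidence_raises(self):
        net = chain_ab((1.0, 0.0))
        with pytest.raises(ImpossibleEvidenceError):
            posterior_marginal(net, {"A": "yes", "B": "no"}, "A")

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            net = random_network(rng, n_nodes=6)
            evidence = random_evidence(rng, net)
            query = next(n for n in net.structure.names if n not in evidence)
            try:
                expected = brute_posterior(net, evidence, query)
            except ZeroDivisionError:
                with pytest.raises(ImpossibleEvidenceError):
                    posterior_marginal(net, evidence, query)
                continue
            got = posterior_marginal(net, evidence, query)
            np.testing.assert_allclose(got.probabilities, expected, atol=1e-9)
            assert got.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(got.probabilities >= 0)

    def test_query_inside_evidence_is_masked_posterior(self, rng):
        net = random_network(rng, n_nodes=5)
        name = net.structure.names[0]
        var = net.structure[name]
        if var.n_states < 3:
            net = random_network(rng, n_nodes=5, max_states=4)
            name = next(n for n in net.structure.names if net.structure[n].n_states >= 3)
            var = net.structure[name]
        subset = var.states[:2]
        d = posterior_marginal(net, {name: subset}, name)
        expected = brute_posterior(net, {name: subset}, name)
        np.testing.assert_allclose(d.probabilities, expected, atol=1e-9)


class TestMostLikelyState:
    def test_argmax(self):
        v = Variable("t", ("yes", "no"))
        assert most_likely_state(Distribution(v, np.array([0.7, 0.3]))) == "yes"

    def test_tie_breaks_to_first_declared_state(self):
        v = Variable("t", ("no", "yes"))
        assert most_likely_state(Distribution(v, np.array([0.5, 0.5]))) == "no"

    def test_base_rate_prediction_is_no_adoption(self):
        # a target-only network with adoption rate 40% predicts "no" always
        t = Variable("adopt", ("no", "yes"), "target")
        net = BeliefNetwork(NetworkStructure([t], []), {"adopt": CPT(t, (), [[0.6, 0.4]])})
        assert most_likely_state(posterior_marginal(net, {}, "adopt")) == "no"


class TestDoIntervention:
    def test_do_on_root_equals_conditioning(self, rng):
        net = random_network(rng, n_nodes=5)
        root = next(n for n in net.structure.names if not net.structure.parents(n))
        var = net.structure[root]
        forced = np.zeros(var.n_states)
        forced[0] = 1.0
        mutilated = do_intervention(net, root, forced)
        for query in net.structure.names:
            if query == root:
                continue
            np.testing.assert_allclose(
                posterior_marginal(mutilated, {}, query).probabilities,
                posterior_marginal(net, {root: var.states[0]}, query).probabilities,
                atol=1e-9)

    def test_identity_when_forcing_current_marginal(self, rng):
        net = random_network(rng, n_nodes=5)
        root = next(n for n in net.structure.names if not net.structure.parents(n))
        current = posterior_marginal(net, {}, root)
        mutilated = do_intervention(net, root, current)
        for query in net.structure.names:
            np.testing.assert_allclose(
                posterior_marginal(mutilated, {}, query).probabilities,
                posterior_marginal(net, {}, query).probabilities, atol=1e-9)

    def test_soft_do_is_mixture_of_hard_dos(self, two_node_income_net):
        net = two_node_income_net
        var = net.structure["farm_size"]
        mixed = do_intervention(net, "farm_size", np.array([0.5, 0.5]))
        got = posterior_marginal(mixed, {}, "income").probabilities
        parts = [posterior_marginal(do_intervention(net, "farm_size", f), {}, "income"
                                    ).probabilities
                 for f in (np.array([1.0, 0.0]), np.array([0.0, 1.0]))]
        np.testing.assert_allclose(got, 0.5 * parts[0] + 0.5 * parts[1], atol=1e-12)
        assert var.states == ("small", "large")

    def test_cannot_intervene_on_target(self):
        t = Variable("adopt", ("no", "yes"), "target")
        net = BeliefNetwork(NetworkStructure([t], []), {"adopt": CPT(t, (), [[0.6, 0.4]])})
        with pytest.raises(NetworkError, match="target"):
            do_intervention(net, "adopt", np.array([1.0, 0.0]))


class TestXmlbifRoundTrip:
    def test_lossless_round_trip(self, rng, tmp_path):
        net = random_network(rng, n_nodes=6)
        path = tmp_path / "net.xmlbif"
        write_xmlbif(net, path)
        back = read_xmlbif(path)
        assert back.structure == net.structure
        for name in net.structure.names:
            assert back.structure[name].role == net.structure[name].role
            np.testing.assert_allclose(back.cpts[name].table, net.cpts[name].table,
                                       atol=1e-12, rtol=0)
            assert back.cpts[name].parent_names == net.cpts[name].parent_names

    def test_joint_marginal_pairs_match_oracle(self, rng):
        net = random_network(rng, n_nodes=5)
        a, b = net.structure.names[0], net.structure.names[-1]
        joint = joint_marginal(net, {}, [a, b])
        for i, sa in enumerate(net.structure[a].states):
            marginal = brute_posterior(net, {a: sa}, b)
            pa = brute_posterior(net, {}, a)[i]
            np.testing.assert_allclose(joint[i], np.array(marginal) * pa, atol=1e-9)
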