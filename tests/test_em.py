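"""EM learning: complete-data exactness, monotonicity, recovery, determinism."""

import numpy as np
import pandas as pd
import pytest

from nadopt.bn import CPT, BeliefNetwork, NetworkStructure, Variable
from nadopt.em import EMConfig, em_fit, encode_dataset
from nadopt.survey_network import build_structure, default_structure_spec, retarget
from nadopt.synthetic import GeneratorConfig, default_ground_truth, generate_survey


def two_node_structure():
    a = Variable("a", ("0", "1"))
    b = Variable("b", ("0", "1"))
    return NetworkStructure([a, b], [("a", "b")])


class TestCompleteData:
    def test_complete_data_equals_frequency_counting(self):
        s = two_node_structure()
        data = pd.DataFrame({"a": ["0", "0", "0", "1"], "b": ["0", "1", "1", "1"]})
        fit = em_fit(s, data, EMConfig(pseudo_count=0.0, restarts=1, seed=1))
        np.testing.assert_allclose(fit.network.cpts["a"].table, [[0.75, 0.25]])
        np.testing.assert_allclose(fit.network.cpts["b"].table,
                                   [[1 / 3, 2 / 3], [0.0, 1.0]])

    def test_laplace_smoothing_shrinks_toward_uniform(self):
        s = two_node_structure()
        data = pd.DataFrame({"a": ["0", "0", "0", "1"], "b": ["0", "1", "1", "1"]})
        fit = em_fit(s, data, EMConfig(pseudo_count=1.0, restarts=1, seed=1))
        np.testing.assert_allclose(fit.network.cpts["a"].table, [[4 / 6, 2 / 6]])
        np.testing.assert_allclose(fit.network.cpts["b"].table,
                                   [[2 / 5, 3 / 5], [1 / 3, 2 / 3]])

    def test_unvisited_parent_combination_warns_and_goes_uniform(self):
        s = two_node_structure()
        data = pd.DataFrame({"a": ["0", "0"], "b": ["0", "1"]})
        with pytest.warns(UserWarning, match="never"):
            fit = em_fit(s, data, EMConfig(pseudo_count=0.0, restarts=1, seed=1))
        np.testing.assert_allclose(fit.network.cpts["b"].table[1], [0.5, 0.5])


class TestMissingAndLatent:
    def test_loglik_monotone_with_missing_cells(self):
        truth = default_ground_truth(practices=["soil_testing"])
        data = generate_survey(GeneratorConfig(
            truth, 400, seed=3, missingness={"income": 0.3, "consultant": 0.3}))
        s = build_structure(retarget(default_structure_spec(), "soil_testing"))
        cols = [c for c in data.columns if c in s.names]
        fit = em_fit(s, data[cols], EMConfig(pseudo_count=0.0, restarts=2,
                                             max_iter=60, seed=2))
        trace = np.array(fit.trace)
        assert np.all(np.diff(trace) >= -1e-7 * np.abs(trace[:-1]))

    def test_fully_latent_variable_with_flat_likelihood_terminates(self):
        # b's rows identical -> a (unobserved) is unidentifiable; EM must not crash
        a = Variable("a", ("0", "1"))
        b = Variable("b", ("0", "1"))
        s = NetworkStructure([a, b], [("a", "b")])
        data = pd.DataFrame({"b": ["0", "1", "1", "0"]})
        fit = em_fit(s, data, EMConfig(restarts=2, max_iter=50, seed=4))
        assert fit.n_iter <= 50
        assert np.isfinite(fit.log_likelihood)

    def test_same_seed_same_data_bit_identical(self):
        truth = default_ground_truth(practices=["fertigation"])
        data = generate_survey(GeneratorConfig(truth, 300, seed=5))
        s = build_structure(retarget(default_structure_spec(), "fertigation"))
        cols = [c for c in data.columns if c in s.names]
        cfg = EMConfig(restarts=2, max_iter=40, seed=9)
        fit1 = em_fit(s, data[cols], cfg)
        fit2 = em_fit(s, data[cols], cfg)
        assert fit1.log_likelihood == fit2.log_likelihood
        assert fit1.restart == fit2.restart
        for name in s.names:
            np.testing.assert_array_equal(fit1.network.cpts[name].table,
                                          fit2.network.cpts[name].table)

    def test_fixed_cpt_is_not_reestimated(self):
        s = two_node_structure()
        data = pd.DataFrame({"a": ["0", "1", "1"], "b": ["0", "1", "0"]})
        pinned = np.array([[0.9, 0.1], [0.1, 0.9]])
        fit = em_fit(s, data, EMConfig(restarts=1, seed=0),
                     fixed_cpts={"b": pinned})
        np.testing.assert_array_equal(fit.network.cpts["b"].table, pinned)


class TestRecovery:
    def test_cpt_recovery_small_net(self):
        # complete data from a known 2-variable truth: entries within 0.03 at n=5000
        a = Variable("a", ("0", "1", "2"))
        b = Variable("b", ("0", "1"))
        s = NetworkStructure([a, b], [("a", "b")])
        truth = BeliefNetwork(s, {
            "a": CPT(a, (), [[0.2, 0.5, 0.3]]),
            "b": CPT(b, (a,), [[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]]),
        })
        data = generate_survey(GeneratorConfig(truth, 5000, seed=11))
        fit = em_fit(s, data, EMConfig(pseudo_count=0.0, restarts=1, seed=0))
        for name in ("a", "b"):
            assert np.max(np.abs(fit.network.cpts[name].table
                                 - truth.cpts[name].table)) < 0.03

    def test_fitted_beats_independence_model_held_out(self):
        # the layered 13-node model should out-predict an all-independent model
        truth = default_ground_truth(practices=["soil_testing"])
        data = generate_survey(GeneratorConfig(truth, 2000, seed=21))
        s = build_structure(retarget(default_structure_spec(), "soil_testing"))
        cols = [c for c in data.columns if c in s.names]
        train, test = data[cols].iloc[:1500], data[cols].iloc[1500:]
        fit = em_fit(s, train, EMConfig(restarts=2, max_iter=80, seed=7))

        observed = [c for c in cols]
        indep = NetworkStructure([s[c] for c in observed], [])
        fit0 = em_fit(indep, train, EMConfig(restarts=1, max_iter=5, seed=7))

        def held_out_ll(structure, network, frame):
            codes = encode_dataset(frame, structure, structure.names)
            from nadopt.em import _completion_index
            sizes = np.array([structure[n].n_states for n in structure.names])
            comp, row = _completion_index(codes, sizes)
            w = np.ones(len(comp))
            for j, name in enumerate(structure.names):
                cpt = network.cpts[name]
                pcols = [structure.names.index(p) for p in structure.parents(name)]
                config = np.zeros(len(comp), dtype=np.int64)
                radix = 1
                for p in reversed(pcols):
                    config += comp[:, p] * radix
                    radix *= sizes[p]
                w *= cpt.table[config, comp[:, j]]
            z = np.bincount(row, weights=w, minlength=len(codes))
            return float(np.log(np.maximum(z, 1e-300)).sum())

        ll_model = held_out_ll(s, fit.network, test)
        ll_indep = held_out_ll(indep, fit0.network, test)
        assert ll_model > ll_indep


class TestLatentLabelInvariance:
    def test_downstream_quantities_invariant_to_latent_relabelling(self):
        from nadopt.bn import joint_marginal
        from nadopt.sensitivity import mutual_information
        truth = default_ground_truth(practices=["fertigation"])
        data = generate_survey(GeneratorConfig(truth, 500, seed=13))
        s = build_structure(retarget(default_structure_spec(), "fertigation"))
        cols = [c for c in data.columns if c in s.names]
        fit = em_fit(s, data[cols], EMConfig(restarts=1, max_iter=40, seed=3))
        net = fit.network

        # permute the states of one latent node consistently everywhere
        perm = [2, 0, 1]
        latent = "engagement"
        lvar = net.structure[latent]
        cpts = {}
        for name, cpt in net.cpts.items():
            table = cpt.table.copy()
            if name == latent:
                table = table[:, perm]
            if latent in cpt.parent_names:
                axis = cpt.parent_names.index(latent)
                shape = [p.n_states for p in cpt.parents] + [cpt.child.n_states]
                arr = table.reshape(shape)
                arr = np.take(arr, perm, axis=axis)
                table = arr.reshape(cpt.table.shape)
            cpts[name] = CPT(cpt.child, cpt.parents, table)
        permuted = BeliefNetwork(net.structure, cpts)

        for ev in ({}, {"farm_size": "large"}, {"self_certification": "yes"}):
            np.testing.assert_allclose(
                joint_marginal(net, ev, ["fertigation"]),
                joint_marginal(permuted, ev, ["fertigation"]), atol=1e-12)
        assert mutual_information(net, "fertigation", "income") == pytest.approx(
            mutual_information(permuted, "fertigation", "income"), abs=1e-12)
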