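"""Skeleton learning, MR orientation, Hamming distance, tuning, effects, pipeline."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import mrnet
from mrnet.errors import CollinearityError, ComparisonError
from mrnet.evaluation import oracle_specs
from mrnet.network import BIDIRECTED, DIRECTED, UNDIRECTED, _pair_status, true_network

from conftest import make_chain


class TestResidualize:
    def test_no_covariates_centers(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 4, 9]})
        out = mrnet.residualize_covariates(df, None)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)

    def test_residual_orthogonal_to_covariate(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 70, 500)
        df = pd.DataFrame({"m": 3 * age + rng.standard_normal(500)})
        out = mrnet.residualize_covariates(df, age)
        assert abs(np.corrcoef(out["m"], age)[0, 1]) < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        cov = rng.standard_normal((200, 2))
        df = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        once = mrnet.residualize_covariates(df, cov)
        twice = mrnet.residualize_covariates(once, cov)
        pd.testing.assert_frame_equal(once, twice)

    def test_rank_deficient_covariates_rejected(self):
        z = np.random.default_rng(2).standard_normal(100)
        df = pd.DataFrame({"a": z})
        with pytest.raises(CollinearityError):
            mrnet.residualize_covariates(df, np.column_stack([z, z]))


class TestSkeleton:
    def test_independent_entities_give_empty_skeleton(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((4000, 6)), columns=list("abcdef"))
        net = mrnet.learn_skeleton(df, mrnet.LearnerConfig(tuning_alpha=0.01))
        assert len(net.edges) <= 1  # up to test level

    def test_chain_separation(self, chain3):
        _, omics = mrnet.simulate_dataset(chain3, 5000, seed=4)
        net = mrnet.learn_skeleton(omics, mrnet.LearnerConfig(tuning_alpha=0.01))
        pairs = {tuple(sorted(e.pair())) for e in net.edges}
        assert pairs == {("M0", "M1"), ("M1", "M2")}
        assert net.meta["separating_sets"][frozenset(("M0", "M2"))] == ("M1",)

    def test_oracle_skeleton_equals_dag_adjacency(self):
        """With population covariance, the learned skeleton is exactly the true
        adjacency; removed pairs are d-separated in the true DAG (networkx oracle)."""
        for seed in range(6):
            spec = mrnet.sample_random_dag(6, 1.5, seed=seed)
            cov = mrnet.sem_covariance(spec)
            net = mrnet.learn_skeleton_from_covariance(cov, mrnet.LearnerConfig())
            learned = {tuple(sorted(e.pair())) for e in net.edges}
            truth = {tuple(sorted((s, t))) for s, t, _ in spec.true_edges()}
            assert learned == truth
            dag = true_network(spec).directed_graph()
            for pair, sep in net.meta["separating_sets"].items():
                a, b = sorted(pair)
                assert nx.is_d_separator(dag, {a}, {b}, set(sep))

    def test_edge_count_monotone_in_alpha(self):
        spec = mrnet.attach_instruments(mrnet.sample_random_dag(8, 1.5, seed=5), alpha=0.5)
        _, omics = mrnet.simulate_dataset(spec, 2000, seed=6)
        counts = [
            len(mrnet.learn_skeleton(omics, mrnet.LearnerConfig(tuning_alpha=a)).edges)
            for a in (0.2, 0.1, 0.05, 0.01, 0.001)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestOrientation:
    def test_chain_oriented_by_single_instrument(self):
        # the screen itself has a 5% false-rejection rate, so require the
        # correct orientation in most replicates and never the reverse
        directed = 0
        spec = make_chain([0.6], alpha=None)
        spec = mrnet.attach_instruments(spec, alpha=0.6, entities=["M0"])
        cfg = mrnet.LearnerConfig(tuning_alpha=0.01)
        for seed in range(5):
            geno, omics = mrnet.simulate_dataset(spec, 5000, seed=seed)
            skel = mrnet.learn_skeleton(omics, cfg)
            ivs = mrnet.assign_instruments(geno, omics, 10.0)
            net = mrnet.orient_edges(skel, ivs, omics, geno.to_frame().astype(float), cfg)
            (edge,) = net.edges
            assert not (edge.kind == DIRECTED and edge.source == "M1")
            directed += edge.kind == DIRECTED and edge.source == "M0"
        assert directed >= 4

    def test_no_instruments_all_bidirected(self):
        spec = make_chain([0.6, 0.6])  # no iv_map at all
        omics = mrnet.simulate_sem(spec, None, seed=8, n_samples=4000)
        cfg = mrnet.LearnerConfig(tuning_alpha=0.01)
        skel = mrnet.learn_skeleton(omics, cfg)
        ivs = mrnet.InstrumentSet(assignments={})
        net = mrnet.orient_edges(skel, ivs, omics, pd.DataFrame(index=omics.index), cfg)
        assert net.edges and all(e.kind == BIDIRECTED for e in net.edges)

    def test_mixed_instrumented_and_dietlike_entities(self):
        # two confounded IV-less entities plus an instrumented pair: the
        # instrumented edge is directed, the IV-less pair bidirected
        entities = ["D0", "D1", "X", "Y"]
        W = np.zeros((4, 4))
        W[2, 3] = 0.6  # X -> Y
        lam = np.zeros((1, 4))
        lam[0, :2] = 0.8  # latent confounder drives the diet-like pair
        spec = mrnet.SemSpec(entity_ids=entities, adjacency=W, confounder_loadings=lam)
        spec = mrnet.attach_instruments(spec, alpha=0.6, entities=["X", "Y"])
        geno, omics = mrnet.simulate_dataset(spec, 5000, seed=9)
        cfg = mrnet.LearnerConfig(tuning_alpha=0.01)
        skel = mrnet.learn_skeleton(omics, cfg)
        ivs = mrnet.assign_instruments(geno, omics, 10.0)
        net = mrnet.orient_edges(skel, ivs, omics, geno.to_frame().astype(float), cfg)
        kinds = {tuple(sorted(e.pair())): e.kind for e in net.edges}
        assert kinds[("D0", "D1")] == BIDIRECTED
        assert kinds[("X", "Y")] == DIRECTED

    def test_population_oracle_recovers_true_dag(self):
        for spec in oracle_specs():
            cov = mrnet.sem_covariance(spec, maf=0.3)
            skel = mrnet.learn_skeleton_from_covariance(cov)
            iv_for = {e: ids[0] for e, (ids, _) in spec.iv_map.items()}
            net = mrnet.orient_edges_from_covariance(
                skel, iv_for, mrnet.joint_covariance(spec, 0.3)
            )
            assert mrnet.hamming_distance(net, true_network(spec)) == 0

    def test_directed_subgraph_always_acyclic(self):
        for seed in range(5):
            spec = mrnet.attach_instruments(
                mrnet.sample_random_dag(10, 1.5, seed=seed), alpha=0.6
            )
            geno, omics = mrnet.simulate_dataset(spec, 2000, seed=seed + 100)
            net, _, _ = mrnet.fit_network(geno, omics, None, mrnet.LearnerConfig(seed=seed))
            assert nx.is_directed_acyclic_graph(net.directed_graph())


class TestHammingDistance:
    def _net(self, nodes, edges):
        return mrnet.CausalNetwork(nodes=nodes, edges=edges)

    def test_identical_graphs_zero(self, chain3):
        t = true_network(chain3)
        assert mrnet.hamming_distance(t, t.copy()) == 0

    def test_empty_vs_complete_four_nodes(self):
        nodes = list("abcd")
        empty = self._net(nodes, [])
        complete = self._net(
            nodes,
            [mrnet.Edge(a, b, UNDIRECTED) for i, a in enumerate(nodes) for b in nodes[i + 1 :]],
        )
        assert mrnet.hamming_distance(empty, complete) == 6

    def test_matches_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(10)
        nodes = list("abcd")
        kinds = [None, DIRECTED, "reversed", UNDIRECTED, BIDIRECTED]

        def random_net():
            # direct edges along a random order so the graph stays acyclic
            order = {v: i for i, v in enumerate(rng.permutation(nodes))}
            edges = []
            for i, a in enumerate(nodes):
                for b in nodes[i + 1 :]:
                    k = kinds[rng.integers(0, 5)]
                    if k is None:
                        continue
                    if k in (DIRECTED, "reversed"):
                        s, t = sorted((a, b), key=order.get)
                        edges.append(mrnet.Edge(s, t, DIRECTED))
                    else:
                        edges.append(mrnet.Edge(a, b, k))
            return self._net(nodes, edges)

        for _ in range(25):
            g1, g2 = random_net(), random_net()
            s1, s2 = _pair_status(g1), _pair_status(g2)
            expected = 0
            for i, a in enumerate(nodes):  # brute force over all pairs
                for b in nodes[i + 1 :]:
                    pr = frozenset((a, b))
                    expected += s1.get(pr, "absent") != s2.get(pr, "absent")
            assert mrnet.hamming_distance(g1, g2) == expected

    def test_mismatched_nodes_rejected(self):
        with pytest.raises(ComparisonError):
            mrnet.hamming_distance(self._net(["a"], []), self._net(["b"], []))


class TestTuningSelection:
    def test_single_grid_value_returned(self, chain3):
        _, omics = mrnet.simulate_dataset(chain3, 600, seed=11)
        alpha, table = mrnet.select_tuning_parameter(omics, [0.01], mrnet.LearnerConfig(seed=1))
        assert alpha == 0.01 and len(table) == 1

    def test_chosen_minimizes_mean_distance_and_is_deterministic(self, chain3):
        _, omics = mrnet.simulate_dataset(chain3, 1500, seed=12)
        cfg = mrnet.LearnerConfig(seed=2, subsamples=6)
        a1, t1 = mrnet.select_tuning_parameter(omics, [0.1, 0.01, 0.001], cfg)
        a2, t2 = mrnet.select_tuning_parameter(omics, [0.1, 0.01, 0.001], cfg)
        assert a1 == a2
        pd.testing.assert_frame_equal(t1, t2)
        chosen = t1.loc[t1["alpha"] == a1, "mean_hamming"].iloc[0]
        assert (chosen <= t1["mean_hamming"] + 1e-12).all()


class TestEdgeEffects:
    def test_chain_effect_recovered(self):
        spec = make_chain([0.5], alpha=1.0)
        geno, omics = mrnet.simulate_dataset(spec, 50_000, seed=13)
        net = true_network(spec).copy()
        for e in net.edges:
            e.effect = None
        out = mrnet.estimate_edge_effects(net, omics)
        assert out.find_edge("M0", "M1").effect == pytest.approx(0.5, abs=0.02)

    def test_parentless_nodes_unannotated_and_relabel_invariant(self, chain3):
        _, omics = mrnet.simulate_dataset(chain3, 5000, seed=14)
        net = true_network(chain3)
        out = mrnet.estimate_edge_effects(net, omics)
        effects = {(e.source, e.target): e.effect for e in out.edges}
        # relabel nodes and re-estimate: effects must follow the labels
        mapping = {"M0": "x", "M1": "y", "M2": "z"}
        renamed = mrnet.CausalNetwork(
            nodes=[mapping[v] for v in net.nodes],
            edges=[mrnet.Edge(mapping[e.source], mapping[e.target]) for e in net.edges],
        )
        out2 = mrnet.estimate_edge_effects(renamed, omics.rename(columns=mapping))
        for (s, t), val in effects.items():
            assert out2.find_edge(mapping[s], mapping[t]).effect == pytest.approx(val)


class TestFitNetwork:
    def test_deterministic_under_seed(self, chain3):
        geno, omics = mrnet.simulate_dataset(chain3, 3000, seed=15)
        cfg = mrnet.LearnerConfig(seed=3)
        n1, _, r1 = mrnet.fit_network(geno, omics, None, cfg)
        n2, _, r2 = mrnet.fit_network(geno, omics, None, cfg)
        pd.testing.assert_frame_equal(n1.to_frame(), n2.to_frame())
        assert r1["edge_counts"] == r2["edge_counts"]

    def test_report_counts_and_directed_sources_instrumented(self):
        spec = mrnet.attach_instruments(mrnet.sample_random_dag(8, 1.2, seed=16), alpha=0.6)
        geno, omics = mrnet.simulate_dataset(spec, 4000, seed=17)
        net, ivs, report = mrnet.fit_network(geno, omics, None, mrnet.LearnerConfig(seed=4))
        assert report["n_valid_instruments"] <= report["n_candidate_instruments"]
        for e in net.edges_of_kind(DIRECTED):
            assert ivs.best_instrument(e.source) is not None

    def test_covariate_stage_removes_shared_drivers(self):
        # a shared measured covariate would otherwise connect all entities
        rng = np.random.default_rng(18)
        n = 4000
        age = rng.standard_normal(n)
        spec = make_chain([0.0], alpha=0.6)  # two causally unrelated entities
        geno, omics = mrnet.simulate_dataset(spec, n, seed=19)
        omics = omics + np.outer(age, [1.0, 1.0])
        cfg = mrnet.LearnerConfig(tuning_alpha=0.01, seed=5)
        with_cov, _, _ = mrnet.fit_network(geno, omics, pd.DataFrame({"age": age}), cfg)
        without, _, _ = mrnet.fit_network(geno, omics, None, cfg)
        assert len(with_cov.edges) == 0
        assert len(without.edges) == 1
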