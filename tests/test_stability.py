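"""Backdoor machinery and the four stability diagnostics."""

import numpy as np
import pandas as pd
import pytest

import mrnet
from mrnet.errors import AmbiguityError, QueryError
from mrnet.evaluation import (
    backdoor_exhaustive,
    equivalence_study_spec,
    stability_fixture_spec,
    _increment_data,
)
from mrnet.network import BIDIRECTED, LearnerConfig, fit_network, true_network
from mrnet.stability import (
    AdjustmentQuery,
    backdoor_adjustment_sets,
    confounding_equivalence_test,
    permutation_test,
    pure_broadcasters,
    pure_receptors,
    variable_increment_test,
    variable_reduction_test,
)
from mrnet.synthetic import sem_covariance, simulate_dataset


class TestBackdoor:
    def test_two_equivalent_confounder_sets(self):
        _, net = equivalence_study_spec()
        sets = backdoor_adjustment_sets(net, "X", "Y", max_size=2)
        assert {frozenset({"E", "Z"}), frozenset({"F", "Z"})} == set(sets)

    def test_direct_edge_allows_empty_set(self):
        net = mrnet.CausalNetwork(nodes=["x", "y"], edges=[mrnet.Edge("x", "y")])
        assert frozenset() in backdoor_adjustment_sets(net, "x", "y")

    def test_exhaustive_agreement_with_dsep_oracle_small(self):
        # all DAGs up to 4 nodes, every query pair (5-node sweep runs in the
        # acceptance suite)
        assert backdoor_exhaustive(max_nodes=4)["mismatched_queries"] == 0

    def test_unresolved_edge_on_relevant_path_raises(self):
        net = mrnet.CausalNetwork(
            nodes=["x", "y", "z"],
            edges=[mrnet.Edge("x", "y"), mrnet.Edge("z", "x", BIDIRECTED)],
        )
        with pytest.raises(AmbiguityError):
            backdoor_adjustment_sets(net, "z", "y")

    def test_unknown_nodes_rejected(self):
        net = mrnet.CausalNetwork(nodes=["x"], edges=[])
        with pytest.raises(QueryError):
            backdoor_adjustment_sets(net, "x", "nope")


class TestConfoundingEquivalence:
    def test_identical_sets_give_exact_zero(self):
        spec, _ = equivalence_study_spec()
        omics = mrnet.simulate_sem(spec, None, seed=1, n_samples=1000)
        q = AdjustmentQuery("X", "Y", sets=[{"E", "Z"}, {"E", "Z"}])
        rep = confounding_equivalence_test(omics, q, seed=0)
        assert rep.statistic == 0.0 and rep.p_value == 1.0 and rep.passed

    def test_equivalent_sets_agree(self):
        spec, _ = equivalence_study_spec()
        omics = mrnet.simulate_sem(spec, None, seed=2, n_samples=5000)
        q = AdjustmentQuery("X", "Y", sets=[{"E", "Z"}, {"F", "Z"}])
        rep = confounding_equivalence_test(omics, q, seed=0)
        assert rep.passed and rep.p_value is not None

    def test_missing_confounder_detected(self):
        spec, _ = equivalence_study_spec()
        omics = mrnet.simulate_sem(spec, None, seed=3, n_samples=5000)
        q = AdjustmentQuery("X", "Y", sets=[{"E", "Z"}, {"E"}])  # S2 omits Z
        rep = confounding_equivalence_test(omics, q, seed=0)
        assert not rep.passed

    def test_closed_form_matches_bootstrap_scale(self):
        spec, _ = equivalence_study_spec()
        omics = mrnet.simulate_sem(spec, None, seed=4, n_samples=5000)
        q = AdjustmentQuery("X", "Y", sets=[{"E", "Z"}, {"F", "Z"}])
        boot = confounding_equivalence_test(omics, q, seed=0, n_boot=800)
        closed = confounding_equivalence_test(omics, q, method="closed_form")
        assert closed.details["se"] == pytest.approx(boot.details["se"], rel=0.2)

    def test_query_validation(self):
        with pytest.raises(QueryError):
            AdjustmentQuery("X", "X", sets=[])
        with pytest.raises(QueryError):
            AdjustmentQuery("X", "Y", sets=[{"X"}])


class TestVariableIncrement:
    def test_irrelevant_extra_passes_with_null_coefficient(self):
        df = _increment_data(5000, seed=5, violation=False)
        rng = np.random.default_rng(0)
        df["T"] = rng.standard_normal(len(df))  # pure noise add-on
        q = AdjustmentQuery("X", "Y", sets=[{"Z"}], extra="T")
        rep = variable_increment_test(df, q, seed=0)
        assert rep.passed
        assert abs(rep.details["beta_t"]) < 0.05

    def test_child_of_exposure_passes(self):
        df = _increment_data(5000, seed=6, violation=False)
        q = AdjustmentQuery("X", "Y", sets=[{"Z"}], extra="T")
        assert variable_increment_test(df, q, seed=0).passed

    def test_direct_cause_of_outcome_rejected(self):
        df = _increment_data(5000, seed=7, violation=True)
        q = AdjustmentQuery("X", "Y", sets=[{"Z"}], extra="T")
        assert not variable_increment_test(df, q, seed=0).passed

    def test_extra_in_set_rejected(self):
        df = _increment_data(100, seed=8, violation=False)
        q = AdjustmentQuery("X", "Y", sets=[{"Z", "T"}], extra="T")
        with pytest.raises(QueryError):
            variable_increment_test(df, q)


@pytest.fixture(scope="module")
def fitted_fixture():
    spec = stability_fixture_spec()
    geno, omics = simulate_dataset(spec, 4000, seed=21, maf=0.3)
    cfg = LearnerConfig(tuning_alpha=0.01, seed=21, subsamples=8)
    net, _, _ = fit_network(geno, omics, None, cfg)
    return spec, omics, net, cfg


class TestVariableReduction:
    def test_population_oracle_perfect_recovery(self, fitted_fixture):
        spec, omics, _, cfg = fitted_fixture
        rep = variable_reduction_test(
            omics, true_network(spec), cfg, n_removals=3, seed=1,
            cov=sem_covariance(spec, maf=0.3),
        )
        assert rep.auc == 1.0

    def test_finite_sample_recovery_high(self, fitted_fixture):
        _, omics, net, cfg = fitted_fixture
        rep = variable_reduction_test(omics, net, cfg, n_removals=3, seed=1)
        assert rep.auc is not None and rep.auc >= 0.9

    def test_no_receptors_not_applicable(self):
        net = mrnet.CausalNetwork(nodes=["a", "b"], edges=[mrnet.Edge("a", "b", BIDIRECTED)])
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((200, 2)), columns=["a", "b"])
        rep = variable_reduction_test(df, net)
        assert rep.passed is None and "not applicable" in rep.details["note"]


class TestPermutation:
    def test_zero_permutations_empty_report(self, fitted_fixture):
        _, omics, net, cfg = fitted_fixture
        rep = permutation_test(omics, net, cfg, n_permutations=0)
        assert rep.passed is None and rep.auc is None

    def test_receptor_permutation_preserves_remainder(self, fitted_fixture):
        _, omics, net, cfg = fitted_fixture
        assert len(pure_receptors(net)) >= 2
        rep = permutation_test(
            omics, net, cfg, n_permutations=3, nodes_per_perm=2, role="receptors", seed=2
        )
        assert rep.auc is not None and rep.auc >= 0.9

    def test_broadcaster_permutation_destroys_their_edges(self, fitted_fixture):
        _, omics, net, cfg = fitted_fixture
        assert len(pure_broadcasters(net)) >= 2
        rep = permutation_test(
            omics, net, cfg, n_permutations=3, nodes_per_perm=2, role="broadcasters", seed=2
        )
        # remainder stays recoverable, but edges incident to the permuted
        # broadcasters collapse toward chance
        assert rep.details["incident_auc"] is not None
        assert rep.details["incident_auc"] <= 0.7

    def test_infeasible_group_reports_largest(self, fitted_fixture):
        _, omics, net, cfg = fitted_fixture
        rep = permutation_test(omics, net, cfg, n_permutations=2, nodes_per_perm=50)
        assert rep.passed is None
        assert rep.details["largest_matched_group"] < 50

    def test_bad_role_rejected(self, fitted_fixture):
        _, omics, net, cfg = fitted_fixture
        with pytest.raises(QueryError):
            permutation_test(omics, net, cfg, role="hubs")
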