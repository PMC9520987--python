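"""Reproducibility studies: the package's headline property checks.

Each function here sets up a simulation study with the package's reference
conditions (documented in docs/methods.md), runs the relevant estimator or
learner from scratch, and returns the measured quantities. They back both the
acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from itertools import combinations, product

import networkx as nx
import numpy as np
import pandas as pd

from .analysis import outcome_integration
from .classical import first_stage_predict, multivariable_mr, two_step_mediation, wald_ratio
from .instruments import pleiotropy_test
from .network import (
    CausalNetwork,
    Edge,
    LearnerConfig,
    fit_network,
    hamming_distance,
    learn_skeleton,
    learn_skeleton_from_covariance,
    orient_edges_from_covariance,
    select_tuning_parameter,
    true_network,
)
from .stability import (
    AdjustmentQuery,
    backdoor_adjustment_sets,
    confounding_equivalence_test,
    variable_increment_test,
    variable_reduction_test,
)
from .synthetic import (
    SemSpec,
    TraitSpec,
    attach_instruments,
    inject_pleiotropy,
    joint_covariance,
    make_two_sample,
    sample_random_dag,
    sem_covariance,
    simulate_dataset,
    simulate_outcome,
    summary_for_entity,
)

MAF = 0.3  # reference minor-allele frequency for study genotypes


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def chain_spec(alpha: float = 0.5, weight: float = 0.5) -> SemSpec:
    """IV -> Mi -> Mj, the canonical pleiotropy-screen null."""
    W = np.array([[0.0, weight], [0.0, 0.0]])
    return SemSpec(
        entity_ids=["Mi", "Mj"],
        adjacency=W,
        iv_map={"Mi": (["iv_Mi"], np.array([alpha]))},
    )


def pleiotropy_calibration(
    n: int = 2000,
    reps: int = 1000,
    alpha_level: float = 0.05,
    pleiotropy_effect: float = 0.3,
    seed: int = 0,
) -> dict:
    """Type-I error under the chain null and power against injected pleiotropy."""
    null_spec = chain_spec()
    alt_spec = inject_pleiotropy(null_spec, "iv_Mi", "Mj", pleiotropy_effect)
    seeds = _spawn(seed, 2 * reps)
    rejections = {"null": 0, "alt": 0}
    for r in range(reps):
        for key, spec, s in (("null", null_spec, seeds[r]), ("alt", alt_spec, seeds[reps + r])):
            geno, omics = simulate_dataset(spec, n, seed=s, maf=MAF)
            _, _, passed = pleiotropy_test(
                geno.column("iv_Mi"),
                omics["Mi"].to_numpy(),
                omics["Mj"].to_numpy(),
                alpha_level,
            )
            rejections[key] += not passed
    return {
        "type1_error": rejections["null"] / reps,
        "power": rejections["alt"] / reps,
        "n": n,
        "reps": reps,
    }


def mediation_identity_error(seed: int = 0, reps: int = 5, n: int = 2000) -> dict:
    """Max |phi - (beta_total - tau*gamma)| over freshly fitted datasets."""
    worst = 0.0
    for s in _spawn(seed, reps):
        rng = np.random.default_rng(s)
        iv1 = rng.binomial(2, MAF, n).astype(float)
        iv2 = rng.binomial(2, MAF, n).astype(float)
        u = rng.standard_normal(n)
        x = 0.5 * iv1 + u + rng.standard_normal(n)
        m = 0.5 * x + 0.5 * iv2 + rng.standard_normal(n)
        y = 0.3 * x + 0.4 * m + u + rng.standard_normal(n)
        est = two_step_mediation(x, m, y, iv1, iv2)
        worst = max(worst, abs(est.phi - (est.beta_total - est.tau * est.gamma)))
    return {"max_identity_error": worst, "n": n, "reps": reps}


def single_iv_equivalence(reps: int = 100, n: int = 500, seed: int = 0) -> dict:
    """Max |2SLS - Wald ratio| over random single-instrument datasets."""
    worst = 0.0
    for s in _spawn(seed, reps):
        rng = np.random.default_rng(s)
        iv = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
        u = rng.standard_normal(n)
        x = rng.uniform(0.3, 1.0) * iv + u + rng.standard_normal(n)
        y = rng.uniform(-1, 1) * x + u + rng.standard_normal(n)
        fs = first_stage_predict(x, iv)
        tsls = multivariable_mr(y, [fs])[0].beta
        ivc = iv - iv.mean()
        beta_gx = float(ivc @ (x - x.mean()) / (ivc @ ivc))
        beta_gy = float(ivc @ (y - y.mean()) / (ivc @ ivc))
        wald = wald_ratio(beta_gy, 0.0, beta_gx, 0.0).beta
        worst = max(worst, abs(tsls - wald))
    return {"max_abs_difference": worst, "n": n, "reps": reps}


def two_sample_consistency(
    reps: int = 100, n1: int = 10_000, n2: int = 10_000, seed: int = 0
) -> dict:
    """Agreement of the two-sample ratio with one-sample 2SLS on a single-IV chain."""
    spec = SemSpec(
        entity_ids=["X"], adjacency=np.zeros((1, 1)), iv_map={"X": (["iv_X"], np.array([0.5]))}
    )
    trait = TraitSpec(parent_entities=["X"], effects=np.array([0.5]))
    agree = 0
    seeds = _spawn(seed, reps)
    for s in seeds:
        s1, s2 = s, s + 1
        cohort1, _, summaries = make_two_sample(spec, trait, n1, n2, (s1, s2), maf=MAF)
        row_x = summary_for_entity(summaries["exposure"], "X").iloc[0]
        row_y = summaries["outcome"].iloc[0]
        est2 = wald_ratio(row_y["beta"], row_y["se"], row_x["beta"], row_x["se"])
        # one-sample 2SLS on cohort 1 with its own outcome draw
        y1 = simulate_outcome(cohort1["omics"], trait, seed=s1 + 7)
        fs = first_stage_predict(
            cohort1["omics"]["X"].to_numpy(), cohort1["genotypes"].column("iv_X")
        )
        est1 = multivariable_mr(y1.to_numpy(), [fs])[0]
        joint_se = np.sqrt(est1.se**2 + est2.se**2)
        agree += abs(est1.beta - est2.beta) < 2.0 * joint_se
    return {"agreement_rate": agree / reps, "n": n1, "reps": reps}


# ---------------------------------------------------------------------------
# network recovery


def oracle_specs() -> list[SemSpec]:
    """Shipped fully-instrumented specs (<= 6 nodes) for the population oracle.

    All are polytrees: the pleiotropy screen conditions on the exposure alone,
    which identifies the direction exactly when no two adjacent entities share
    an ancestor-induced backdoor (always true in a polytree).
    """

    def spec_from(entities, weighted_edges):
        W = np.zeros((len(entities), len(entities)))
        idx = {e: i for i, e in enumerate(entities)}
        for s, t, w in weighted_edges:
            W[idx[s], idx[t]] = w
        return attach_instruments(SemSpec(entity_ids=entities, adjacency=W), alpha=0.6)

    chain5 = spec_from(
        [f"M{i}" for i in range(5)],
        [("M0", "M1", 0.7), ("M1", "M2", -0.6), ("M2", "M3", 0.5), ("M3", "M4", 0.8)],
    )
    fork = spec_from(["A", "B", "C"], [("A", "B", 0.6), ("A", "C", -0.7)])
    collider = spec_from(["A", "B", "C"], [("A", "C", 0.6), ("B", "C", 0.5)])
    polytree6 = spec_from(
        [f"M{i}" for i in range(6)],
        [
            ("M0", "M1", 0.7),
            ("M1", "M2", 0.6),
            ("M1", "M3", -0.5),
            ("M3", "M4", 0.6),
            ("M5", "M3", 0.8),
        ],
    )
    return [chain5, fork, collider, polytree6]


def oracle_network_recovery() -> dict:
    """Structural Hamming distance of the population-oracle fit on each shipped spec."""
    distances = []
    for spec in oracle_specs():
        cov = sem_covariance(spec, maf=MAF)
        skel = learn_skeleton_from_covariance(cov, LearnerConfig())
        iv_for = {e: ids[0] for e, (ids, _) in spec.iv_map.items()}
        net = orient_edges_from_covariance(skel, iv_for, joint_covariance(spec, MAF))
        distances.append(hamming_distance(net, true_network(spec)))
    return {"max_shd": int(max(distances)), "n": len(distances), "per_spec": distances}


def recovery_spec(seed: int, n_entities: int = 20) -> SemSpec:
    """Reference finite-sample recovery condition: sparse 20-node SEM,
    one instrument per entity."""
    spec = sample_random_dag(n_entities, 1.0, weight_range=(0.4, 0.8), seed=seed)
    return attach_instruments(spec, alpha=0.6)


def finite_sample_recovery(
    n_seeds: int = 20, n: int = 5000, n_entities: int = 20, seed: int = 0
) -> dict:
    """Median SHD/true-edge-count ratio of the full pipeline over random SEMs."""
    ratios, shds, edge_counts = [], [], []
    for s in _spawn(seed, n_seeds):
        spec = recovery_spec(s, n_entities)
        geno, omics = simulate_dataset(spec, n, seed=s + 1, maf=MAF)
        cfg = LearnerConfig(seed=s)
        # full five-step procedure incl. Hamming-distance tuning selection
        net, _, _ = fit_network(geno, omics, None, cfg, alpha_grid=[0.05, 0.01, 0.001])
        shd = hamming_distance(net, true_network(spec))
        n_true = max(len(spec.true_edges()), 1)
        ratios.append(shd / n_true)
        shds.append(shd)
        edge_counts.append(n_true)
    return {
        "median_shd_ratio": float(np.median(ratios)),
        "median_shd": float(np.median(shds)),
        "median_true_edges": float(np.median(edge_counts)),
        "n": n,
        "seeds": n_seeds,
    }


def tuning_behavior(
    seed: int = 0,
    n: int = 5000,
    grid: tuple[float, ...] = (0.1, 0.05, 0.01, 0.001),
) -> dict:
    """Hamming-distance tuning: minimizer property and skeleton monotonicity."""
    spec = attach_instruments(
        sample_random_dag(10, 1.5, weight_range=(0.5, 0.9), seed=seed), alpha=0.6
    )
    _, omics = simulate_dataset(spec, n, seed=seed + 1, maf=MAF)
    cfg = LearnerConfig(seed=seed, subsamples=10)
    chosen, table = select_tuning_parameter(omics, list(grid), cfg)
    chosen_dist = float(table.loc[table["alpha"] == chosen, "mean_hamming"].iloc[0])
    minimal = bool((chosen_dist <= table["mean_hamming"] + 1e-12).all())
    edge_counts = [
        len(learn_skeleton(omics, LearnerConfig(tuning_alpha=a, seed=seed)).edges)
        for a in sorted(grid, reverse=True)
    ]
    monotone = bool(all(a >= b for a, b in zip(edge_counts, edge_counts[1:])))
    return {
        "chosen_alpha": chosen,
        "chosen_is_minimal": minimal,
        "monotone_nonincreasing": monotone,
        "edge_counts_by_decreasing_alpha": edge_counts,
        "table": table.to_dict(orient="records"),
        "n": n,
    }


# ---------------------------------------------------------------------------
# stability diagnostics


def equivalence_study_spec() -> tuple[SemSpec, CausalNetwork]:
    """Five-entity network with two equivalent adjustment sets for X -> Y.

    Structure: Z -> X, Z -> Y, E -> X, E -> F, F -> Y, X -> Y. The backdoor
    paths X <- Z -> Y and X <- E -> F -> Y are blocked by {E, Z} or {F, Z}.
    """
    entities = ["E", "F", "X", "Y", "Z"]
    edges = [
        ("Z", "X", 0.6),
        ("Z", "Y", 0.6),
        ("E", "X", 0.6),
        ("E", "F", 0.6),
        ("F", "Y", 0.6),
        ("X", "Y", 0.5),
    ]
    W = np.zeros((5, 5))
    idx = {e: i for i, e in enumerate(entities)}
    for s, t, w in edges:
        W[idx[s], idx[t]] = w
    spec = SemSpec(entity_ids=entities, adjacency=W)
    net = CausalNetwork(
        nodes=entities, edges=[Edge(s, t, effect=w) for s, t, w in edges]
    )
    return spec, net


def ztest_calibration(
    reps: int = 500,
    violation_reps: int = 200,
    n: int = 5000,
    level: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Empirical size and violation-rejection rate of both Z-test diagnostics.

    Size: data drawn from the five-entity equivalence structure with the
    correct network. Violations: the confounding-equivalence test is fed a
    second set omitting the confounder Z; the variable-increment test is fed a
    T that is a direct cause of Y correlated with X given Z.
    """
    spec, _ = equivalence_study_spec()
    seeds = _spawn(seed, 2 * reps + 2 * violation_reps)
    it = iter(seeds)

    ce_query = AdjustmentQuery("X", "Y", sets=[{"E", "Z"}, {"F", "Z"}])
    ce_bad = AdjustmentQuery("X", "Y", sets=[{"E", "Z"}, {"E"}])
    ce_rej = 0
    ce_bad_rej = 0
    for r in range(reps):
        omics = _sim_entities(spec, n, next(it))
        rep = confounding_equivalence_test(omics, ce_query, level, n_boot=n_boot, seed=r)
        ce_rej += not rep.passed
    for r in range(violation_reps):
        omics = _sim_entities(spec, n, next(it))
        rep = confounding_equivalence_test(omics, ce_bad, level, n_boot=n_boot, seed=r)
        ce_bad_rej += not rep.passed

    vi_rej = 0
    vi_bad_rej = 0
    for r in range(reps):
        df = _increment_data(n, next(it), violation=False)
        q = AdjustmentQuery("X", "Y", sets=[{"Z"}], extra="T")
        rep = variable_increment_test(df, q, level, n_boot=n_boot, seed=r)
        vi_rej += not rep.passed
    for r in range(violation_reps):
        df = _increment_data(n, next(it), violation=True)
        q = AdjustmentQuery("X", "Y", sets=[{"Z"}], extra="T")
        rep = variable_increment_test(df, q, level, n_boot=n_boot, seed=r)
        vi_bad_rej += not rep.passed

    return {
        "confounding_equivalence_size": ce_rej / reps,
        "confounding_equivalence_violation_rate": ce_bad_rej / violation_reps,
        "variable_increment_size": vi_rej / reps,
        "variable_increment_violation_rate": vi_bad_rej / violation_reps,
        "n": n,
        "reps": reps,
    }


def _sim_entities(spec: SemSpec, n: int, seed: int) -> pd.DataFrame:
    from .synthetic import simulate_sem

    return simulate_sem(spec, None, seed=seed, n_samples=n)


def _increment_data(n: int, seed: int, violation: bool) -> pd.DataFrame:
    """Confounded X -> Y with an extra variable T.

    Null: T is a child of X, so Y _|_ T | (X, Z). Violation: T additionally
    causes Y directly, so adjusting for it moves the X coefficient.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    x = 0.6 * z + rng.standard_normal(n)
    t = 0.6 * x + rng.standard_normal(n)
    y = 0.6 * x + 0.6 * z + rng.standard_normal(n)
    if violation:
        y = y + 0.5 * t
    return pd.DataFrame({"X": x, "Y": y, "Z": z, "T": t})


def stability_fixture_spec() -> SemSpec:
    """Deterministic 20-node study network with clear broadcasters and receptors.

    Two degree-matched broadcasters (two children each) feed parallel chains
    ending in pure receptors, plus two separate three-node chains — so both
    the reduction test (>= 3 receptors) and the degree-matched permutation
    test (two exchangeable broadcasters, six exchangeable receptors) apply.
    """
    entities = (
        ["B0", "B1"]
        + [f"C{i}" for i in range(4)]
        + [f"E{i}" for i in range(4)]
        + [f"R{i}" for i in range(4)]
        + ["G0", "G1", "G2", "H0", "H1", "H2"]
    )
    edges = []
    for c in ["C0", "C1"]:
        edges.append(("B0", c, 0.7))
    for c in ["C2", "C3"]:
        edges.append(("B1", c, 0.7))
    for i in range(4):
        edges.append((f"C{i}", f"E{i}", 0.6))
        edges.append((f"E{i}", f"R{i}", 0.6))
    edges += [("G0", "G1", 0.7), ("G1", "G2", 0.6)]
    edges += [("H0", "H1", 0.7), ("H1", "H2", 0.6)]
    W = np.zeros((len(entities), len(entities)))
    idx = {e: i for i, e in enumerate(entities)}
    for s, t, w in edges:
        W[idx[s], idx[t]] = w
    return attach_instruments(SemSpec(entity_ids=entities, adjacency=W), alpha=0.6)


def reduction_study(n: int = 5000, seed: int = 0, n_removals: int = 3) -> dict:
    """Variable-reduction AUCs: population oracle, finite sample, and the
    broadcaster-removal negative control."""
    spec = stability_fixture_spec()
    geno, omics = simulate_dataset(spec, n, seed=seed, maf=MAF)
    cfg = LearnerConfig(tuning_alpha=0.01, seed=seed, subsamples=10)
    net, _, _ = fit_network(geno, omics, None, cfg)
    cov = sem_covariance(spec, maf=MAF)
    oracle_net = true_network(spec)
    r_oracle = variable_reduction_test(
        omics, oracle_net, cfg, n_removals=n_removals, seed=seed, cov=cov
    )
    r_data = variable_reduction_test(omics, net, cfg, n_removals=n_removals, seed=seed)
    r_neg = variable_reduction_test(
        omics, net, cfg, n_removals=2, seed=seed, role="broadcasters"
    )
    return {
        "oracle_auc": r_oracle.auc,
        "finite_sample_auc": r_data.auc,
        "broadcaster_control_auc": r_neg.auc,
        "n": n,
    }


def outcome_integration_recovery(
    n_seeds: int = 20,
    n: int = 5000,
    n_entities: int = 30,
    n_parents: int = 9,
    seed: int = 0,
) -> dict:
    """Direct-parent recovery of a trait built from 9 of 30 entities."""
    recovered, spurious_orient = [], 0
    for s in _spawn(seed, n_seeds):
        spec = attach_instruments(
            sample_random_dag(n_entities, 1.0, weight_range=(0.4, 0.8), seed=s), alpha=0.6
        )
        geno, omics = simulate_dataset(spec, n, seed=s + 1, maf=MAF)
        rng = np.random.default_rng(s + 2)
        parents = sorted(rng.choice(spec.entity_ids, size=n_parents, replace=False).tolist())
        effects = rng.choice((-0.4, 0.4), size=n_parents)
        trait = TraitSpec(parent_entities=parents, effects=effects)
        tvals = simulate_outcome(omics, trait, seed=s + 3)
        cfg = LearnerConfig(tuning_alpha=0.01, seed=s)
        net, ivs, _ = fit_network(geno, omics, None, cfg)
        table, report = outcome_integration(net, omics, tvals, ivs, cfg)
        recovered.append(len(set(table["entity"]) & set(parents)))
        spurious_orient += report["trait_outgoing_edges"]
    return {
        "median_recovered": float(np.median(recovered)),
        "n_parents": n_parents,
        "trait_outgoing_edges": spurious_orient,
        "n": n,
        "seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# backdoor enumeration


def _all_dag_patterns(n: int):
    """All DAGs on n nodes in canonical (upper-triangular) labeling."""
    slots = list(combinations(range(n), 2))
    for bits in product((0, 1), repeat=len(slots)):
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        g.add_edges_from(s for s, b in zip(slots, bits) if b)
        yield g


def _oracle_backdoor(dag: nx.DiGraph, x, y, S: set) -> bool:
    """Independent check: no descendant of x in S, and S d-separates x from y
    in the graph with x's outgoing edges removed."""
    if S & (nx.descendants(dag, x) | {x}):
        return False
    g = dag.copy()
    g.remove_edges_from(list(g.out_edges(x)))
    return nx.is_d_separator(g, {x}, {y}, S)


def backdoor_exhaustive(max_nodes: int = 5, max_size: int = 3) -> dict:
    """Compare backdoor enumeration with the d-separation oracle on all DAGs.

    Every DAG is isomorphic to an upper-triangular pattern, and both the
    enumeration and the oracle are label-equivariant, so sweeping all patterns
    and all ordered (x, y) query pairs covers all DAGs up to ``max_nodes``.
    """
    mismatches = 0
    n_dags = 0
    n_queries = 0
    for n in range(2, max_nodes + 1):
        for dag in _all_dag_patterns(n):
            n_dags += 1
            nodes = list(dag.nodes)
            net = CausalNetwork(
                nodes=[str(v) for v in nodes],
                edges=[Edge(str(a), str(b)) for a, b in dag.edges],
            )
            pairs = [(x, y) for x in nodes for y in nodes if x != y]
            for x, y in pairs:
                n_queries += 1
                mine = {
                    frozenset(s)
                    for s in backdoor_adjustment_sets(net, str(x), str(y), max_size)
                }
                candidates = [v for v in nodes if v not in (x, y)]
                oracle = set()
                for size in range(max_size + 1):
                    for S in combinations(candidates, size):
                        if _oracle_backdoor(dag, x, y, set(S)):
                            oracle.add(frozenset(str(v) for v in S))
                mismatches += mine != oracle
    return {"mismatched_queries": mismatches, "n_dags": n_dags, "n_queries": n_queries}
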