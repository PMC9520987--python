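"""Post-identification stability diagnostics for a fitted causal network.

Four tests probe whether the instrument/network assumptions held:

* **Confounding-equivalence** — two adjustment sets S1, S2 that the network
  declares equivalent for the effect of X on Y must give the same adjusted
  effect; under the linear-Gaussian model the stratum-sum adjustment reduces
  to the X coefficient in the regression of Y on (X, S), so the test is a
  Z-test on the difference of the two X coefficients.
* **Variable-increment** — adding a variable T outside the confounder set Z
  must not move the X coefficient: beta_1 = beta'_1 between
  y ~ x + Z and y ~ x + Z + T, again a Z-test.
* **Variable-reduction** — dropping pure receptors (arrows in, none out)
  leaves the joint distribution of the remaining variables unchanged, so
  re-learning on the subset should reproduce the original edges; scored by
  ROC AUC with subsample edge frequency as the score.
* **Permutation** — permuting data columns within a degree-matched group of
  receptors (or broadcasters) and re-learning should leave the unpermuted
  remainder's edges recoverable; scored by ROC AUC.

Both Z-tests account for the shared sample by a seeded paired bootstrap
(default) or a closed-form influence-function covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._stats import add_intercept
from .errors import AmbiguityError, CollinearityError, DataError, QueryError
from .network import (
    DIRECTED,
    CausalNetwork,
    LearnerConfig,
    edge_confidence,
    learn_skeleton_from_covariance,
)

__all__ = [
    "AdjustmentQuery",
    "StabilityReport",
    "backdoor_adjustment_sets",
    "confounding_equivalence_test",
    "variable_increment_test",
    "variable_reduction_test",
    "permutation_test",
    "pure_receptors",
    "pure_broadcasters",
]


@dataclass
class AdjustmentQuery:
    """An exposure/outcome pair with candidate adjustment sets and optional extra."""

    exposure: str
    outcome: str
    sets: list[set] = field(default_factory=list)
    extra: str | None = None

    def __post_init__(self):
        if self.exposure == self.outcome:
            raise QueryError("exposure and outcome must differ")
        self.sets = [set(s) for s in self.sets]
        for s in self.sets:
            if self.exposure in s or self.outcome in s:
                raise QueryError("exposure/outcome may not appear in an adjustment set")
        if self.extra is not None and self.extra in {self.exposure, self.outcome}:
            raise QueryError("extra variable may not be the exposure or outcome")


@dataclass
class StabilityReport:
    test: str
    statistic: float | None = None
    p_value: float | None = None
    auc: float | None = None
    passed: bool | None = None
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# backdoor machinery


def _undirected_paths(g: nx.Graph, x: str, y: str):
    return nx.all_simple_paths(g, x, y)


def backdoor_adjustment_sets(
    network: CausalNetwork, x: str, y: str, max_size: int = 3
) -> list[frozenset]:
    """All adjustment sets up to ``max_size`` satisfying the backdoor criterion.

    A set S qualifies when it contains no descendant of x and blocks every
    path from x to y that starts with an arrow into x. Paths are enumerated
    exhaustively (intended for the small graphs this package fits). Any
    undirected or bidirected edge lying on a simple path between x and y
    raises an ambiguity error: the caller must resolve or exclude it.
    """
    if x not in network.nodes or y not in network.nodes:
        raise QueryError(f"{x!r} or {y!r} not in the network")
    skel = network.skeleton_graph()
    unresolved = {
        e.pair() for e in network.edges if e.kind != DIRECTED
    }
    if unresolved and skel.has_node(x):
        for path in _undirected_paths(skel, x, y):
            for a, b in zip(path, path[1:]):
                if frozenset((a, b)) in unresolved:
                    raise AmbiguityError(
                        f"unresolved edge {a}-{b} lies on a path between {x} and {y}; "
                        "resolve its direction or exclude these nodes"
                    )
    dag = network.directed_graph()
    desc_x = nx.descendants(dag, x) | {x}
    backdoor_paths = []
    for path in _undirected_paths(nx.Graph(dag.to_undirected()), x, y):
        if len(path) >= 2 and dag.has_edge(path[1], path[0]):
            backdoor_paths.append(path)
    candidates = sorted(set(network.nodes) - desc_x - {y})
    descendants = {v: nx.descendants(dag, v) | {v} for v in dag.nodes}

    def blocked(path, S):
        for a, b, c in zip(path, path[1:], path[2:]):
            collider = dag.has_edge(a, b) and dag.has_edge(c, b)
            if collider:
                if not (descendants[b] & S):
                    return True
            elif b in S:
                return True
        return False  # no blocking node found (incl. the direct x <- y path)

    def admissible(S):
        return all(blocked(p, S) for p in backdoor_paths)

    out = []
    for size in range(max_size + 1):
        for S in combinations(candidates, size):
            if admissible(set(S)):
                out.append(frozenset(S))
    return out


# ---------------------------------------------------------------------------
# Z-test diagnostics


def _coef_of_x(y: np.ndarray, x: np.ndarray, Z: np.ndarray | None):
    n = y.size
    cols = [x] if Z is None or Z.size == 0 else [x, *Z.T]
    D = add_intercept(np.column_stack(cols), n)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise CollinearityError(["adjustment design"], "adjusted regression")
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    return float(coef[1]), D, coef


def _paired_bootstrap_se(y, x, Z1, Z2, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    n = y.size
    D1 = add_intercept(np.column_stack([x] if Z1 is None else [x, *Z1.T]), n)
    D2 = add_intercept(np.column_stack([x] if Z2 is None else [x, *Z2.T]), n)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        A1, A2 = D1[idx], D2[idx]
        c1 = np.linalg.solve(A1.T @ A1, A1.T @ yb)
        c2 = np.linalg.solve(A2.T @ A2, A2.T @ yb)
        diffs[b] = c1[1] - c2[1]
    return float(diffs.std(ddof=1))


def _influence_se(y, x, Z1, Z2) -> float:
    """Closed-form se of the coefficient difference via influence functions."""

    def psi(Zmat):
        _, D, coef = _coef_of_x(y, x, Zmat)
        n = y.size
        A = np.linalg.inv(D.T @ D / n)
        resid = y - D @ coef
        return (D @ A[:, 1]) * resid

    p1, p2 = psi(Z1), psi(Z2)
    d = p1 - p2
    return float(d.std(ddof=1) / np.sqrt(y.size))


def _cols(data: pd.DataFrame, names) -> np.ndarray | None:
    names = sorted(names)
    if not names:
        return None
    return data[names].to_numpy(dtype=float)


def _ztest_report(test, diff, se, level, details) -> StabilityReport:
    if se == 0:
        z, p = 0.0, 1.0
    else:
        z = diff / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    details.update({"difference": diff, "se": se})
    return StabilityReport(
        test=test, statistic=float(z), p_value=p, passed=p >= level, details=details
    )


def confounding_equivalence_test(
    data: pd.DataFrame,
    query: AdjustmentQuery,
    level: float = 0.05,
    method: str = "bootstrap",
    n_boot: int = 500,
    seed: int = 0,
) -> StabilityReport:
    """Z-test that adjusting for S1 or S2 yields the same effect of X on Y.

    The adjusted effect is the X coefficient in Y ~ X + S; the covariance of
    the two estimates (shared sample) comes from a seeded paired bootstrap or
    the influence-function closed form (``method="closed_form"``).
    """
    if len(query.sets) < 2:
        raise QueryError("confounding-equivalence needs two candidate sets")
    S1, S2 = query.sets[0], query.sets[1]
    y = data[query.outcome].to_numpy(dtype=float)
    x = data[query.exposure].to_numpy(dtype=float)
    Z1, Z2 = _cols(data, S1), _cols(data, S2)
    b1, _, _ = _coef_of_x(y, x, Z1)
    b2, _, _ = _coef_of_x(y, x, Z2)
    details = {"beta_s1": b1, "beta_s2": b2, "s1": sorted(S1), "s2": sorted(S2)}
    if S1 == S2:
        return StabilityReport(
            test="confounding_equivalence",
            statistic=0.0,
            p_value=1.0,
            passed=True,
            details=details,
        )
    if method == "bootstrap":
        se = _paired_bootstrap_se(y, x, Z1, Z2, n_boot, seed)
    elif method == "closed_form":
        se = _influence_se(y, x, Z1, Z2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _ztest_report("confounding_equivalence", b1 - b2, se, level, details)


def variable_increment_test(
    data: pd.DataFrame,
    query: AdjustmentQuery,
    level: float = 0.05,
    method: str = "bootstrap",
    n_boot: int = 500,
    seed: int = 0,
) -> StabilityReport:
    """Z-test that adding T beyond the confounder set Z leaves beta_1 unchanged.

    Fits y = b0 + b1 x + b2 Z and y = b0' + b1' x + b2' Z + b3' T and tests
    b1 - b1' accounting for the shared sample.
    """
    if query.extra is None:
        raise QueryError("variable-increment needs an extra variable T")
    Z = query.sets[0] if query.sets else set()
    if query.extra in Z:
        raise QueryError("T must not belong to the adjustment set Z")
    y = data[query.outcome].to_numpy(dtype=float)
    x = data[query.exposure].to_numpy(dtype=float)
    Zm = _cols(data, Z)
    Zt = _cols(data, set(Z) | {query.extra})
    b1, _, _ = _coef_of_x(y, x, Zm)
    b1p, _, coef_full = _coef_of_x(y, x, Zt)
    # columns of the full design: intercept, x, then sorted(Z | {T})
    t_pos = 2 + sorted(set(Z) | {query.extra}).index(query.extra)
    details = {
        "beta1": b1,
        "beta1_prime": b1p,
        "z": sorted(Z),
        "t": query.extra,
        "beta_t": float(coef_full[t_pos]),
    }
    if method == "bootstrap":
        se = _paired_bootstrap_se(y, x, Zm, Zt, n_boot, seed)
    elif method == "closed_form":
        se = _influence_se(y, x, Zm, Zt)
    else:
        raise ValueError(f"unknown method {method!r}")
    return _ztest_report("variable_increment", b1 - b1p, se, level, details)


# ---------------------------------------------------------------------------
# ROC diagnostics


def _role_nodes(network: CausalNetwork, role: str) -> list[str]:
    dg = network.directed_graph()
    touched_unresolved = {
        v for e in network.edges if e.kind != DIRECTED for v in (e.source, e.target)
    }
    out = []
    for v in network.nodes:
        indeg, outdeg = dg.in_degree(v), dg.out_degree(v)
        if v in touched_unresolved:
            continue
        if role == "receptors" and indeg > 0 and outdeg == 0:
            out.append(v)
        elif role == "broadcasters" and indeg == 0 and outdeg > 0:
            out.append(v)
    return sorted(out)


def pure_receptors(network: CausalNetwork) -> list[str]:
    """Nodes with arrows in, none out, and no unresolved incident edges."""
    return _role_nodes(network, "receptors")


def pure_broadcasters(network: CausalNetwork) -> list[str]:
    """Nodes with arrows out, none in, and no unresolved incident edges."""
    return _role_nodes(network, "broadcasters")


def _edge_labels(network: CausalNetwork, nodes: list[str]) -> dict[frozenset, int]:
    present = {e.pair() for e in network.edges}
    return {
        frozenset((a, b)): int(frozenset((a, b)) in present)
        for a, b in combinations(sorted(nodes), 2)
    }


def _score_recovery(
    data: pd.DataFrame,
    nodes: list[str],
    learner: LearnerConfig,
    cov: pd.DataFrame | None,
) -> dict[frozenset, float]:
    if cov is not None:
        net = learn_skeleton_from_covariance(cov.loc[nodes, nodes], learner, n=None)
        return {e.pair(): 1.0 for e in net.edges}
    return edge_confidence(data[nodes], learner)


def _auc(labels: list[int], scores: list[float]) -> float | None:
    if len(set(labels)) < 2:
        return None
    return float(roc_auc_score(labels, scores))


def variable_reduction_test(
    data: pd.DataFrame,
    network: CausalNetwork,
    learner: LearnerConfig | None = None,
    n_removals: int = 3,
    seed: int = 0,
    floor: float = 0.8,
    cov: pd.DataFrame | None = None,
    role: str = "receptors",
) -> StabilityReport:
    """Remove pure receptors, re-learn, and score edge recovery by ROC AUC.

    For k = 1..n_removals, k randomly chosen pure receptors are dropped, the
    skeleton is re-learned on the remaining columns, and every remaining node
    pair is scored by subsample edge frequency against the original network's
    edges as labels (pooled over k). With ``cov`` (population covariance over
    all entities) the re-learn runs against exact partial correlations.

    ``role="broadcasters"`` runs the negative control: dropping a common
    cause confounds its children, so recovery should degrade.
    """
    learner = learner or LearnerConfig()
    receptors = _role_nodes(network, role)
    if not receptors:
        return StabilityReport(
            test="variable_reduction",
            details={"note": f"not applicable: no pure {role}"},
        )
    n_removals = min(n_removals, len(receptors))
    rng = np.random.default_rng(seed)
    labels: list[int] = []
    scores: list[float] = []
    removed_log = []
    for k in range(1, n_removals + 1):
        drop = sorted(rng.choice(receptors, size=k, replace=False).tolist())
        removed_log.append(drop)
        keep = [v for v in network.nodes if v not in drop]
        conf = _score_recovery(data, keep, learner, cov)
        lab = _edge_labels(network, keep)
        for pair, y in lab.items():
            labels.append(y)
            scores.append(conf.get(pair, 0.0))
    auc = _auc(labels, scores)
    return StabilityReport(
        test="variable_reduction",
        auc=auc,
        passed=None if auc is None else auc >= floor,
        details={"removed": removed_log, "n_pairs": len(labels), "floor": floor, "role": role},
    )


def permutation_test(
    data: pd.DataFrame,
    network: CausalNetwork,
    learner: LearnerConfig | None = None,
    n_permutations: int = 5,
    nodes_per_perm: int = 2,
    role: str = "receptors",
    seed: int = 0,
    floor: float = 0.8,
    cov: pd.DataFrame | None = None,
) -> StabilityReport:
    """Permute a degree-matched group of receptors or broadcasters and re-learn.

    Groups are drawn without replacement inside exact (in-degree, out-degree)
    classes of the requested role; the data columns of the chosen nodes are
    permuted among themselves, the skeleton re-learned, and the unpermuted
    remainder's edges scored by ROC AUC against the original network. If no
    class holds ``nodes_per_perm`` nodes the test reports not-applicable.
    """
    learner = learner or LearnerConfig()
    if role not in ("receptors", "broadcasters"):
        raise QueryError("role must be 'receptors' or 'broadcasters'")
    if n_permutations == 0:
        return StabilityReport(test="permutation", details={"note": "no permutations"})
    nodes = _role_nodes(network, role)
    dg = network.directed_graph()
    classes: dict[tuple[int, int], list[str]] = {}
    for v in nodes:
        classes.setdefault((dg.in_degree(v), dg.out_degree(v)), []).append(v)
    feasible = {k: v for k, v in classes.items() if len(v) >= nodes_per_perm}
    if not feasible:
        largest = max((len(v) for v in classes.values()), default=0)
        return StabilityReport(
            test="permutation",
            details={
                "note": "not applicable: no degree-matched group is large enough",
                "largest_matched_group": largest,
                "requested": nodes_per_perm,
            },
        )
    rng = np.random.default_rng(seed)
    keys = sorted(feasible)
    aucs = []
    incident_aucs = []
    groups_used = []
    for _ in range(n_permutations):
        key = keys[rng.integers(0, len(keys))]
        group = sorted(rng.choice(feasible[key], size=nodes_per_perm, replace=False).tolist())
        groups_used.append(group)
        permuted = data.copy()
        perm = rng.permutation(nodes_per_perm)
        while nodes_per_perm > 1 and (perm == np.arange(nodes_per_perm)).all():
            perm = rng.permutation(nodes_per_perm)  # require a real permutation
        permuted[group] = data[[group[i] for i in perm]].to_numpy()
        remainder = [v for v in network.nodes if v not in group]
        conf = _score_recovery(permuted, remainder, learner, None)
        lab = _edge_labels(network, remainder)
        auc = _auc(list(lab.values()), [conf.get(p, 0.0) for p in lab])
        if auc is not None:
            aucs.append(auc)
        # secondary readout: recovery of edges incident to the permuted nodes
        conf_all = _score_recovery(permuted, list(network.nodes), learner, None)
        lab_all = _edge_labels(network, list(network.nodes))
        inc = {p: v for p, v in lab_all.items() if p & set(group)}
        inc_auc = _auc(list(inc.values()), [conf_all.get(p, 0.0) for p in inc])
        if inc_auc is not None:
            incident_aucs.append(inc_auc)
    mean_auc = float(np.mean(aucs)) if aucs else None
    return StabilityReport(
        test="permutation",
        auc=mean_auc,
        passed=None if mean_auc is None else mean_auc >= floor,
        details={
            "groups": groups_used,
            "role": role,
            "floor": floor,
            "incident_auc": float(np.mean(incident_aucs)) if incident_aucs else None,
        },
    )
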