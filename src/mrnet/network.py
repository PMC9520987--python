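"""MR-constrained causal-network identification.

The pipeline follows five steps: (1) adjust the omics matrix for covariates;
(2) build and assign genetic instruments; (3) learn an undirected skeleton
from conditional-independence tests (a PC-stable constraint learner with
Fisher-z Gaussian tests); (4) orient each skeleton edge Mi - Mj with the
instruments: Mi -> Mj is supported when Mi's instrument is marginally
associated with Mj *and* passes the pleiotropy screen Mj _|_ IV | Mi (its
effect on Mj is fully mediated by Mi); (5) annotate directed edges with
causal effect sizes.

Edges where neither endpoint has a valid instrument stay *bidirected* (the
direction is unidentifiable without an instrument); instrumented but
inconclusive edges stay undirected. The conditional-independence level (the
learner's tuning parameter) can be chosen by minimizing the average Hamming
distance between networks learned on subsamples, which keeps only robust
connections.

Every learner here is deterministic given its inputs and seed, and each
conditional-independence test can be run against an exact population
covariance instead of data, which turns the learner into its own asymptotic
oracle for testing.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import fisher_z_pvalue, partial_correlation, residualize
from .errors import (
    CollinearityError,
    ComparisonError,
    DataError,
    ParameterError,
)
from .instruments import (
    InstrumentSet,
    PolygenicFactors,
    assign_instruments,
    build_polygenic_factors,
    pleiotropy_test,
)
from .synthetic import GenotypeMatrix

__all__ = [
    "Edge",
    "CausalNetwork",
    "LearnerConfig",
    "residualize_covariates",
    "learn_skeleton",
    "learn_skeleton_from_covariance",
    "orient_edges",
    "orient_edges_from_covariance",
    "hamming_distance",
    "select_tuning_parameter",
    "estimate_edge_effects",
    "fit_network",
]

logger = logging.getLogger(__name__)

_POP_TOL = 1e-8  # a population partial correlation below this is an exact zero

DIRECTED = "directed"
UNDIRECTED = "undirected"
BIDIRECTED = "bidirected"


@dataclass
class Edge:
    source: str
    target: str
    kind: str = DIRECTED
    effect: float | None = None
    confidence: float | None = None

    def pair(self) -> frozenset:
        return frozenset((self.source, self.target))


@dataclass
class CausalNetwork:
    """Mixed graph over entities: directed, undirected and bidirected edges."""

    nodes: list[str]
    edges: list[Edge] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        known = set(self.nodes)
        pairs = set()
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise DataError(f"edge {e.source}->{e.target} references unknown node")
            if e.kind not in (DIRECTED, UNDIRECTED, BIDIRECTED):
                raise DataError(f"unknown edge kind {e.kind!r}")
            if e.kind != DIRECTED and e.effect is not None:
                raise DataError("only directed edges may carry an effect")
            pr = e.pair()
            if pr in pairs:
                raise DataError(f"pair {set(pr)} appears in more than one edge")
            pairs.add(pr)
        dg = self.directed_graph()
        if not nx.is_directed_acyclic_graph(dg):
            raise DataError("directed subgraph contains a cycle")

    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.kind == DIRECTED:
                g.add_edge(e.source, e.target, effect=e.effect, confidence=e.confidence)
        return g

    def skeleton_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            w = abs(e.effect) if e.effect is not None else 1.0
            g.add_edge(e.source, e.target, weight=w, kind=e.kind)
        return g

    def edges_of_kind(self, kind: str) -> list[Edge]:
        return [e for e in self.edges if e.kind == kind]

    def find_edge(self, a: str, b: str) -> Edge | None:
        pr = frozenset((a, b))
        for e in self.edges:
            if e.pair() == pr:
                return e
        return None

    def copy(self) -> "CausalNetwork":
        return copy.deepcopy(self)

    def edge_counts(self) -> dict[str, int]:
        return {k: len(self.edges_of_kind(k)) for k in (DIRECTED, UNDIRECTED, BIDIRECTED)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.source,
                    "target": e.target,
                    "kind": e.kind,
                    "effect": e.effect,
                    "confidence": e.confidence,
                }
                for e in self.edges
            ],
            columns=["source", "target", "kind", "effect", "confidence"],
        )


@dataclass
class LearnerConfig:
    """Knobs of the constraint learner.

    ``tuning_alpha`` is the conditional-independence significance level (the
    network's tuning parameter); ``orient_alpha`` the level of the marginal
    and pleiotropy tests used for orientation; ``subsamples`` and
    ``subsample_fraction`` drive Hamming-distance tuning and edge confidence.
    """

    tuning_alpha: float = 0.01
    max_conditioning: int = 3
    subsamples: int = 10
    subsample_fraction: float = 0.7
    seed: int = 0
    orient_alpha: float = 0.05
    strength_threshold: float = 10.0

    def __post_init__(self):
        if not (0.0 < self.tuning_alpha < 1.0):
            raise ParameterError("tuning_alpha must lie in (0, 1)")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ParameterError("subsample_fraction must lie in (0, 1]")
        if self.max_conditioning < 0:
            raise ParameterError("max_conditioning must be non-negative")


def residualize_covariates(
    omics: pd.DataFrame, covariates: pd.DataFrame | np.ndarray | None
) -> pd.DataFrame:
    """Replace each entity by its residual on the covariates plus an intercept.

    With no covariates this centers the columns. Residualizing twice equals
    residualizing once (projection).
    """
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.size == 0:
            cov = None
        elif cov.ndim == 1:
            cov = cov.reshape(-1, 1)
    try:
        R = residualize(omics.to_numpy(dtype=float), cov)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(
            ["covariates"], "covariate residualization"
        ) from exc
    return pd.DataFrame(R, index=omics.index, columns=omics.columns)


class _GaussCI:
    """Gaussian conditional-independence tests from a covariance matrix.

    With finite ``n`` the Fisher-z test is used; with ``n=None`` the
    covariance is treated as the population truth and a test "passes"
    (p-value 1) exactly when the partial correlation vanishes numerically.
    """

    def __init__(self, cov: np.ndarray, ids: list[str], n: int | None):
        self.cov = np.asarray(cov, dtype=float)
        self.ids = list(ids)
        self.index = {v: i for i, v in enumerate(self.ids)}
        self.n = n

    @classmethod
    def from_data(cls, data: pd.DataFrame) -> "_GaussCI":
        X = data.to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise DataError("data contain non-finite values")
        return cls(np.cov(X, rowvar=False), list(data.columns), len(data))

    def pcorr(self, i: str, j: str, cond: tuple[str, ...]) -> float:
        idx = tuple(self.index[c] for c in cond)
        return partial_correlation(self.cov, self.index[i], self.index[j], idx)

    def pvalue(self, i: str, j: str, cond: tuple[str, ...]) -> float:
        r = self.pcorr(i, j, cond)
        if self.n is None:
            return 1.0 if abs(r) < _POP_TOL else 0.0
        return fisher_z_pvalue(r, self.n, len(cond))


def _pc_skeleton(ci: _GaussCI, entities: list[str], config: LearnerConfig) -> CausalNetwork:
    """PC-stable skeleton: frozen neighborhoods per level, lexicographic sets."""
    adj: dict[str, set[str]] = {v: set(entities) - {v} for v in entities}
    sepsets: dict[frozenset, tuple[str, ...]] = {}
    alpha = config.tuning_alpha
    for level in range(config.max_conditioning + 1):
        frozen = {v: sorted(adj[v]) for v in entities}
        if all(len(frozen[v]) - 1 < level for v in entities):
            break
        for i in entities:
            for j in sorted(adj[i]):
                if j <= i or j not in adj[i]:
                    continue
                removed = False
                for base in (i, j):
                    other = j if base == i else i
                    neigh = [v for v in frozen[base] if v != other]
                    if len(neigh) < level:
                        continue
                    for S in combinations(neigh, level):
                        if ci.pvalue(i, j, S) >= alpha:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            sepsets[frozenset((i, j))] = S
                            removed = True
                            break
                    if removed:
                        break
    edges = [
        Edge(i, j, UNDIRECTED)
        for i in entities
        for j in sorted(adj[i])
        if i < j
    ]
    return CausalNetwork(
        nodes=list(entities),
        edges=edges,
        meta={"separating_sets": sepsets, "tuning_alpha": alpha},
    )


def learn_skeleton(omics: pd.DataFrame, config: LearnerConfig | None = None) -> CausalNetwork:
    """Constraint-based undirected skeleton of the omics entities."""
    config = config or LearnerConfig()
    ci = _GaussCI.from_data(omics)
    return _pc_skeleton(ci, list(omics.columns), config)


def learn_skeleton_from_covariance(
    cov: pd.DataFrame, config: LearnerConfig | None = None, n: int | None = None
) -> CausalNetwork:
    """Skeleton from a covariance matrix; ``n=None`` means population truth."""
    config = config or LearnerConfig()
    ci = _GaussCI(cov.to_numpy(dtype=float), list(cov.columns), n)
    return _pc_skeleton(ci, list(cov.columns), config)


def _resolve_orientations(
    skeleton: CausalNetwork, proposals: list[Edge], fallbacks: dict[frozenset, Edge]
) -> CausalNetwork:
    """Apply directed proposals in decreasing confidence, rejecting cycles."""
    dg = nx.DiGraph()
    dg.add_nodes_from(skeleton.nodes)
    accepted: list[Edge] = []
    order = sorted(
        proposals, key=lambda e: (-(e.confidence or 0.0), e.source, e.target)
    )
    for e in order:
        if dg.has_node(e.target) and nx.has_path(dg, e.target, e.source):
            logger.warning(
                "orientation %s->%s closes a directed cycle; reverted", e.source, e.target
            )
            accepted.append(fallbacks[e.pair()])
            continue
        dg.add_edge(e.source, e.target)
        accepted.append(e)
    return accepted


def _decide_direction(support_ij, support_ji, conf_ij, conf_ji, has_iv_i, has_iv_j, i, j):
    """Shared orientation logic. Returns an Edge (direction or fallback kind)."""
    if support_ij and support_ji:
        logger.warning("conflicting orientations for %s-%s; kept bidirected", i, j)
        return Edge(i, j, BIDIRECTED)
    if support_ij:
        return Edge(i, j, DIRECTED, confidence=conf_ij)
    if support_ji:
        return Edge(j, i, DIRECTED, confidence=conf_ji)
    if not has_iv_i and not has_iv_j:
        return Edge(i, j, BIDIRECTED)
    return Edge(i, j, UNDIRECTED)


def orient_edges(
    skeleton: CausalNetwork,
    instruments: InstrumentSet,
    omics: pd.DataFrame,
    iv_values: pd.DataFrame,
    config: LearnerConfig | None = None,
) -> CausalNetwork:
    """Orient skeleton edges with the instruments' pleiotropy screen.

    For edge Mi - Mj and Mi's strongest valid instrument: Mi -> Mj is
    supported when the instrument is marginally associated with Mj and the
    conditional-independence property Mj _|_ IV | Mi passes. Conflicting
    support on both sides yields a bidirected edge; no instrument on either
    side yields a bidirected edge (direction unidentifiable); an instrumented
    but inconclusive edge stays undirected. Directed orientations that would
    close a cycle are reverted in increasing order of confidence.
    """
    config = config or LearnerConfig()
    alpha = config.orient_alpha
    n = len(omics)
    proposals: list[Edge] = []
    fallbacks: dict[frozenset, Edge] = {}
    resolved: list[Edge] = []

    def side_support(src: str, dst: str):
        rec = instruments.best_instrument(src, for_pair=dst)
        if rec is None or rec.instrument_id not in iv_values.columns:
            return None, 0.0, False
        iv = iv_values[rec.instrument_id].to_numpy(dtype=float)
        r = np.corrcoef(iv, omics[dst].to_numpy(dtype=float))[0, 1]
        p_marg = fisher_z_pvalue(r, n, 0)
        _, p_pleio, passed = pleiotropy_test(
            iv, omics[src].to_numpy(dtype=float), omics[dst].to_numpy(dtype=float), alpha
        )
        rec.record_pleiotropy(dst, passed)
        support = (p_marg < alpha) and passed
        confidence = min(p_pleio, 1.0 - p_marg)
        return support, confidence, True

    for e in skeleton.edges:
        i, j = sorted((e.source, e.target))
        sup_ij, conf_ij, has_i = side_support(i, j)
        sup_ji, conf_ji, has_j = side_support(j, i)
        decided = _decide_direction(
            bool(sup_ij), bool(sup_ji), conf_ij, conf_ji, has_i, has_j, i, j
        )
        if decided.kind == DIRECTED:
            proposals.append(decided)
            fallbacks[decided.pair()] = Edge(i, j, UNDIRECTED)
        else:
            resolved.append(decided)

    accepted = _resolve_orientations(skeleton, proposals, fallbacks)
    return CausalNetwork(
        nodes=list(skeleton.nodes),
        edges=resolved + accepted,
        meta=dict(skeleton.meta),
    )


def orient_edges_from_covariance(
    skeleton: CausalNetwork,
    iv_for: dict[str, str],
    joint_cov: pd.DataFrame,
    config: LearnerConfig | None = None,
    n: int | None = None,
) -> CausalNetwork:
    """Orientation against a joint (instruments + entities) covariance.

    With ``n=None`` the covariance is population truth and support is exact:
    Mi -> Mj requires Cov(IV_i, Mj) != 0 and pcor(Mj, IV_i | Mi) == 0.
    """
    config = config or LearnerConfig()
    ci = _GaussCI(joint_cov.to_numpy(dtype=float), list(joint_cov.columns), n)
    alpha = config.orient_alpha
    proposals: list[Edge] = []
    fallbacks: dict[frozenset, Edge] = {}
    resolved: list[Edge] = []

    def side_support(src: str, dst: str):
        iv = iv_for.get(src)
        if iv is None:
            return False, 0.0, False
        p_marg = ci.pvalue(iv, dst, ())
        p_pleio = ci.pvalue(dst, iv, (src,))
        support = (p_marg < alpha) and (p_pleio >= alpha)
        return support, min(p_pleio, 1.0 - p_marg), True

    for e in skeleton.edges:
        i, j = sorted((e.source, e.target))
        sup_ij, conf_ij, has_i = side_support(i, j)
        sup_ji, conf_ji, has_j = side_support(j, i)
        decided = _decide_direction(sup_ij, sup_ji, conf_ij, conf_ji, has_i, has_j, i, j)
        if decided.kind == DIRECTED:
            proposals.append(decided)
            fallbacks[decided.pair()] = Edge(i, j, UNDIRECTED)
        else:
            resolved.append(decided)

    accepted = _resolve_orientations(skeleton, proposals, fallbacks)
    return CausalNetwork(
        nodes=list(skeleton.nodes), edges=resolved + accepted, meta=dict(skeleton.meta)
    )


def true_network(spec) -> CausalNetwork:
    """The ground-truth directed network of a simulation spec."""
    return CausalNetwork(
        nodes=list(spec.entity_ids),
        edges=[Edge(s, t, DIRECTED, effect=w) for s, t, w in spec.true_edges()],
    )


def _pair_status(net: CausalNetwork) -> dict[frozenset, str]:
    out = {}
    for e in net.edges:
        if e.kind == DIRECTED:
            out[e.pair()] = f"{e.source}>{e.target}"
        else:
            out[e.pair()] = "unoriented"
    return out


def hamming_distance(g1: CausalNetwork, g2: CausalNetwork) -> int:
    """Number of node pairs whose edge status differs between two networks.

    Convention: a pair's status is one of {absent, i->j, j->i, unoriented}
    (undirected and bidirected both count as unoriented); any mismatch of
    status contributes exactly 1. Presence/absence and orientation mismatches
    therefore both cost 1, as does directed-vs-unoriented.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ComparisonError("networks have different node sets")
    s1, s2 = _pair_status(g1), _pair_status(g2)
    pairs = set(s1) | set(s2)
    return sum(s1.get(p, "absent") != s2.get(p, "absent") for p in pairs)


def _subsample_indices(n: int, config: LearnerConfig) -> list[np.ndarray]:
    rng = np.random.default_rng(config.seed)
    k = max(2, int(round(config.subsample_fraction * n)))
    k = min(k, n)
    return [rng.choice(n, size=k, replace=False) for _ in range(config.subsamples)]


def select_tuning_parameter(
    omics: pd.DataFrame, grid: list[float], config: LearnerConfig | None = None
) -> tuple[float, pd.DataFrame]:
    """Choose the conditional-independence level by subsample stability.

    For each candidate level, skeletons are learned on seeded subsamples
    (without replacement) and the mean pairwise Hamming distance between them
    is recorded; the level minimizing that mean is returned (ties broken
    toward the smaller level). The full table is returned for logging.
    """
    if not grid:
        raise ParameterError("grid must be non-empty")
    config = config or LearnerConfig()
    if config.subsamples < 2:
        raise ParameterError("subsamples must be >= 2 for stability tuning")
    idx_sets = _subsample_indices(len(omics), config)
    rows = []
    for alpha in grid:
        cfg = replace(config, tuning_alpha=alpha)
        nets = [learn_skeleton(omics.iloc[idx], cfg) for idx in idx_sets]
        dists = [
            hamming_distance(a, b) for a, b in combinations(nets, 2)
        ]
        rows.append({"alpha": alpha, "mean_hamming": float(np.mean(dists))})
    table = pd.DataFrame(rows)
    best = table.sort_values(["mean_hamming", "alpha"]).iloc[0]
    return float(best["alpha"]), table


def edge_confidence(
    omics: pd.DataFrame, config: LearnerConfig | None = None
) -> dict[frozenset, float]:
    """Edge frequency across subsample skeletons, used as a confidence score."""
    config = config or LearnerConfig()
    idx_sets = _subsample_indices(len(omics), config)
    counts: dict[frozenset, int] = {}
    for idx in idx_sets:
        net = learn_skeleton(omics.iloc[idx], config)
        for e in net.edges:
            counts[e.pair()] = counts.get(e.pair(), 0) + 1
    return {p: c / len(idx_sets) for p, c in counts.items()}


def estimate_edge_effects(network: CausalNetwork, omics: pd.DataFrame) -> CausalNetwork:
    """Annotate each directed edge Mi -> Mj with Mi's coefficient in the
    regression of Mj on all of Mj's directed parents."""
    net = network.copy()
    dg = net.directed_graph()
    for node in net.nodes:
        parents = sorted(dg.predecessors(node))
        if not parents:
            continue
        X = omics[parents].to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        if np.linalg.matrix_rank(Xc) < len(parents):
            raise CollinearityError(parents, f"parents of {node}")
        y = omics[node].to_numpy(dtype=float)
        D = np.hstack([np.ones((len(y), 1)), X])
        coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
        for p, b in zip(parents, coef[1:]):
            edge = net.find_edge(p, node)
            if edge is not None and edge.kind == DIRECTED and edge.source == p:
                edge.effect = float(b)
    return net


def fit_network(
    genotypes: GenotypeMatrix | PolygenicFactors,
    omics: pd.DataFrame,
    covariates: pd.DataFrame | np.ndarray | None = None,
    config: LearnerConfig | None = None,
    alpha_grid: list[float] | None = None,
    n_factors: int | None = None,
    factor_method: str = "pca",
) -> tuple[CausalNetwork, InstrumentSet, dict]:
    """End-to-end identification: residualize, instrument, learn, orient, estimate.

    ``genotypes`` may be a raw variant panel (each variant a candidate
    instrument, the QTL mode) or pre-built polygenic factors; passing
    ``n_factors`` builds factors from the variant panel first. When
    ``alpha_grid`` is given the tuning parameter is chosen by subsample
    Hamming-distance minimization before the final fit.
    """
    config = config or LearnerConfig()
    report: dict = {}

    adjusted = residualize_covariates(omics, covariates)

    candidates = genotypes
    if isinstance(genotypes, GenotypeMatrix) and n_factors is not None:
        candidates = build_polygenic_factors(genotypes, n_factors, factor_method)
    if isinstance(candidates, PolygenicFactors):
        iv_values = candidates.to_frame().set_axis(adjusted.index, axis=0)
    else:
        iv_values = candidates.to_frame().astype(float).set_axis(adjusted.index, axis=0)
    instruments = assign_instruments(candidates, adjusted, config.strength_threshold)
    report["n_candidate_instruments"] = iv_values.shape[1]
    report["n_assigned_instruments"] = instruments.n_candidates()
    report["entities_with_instrument"] = sum(
        1 for e in adjusted.columns if instruments.best_instrument(e) is not None
    )

    if alpha_grid:
        chosen, table = select_tuning_parameter(adjusted, alpha_grid, config)
        config = replace(config, tuning_alpha=chosen)
        report["tuning_table"] = table
        report["tuning_alpha"] = chosen
    else:
        report["tuning_alpha"] = config.tuning_alpha

    skeleton = learn_skeleton(adjusted, config)
    report["n_skeleton_edges"] = len(skeleton.edges)

    net = orient_edges(skeleton, instruments, adjusted, iv_values, config)
    report["n_valid_instruments"] = instruments.n_valid()
    net = estimate_edge_effects(net, adjusted)
    report["edge_counts"] = net.edge_counts()
    return net, instruments, report
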