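"""Interrogating a fitted causal network.

Classifies nodes into broadcasters (arrows out, none in — intervention
targets that can shift the whole system), receptors (arrows in, none out —
prediction targets that summarize the system), detects modules of strongly
interacting entities, and integrates a downstream outcome trait to find its
direct causal parents and the mediated routes of everything else — the
network-then-outcome sequence used to relate a metabolite network to a
clinical trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError
from .instruments import InstrumentSet, pleiotropy_test
from .network import DIRECTED, CausalNetwork, Edge, LearnerConfig, _GaussCI

__all__ = [
    "NodeRole",
    "ModuleAssignment",
    "classify_nodes",
    "detect_modules",
    "outcome_integration",
]


@dataclass
class NodeRole:
    node: str
    in_degree: int
    out_degree: int
    role: str  # broadcaster | receptor | mixed | isolated
    hub: bool


@dataclass
class ModuleAssignment:
    membership: dict[str, int]
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def module_of(self, node: str) -> int:
        return self.membership[node]


def classify_nodes(network: CausalNetwork, hub_threshold: int | None = None) -> list[NodeRole]:
    """One role per node from the directed degrees.

    Undirected/bidirected edges count toward hubness (total degree) but not
    toward the broadcaster/receptor determination, whose direction they lack.
    The default hub threshold is the 95th percentile of total degree.
    """
    dg = network.directed_graph()
    skel = network.skeleton_graph()
    total = {v: skel.degree(v) for v in network.nodes}
    if hub_threshold is None:
        hub_threshold = int(np.ceil(np.percentile(list(total.values()), 95))) if total else 0
        hub_threshold = max(hub_threshold, 1)
    out = []
    for v in network.nodes:
        indeg, outdeg = dg.in_degree(v), dg.out_degree(v)
        if total[v] == 0:
            role = "isolated"
        elif indeg == 0 and outdeg > 0:
            role = "broadcaster"
        elif outdeg == 0 and indeg > 0:
            role = "receptor"
        else:
            role = "mixed"
        out.append(
            NodeRole(
                node=v,
                in_degree=indeg,
                out_degree=outdeg,
                role=role,
                hub=total[v] >= hub_threshold and total[v] > 0,
            )
        )
    return out


def detect_modules(network: CausalNetwork) -> ModuleAssignment:
    """Greedy modularity communities on the |effect|-weighted undirected projection.

    Edges without an estimated effect weigh 1. The per-module summary reports
    size, internal |effect| mass, and boundary nodes (members with an edge
    leaving the module) together with their in/out-degrees — the quantities
    that delimit a module's border.
    """
    g = network.skeleton_graph()
    if g.number_of_edges() == 0:
        membership = {v: i for i, v in enumerate(network.nodes)}
        return ModuleAssignment(membership=membership, summary=pd.DataFrame())
    communities = nx.algorithms.community.greedy_modularity_communities(g, weight="weight")
    membership: dict[str, int] = {}
    for mid, comm in enumerate(communities):
        for v in sorted(comm):
            membership[v] = mid
    dg = network.directed_graph()
    rows = []
    for mid, comm in enumerate(communities):
        comm = set(comm)
        internal = sum(
            d["weight"] for a, b, d in g.edges(comm, data=True) if a in comm and b in comm
        )
        boundary = sorted(
            v for v in comm if any(u not in comm for u in g.neighbors(v))
        )
        rows.append(
            {
                "module": mid,
                "size": len(comm),
                "internal_weight": internal,
                "boundary_nodes": ";".join(
                    f"{v}(in={dg.in_degree(v)},out={dg.out_degree(v)})" for v in boundary
                ),
            }
        )
    return ModuleAssignment(membership=membership, summary=pd.DataFrame(rows))


def _trait_parents_pc(
    augmented: pd.DataFrame, trait_name: str, entities: list[str], config: LearnerConfig
) -> list[str]:
    """PC-style adjacency search restricted to the trait's incident edges.

    Because the trait is a pure receptor (sink), its skeleton neighbors are
    exactly its direct parents, so only conditional independencies of the
    trait need testing.
    """
    ci = _GaussCI.from_data(augmented)
    adj = sorted(entities)
    alpha = config.tuning_alpha
    for level in range(config.max_conditioning + 1):
        frozen = list(adj)
        if len(frozen) - 1 < level:
            break
        for e in frozen:
            if e not in adj:
                continue
            others = [v for v in frozen if v != e and v in adj]
            removed = False
            for S in combinations(others, level):
                if ci.pvalue(trait_name, e, S) >= alpha:
                    adj.remove(e)
                    removed = True
                    break
            if removed:
                continue
    return adj


def outcome_integration(
    network: CausalNetwork,
    omics: pd.DataFrame,
    trait: pd.Series | np.ndarray,
    instruments: InstrumentSet | None = None,
    config: LearnerConfig | None = None,
    iv_values: pd.DataFrame | None = None,
    trait_name: str = "trait",
    max_path_length: int = 6,
) -> tuple[pd.DataFrame, dict]:
    """Append an outcome trait to a fitted network and find its direct parents.

    The trait is a pure receptor: entity -> trait edges are the only ones
    considered, so no trait -> entity orientation can ever be produced. The
    trait's direct parents are its skeleton neighbors under the same
    conditional-independence machinery used for the network; their effects
    come from the regression of the trait on all parents jointly. Where an
    entity carries a valid instrument, the pleiotropy screen
    (trait _|_ IV | entity) is run and recorded as MR corroboration. Every
    non-parent entity is annotated with its directed mediating path(s) to the
    trait through the network.
    """
    config = config or LearnerConfig()
    tvals = np.asarray(trait, dtype=float).ravel()
    if tvals.size != len(omics):
        raise DataError("trait length does not match omics rows")
    if np.std(tvals) == 0:
        raise DataError("trait is constant")
    if trait_name in omics.columns:
        raise DataError(f"omics already contains a column named {trait_name!r}")
    entities = list(omics.columns)
    augmented = omics.copy()
    augmented[trait_name] = tvals

    parents = _trait_parents_pc(augmented, trait_name, entities, config)

    effects: dict[str, float] = {}
    if parents:
        X = augmented[parents].to_numpy(dtype=float)
        D = np.hstack([np.ones((len(tvals), 1)), X])
        coef, _, _, _ = np.linalg.lstsq(D, tvals, rcond=None)
        effects = dict(zip(parents, coef[1:]))

    mr_checks = {}
    if instruments is not None:
        for e in parents:
            rec = instruments.best_instrument(e)
            if rec is None:
                continue
            entry: dict = {"instrument": rec.instrument_id}
            if iv_values is not None and rec.instrument_id in iv_values.columns:
                iv = iv_values[rec.instrument_id].to_numpy(dtype=float)
                _, p, passed = pleiotropy_test(
                    iv, omics[e].to_numpy(dtype=float), tvals, config.orient_alpha
                )
                entry.update({"pleiotropy_p": p, "screen_passed": passed})
            mr_checks[e] = entry
    parent_table = pd.DataFrame(
        {
            "entity": parents,
            "effect": [effects.get(e, np.nan) for e in parents],
        }
    )

    dg = network.directed_graph()
    mediated: dict[str, list[list[str]]] = {}
    parent_set = set(parents)
    for e in entities:
        if e in parent_set:
            continue
        paths = []
        for p in parents:
            if e in dg and p in dg:
                for path in nx.all_simple_paths(dg, e, p, cutoff=max_path_length):
                    paths.append(path + [trait_name])
        if paths:
            mediated[e] = paths

    report = {
        "trait": trait_name,
        "direct_parents": parents,
        "n_direct_parents": len(parents),
        "mediated_paths": mediated,
        "mr_corroboration": mr_checks,
        "trait_outgoing_edges": 0,  # receptor constraint, by construction
    }
    return parent_table, report


def append_trait_to_network(
    network: CausalNetwork, parent_table: pd.DataFrame, trait_name: str = "trait"
) -> CausalNetwork:
    """Return a copy of the network with the trait node and its parent edges."""
    net = network.copy()
    net.nodes = list(net.nodes) + [trait_name]
    for _, row in parent_table.iterrows():
        net.edges.append(
            Edge(row["entity"], trait_name, DIRECTED, effect=float(row["effect"]))
        )
    return CausalNetwork(nodes=net.nodes, edges=net.edges, meta=net.meta)
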