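"""Readers and writers for the package's plain-text interchange formats.

Everything is TSV (pandas round-trips), plus YAML for simulation specs and
JSON/GraphML for fitted networks.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .classical import validate_summary_stats
from .errors import DataError
from .network import DIRECTED, CausalNetwork, Edge
from .synthetic import GenotypeMatrix, SemSpec, TraitSpec

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_omics",
    "read_omics",
    "write_trait",
    "read_trait",
    "write_summary_stats",
    "read_summary_stats",
    "write_network",
    "read_network",
    "write_network_graphml",
    "write_report",
    "write_spec",
    "read_spec",
]


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    """Samples x variants dosage TSV; header row of variant ids, maf in a comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# maf\t" + "\t".join(f"{m:.6g}" for m in geno.maf) + "\n")
        geno.to_frame().to_csv(fh, sep="\t", index_label="sample_id")


def read_genotypes(path) -> GenotypeMatrix:
    path = Path(path)
    maf = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# maf"):
            maf = np.array([float(v) for v in first.strip().split("\t")[1:]])
            df = pd.read_csv(fh, sep="\t", index_col="sample_id")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="sample_id")
    dos = df.to_numpy()
    if maf is None:
        freq = dos.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        maf = np.clip(maf, 1e-6, 0.5)
    return GenotypeMatrix(
        sample_ids=[str(s) for s in df.index],
        variant_ids=[str(c) for c in df.columns],
        dosages=dos.astype(int),
        maf=maf,
    )


def write_omics(omics: pd.DataFrame, path) -> None:
    omics.to_csv(path, sep="\t", index_label="sample_id")


def read_omics(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_trait(trait: pd.Series, path) -> None:
    trait.rename("trait").to_csv(path, sep="\t", index_label="sample_id")


def read_trait(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return df.iloc[:, 0]


def write_summary_stats(table: pd.DataFrame, path) -> None:
    validate_summary_stats(table).to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return validate_summary_stats(pd.read_csv(path, sep="\t"))


def write_network(network: CausalNetwork, path) -> None:
    """Edge-list TSV: source, target, kind, effect, confidence (+node list header)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# nodes\t" + "\t".join(network.nodes) + "\n")
        network.to_frame().to_csv(fh, sep="\t", index=False)


def read_network(path) -> CausalNetwork:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# nodes"):
            raise DataError("network TSV must start with a '# nodes' header line")
        nodes = first.strip().split("\t")[1:]
        df = pd.read_csv(fh, sep="\t")
    edges = [
        Edge(
            source=row["source"],
            target=row["target"],
            kind=row["kind"],
            effect=None if pd.isna(row.get("effect")) else float(row["effect"]),
            confidence=None if pd.isna(row.get("confidence")) else float(row["confidence"]),
        )
        for _, row in df.iterrows()
    ]
    return CausalNetwork(nodes=nodes, edges=edges)


def write_network_graphml(network: CausalNetwork, path) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for e in network.edges:
        attrs = {"kind": e.kind}
        if e.effect is not None:
            attrs["effect"] = float(e.effect)
        if e.confidence is not None:
            attrs["confidence"] = float(e.confidence)
        g.add_edge(e.source, e.target, **attrs)
        if e.kind != DIRECTED:
            g.add_edge(e.target, e.source, **attrs)
    nx.write_graphml(g, path)


def write_report(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    Path(path).write_text(json.dumps(report, indent=2, default=_default))


def write_spec(spec: SemSpec, path, trait: TraitSpec | None = None, seed: int | None = None) -> None:
    """Serialize a simulation spec (plus optional trait and seed) to YAML."""
    doc = {
        "entity_ids": list(spec.entity_ids),
        "adjacency": spec.adjacency.tolist(),
        "iv_map": {
            e: {"instruments": list(ids), "alpha": a.tolist()}
            for e, (ids, a) in spec.iv_map.items()
        },
        "confounder_loadings": None
        if spec.confounder_loadings is None
        else spec.confounder_loadings.tolist(),
        "noise_sd": spec.noise_sd.tolist(),
        "pleiotropy_edges": [list(t) for t in spec.pleiotropy_edges],
    }
    if trait is not None:
        doc["trait"] = {
            "parent_entities": list(trait.parent_entities),
            "effects": trait.effects.tolist(),
            "noise_sd": float(trait.noise_sd),
        }
    if seed is not None:
        doc["seed"] = int(seed)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_spec(path) -> tuple[SemSpec, TraitSpec | None, int | None]:
    doc = yaml.safe_load(Path(path).read_text())
    spec = SemSpec(
        entity_ids=doc["entity_ids"],
        adjacency=np.asarray(doc["adjacency"], dtype=float),
        iv_map={
            e: (d["instruments"], np.asarray(d["alpha"], dtype=float))
            for e, d in doc.get("iv_map", {}).items()
        },
        confounder_loadings=None
        if doc.get("confounder_loadings") is None
        else np.asarray(doc["confounder_loadings"], dtype=float),
        noise_sd=np.asarray(doc["noise_sd"], dtype=float),
        pleiotropy_edges=[tuple(t) for t in doc.get("pleiotropy_edges", [])],
    )
    trait = None
    if "trait" in doc:
        t = doc["trait"]
        trait = TraitSpec(
            parent_entities=t["parent_entities"],
            effects=np.asarray(t["effects"], dtype=float),
            noise_sd=float(t["noise_sd"]),
        )
    return spec, trait, doc.get("seed")
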