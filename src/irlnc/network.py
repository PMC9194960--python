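"""Bipartite lncRNA-pathway network from significant enrichment records."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import ExpressionBundle, GeneSetCollection, PipelineError
from .lncres import LncresParams, score_all


@dataclass(frozen=True)
class NetworkEdge:
    lnc: str
    pathway: str
    lncres: float
    sign: str  # "+" activation, "-" repression (ES sign)


def pathway_enrich(
    bundle: ExpressionBundle,
    pathway_sets: GeneSetCollection,
    params: LncresParams | None = None,
    lnc_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Enrich ranked lists against a pathway collection (same machinery as
    the immune scoring); optionally restricted to the given lncRNAs."""
    if lnc_ids is not None:
        missing = sorted(set(lnc_ids) - set(map(str, bundle.lnc.index)))
        if missing:
            raise PipelineError(f"lncRNAs not in bundle: {missing[:5]}")
        bundle = ExpressionBundle(
            lnc=bundle.lnc.loc[list(lnc_ids)], mrna=bundle.mrna, design=bundle.design
        )
    return score_all(bundle, pathway_sets, params)


def build_network(
    records: pd.DataFrame,
    top_k_pathways: int = 5,
    allow_list: list[str] | None = None,
) -> list[NetworkEdge]:
    """Edges for significant (lncRNA, pathway) pairs, restricted to the
    ``top_k_pathways`` by number of significant lncRNA partners (ties broken
    by name) or to an explicit ``allow_list``; deterministic ordering."""
    if records.empty:
        return []
    sig = records[records["significant"]].drop_duplicates(subset=["lnc", "set"])
    if sig.empty:
        return []
    if allow_list is not None:
        kept = [p for p in allow_list if p in set(sig["set"])]
    else:
        counts = (
            sig.groupby("set")["lnc"].nunique().sort_values(ascending=False)
        )
        ordered = sorted(counts.index, key=lambda s: (-counts[s], s))
        kept = ordered[:top_k_pathways]
    sig = sig[sig["set"].isin(kept)].sort_values(["set", "lnc"])
    return [
        NetworkEdge(
            lnc=row.lnc,
            pathway=row.set,
            lncres=float(row.lncres),
            sign="+" if row.es > 0 else "-",
        )
        for row in sig.itertuples()
    ]


def export_network(edges: list[NetworkEdge], path: str | Path, format: str = "sif") -> Path:
    """Write the network as SIF (``lnc<TAB>interacts<TAB>pathway``) or
    GraphML with ``weight``/``sign`` edge attributes."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.lnc}\tinteracts\t{e.pathway}\n")
    elif fmt == "graphml":
        g = to_graph(edges)
        nx.write_graphml(g, path)
    else:
        raise PipelineError(f"unknown network format {format!r} (use sif or graphml)")
    return path


def to_graph(edges: list[NetworkEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_node(e.lnc, kind="lncRNA", bipartite=0)
        g.add_node(e.pathway, kind="pathway", bipartite=1)
        g.add_edge(e.lnc, e.pathway, weight=e.lncres, sign=e.sign)
    return g


def read_graphml(path: str | Path) -> list[NetworkEdge]:
    g = nx.read_graphml(path)
    edges = []
    for u, v, data in g.edges(data=True):
        if g.nodes[u].get("kind") == "pathway":
            u, v = v, u
        edges.append(NetworkEdge(lnc=u, pathway=v, lncres=float(data["weight"]),
                                 sign=str(data["sign"])))
    return sorted(edges, key=lambda e: (e.pathway, e.lnc))
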