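"""Cytoscape-compatible network export.

Writes a SIF edge file plus node- and edge-attribute tables. SIF cannot
carry attributes, so node roles/tiers and regulation signs live in
``nodes.tsv`` and ``edges.tsv``; the interaction label in the SIF encodes
the rendering semantics (positive/negative regulation, genetic
interaction, physical = protein-protein interaction). A synthetic
``direct_target`` edge links the query node to each cascade root.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .io import InteractionEdge
from .cascade import Cascade

__all__ = ["NetworkExport", "export_cytoscape", "read_cytoscape"]

_ROLE_PRIORITY = {"query": 0, "direct_target": 1, "downstream": 2}


@dataclass(frozen=True)
class NetworkExport:
    """Parsed form of an export: node rows and edge rows."""

    nodes: tuple[tuple[str, str, str], ...]  # (gene_id, role, tier)
    edges: tuple[tuple[str, str, str, str], ...]  # (source, target, edge_type, sign)


def _interaction_label(edge: InteractionEdge) -> str:
    if edge.edge_type == "regulatory":
        return edge.sign if edge.sign != "unknown" else "regulatory"
    return edge.edge_type


def _collect(cascades: list[Cascade], query_gene: str, query_tier: str) -> NetworkExport:
    roles: dict[str, str] = {query_gene: "query"}
    tiers: dict[str, str] = {query_gene: query_tier}
    edge_rows: list[tuple[str, str, str, str]] = []
    for c in sorted(cascades, key=lambda c: c.cascade_id):
        if c.query_gene and c.query_gene != query_gene:
            raise ValueError(
                f"cascade {c.cascade_id} belongs to query {c.query_gene!r}, "
                f"not {query_gene!r}"
            )
        for gene in c.nodes:
            role = "direct_target" if gene == c.root_target else "downstream"
            prev = roles.get(gene)
            if prev is None or _ROLE_PRIORITY[role] < _ROLE_PRIORITY[prev]:
                roles[gene] = role
            tiers.setdefault(gene, c.tiers[gene])
        edge_rows.append((query_gene, c.root_target, "direct_target", "unknown"))
        for e in c.edges:
            edge_rows.append((e.source, e.target, e.edge_type, e.sign))

    node_rows = tuple(
        (gene, roles[gene], tiers[gene]) for gene in sorted(roles)
    )
    # dedupe (shared edges across cascades) with deterministic order
    edge_rows = tuple(sorted(set(edge_rows)))
    return NetworkExport(nodes=node_rows, edges=edge_rows)


def export_cytoscape(
    cascades: list[Cascade],
    query_gene: str,
    out_dir: str | os.PathLike,
    query_tier: str = "early_embryo",
) -> dict[str, str]:
    """Write ``network.sif``, ``nodes.tsv`` and ``edges.tsv``.

    All cascades must share ``query_gene``. Ordering is deterministic, so
    identical inputs give byte-identical files. Returns the file paths.
    """
    export = _collect(cascades, query_gene, query_tier)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "sif": os.path.join(out_dir, "network.sif"),
        "nodes": os.path.join(out_dir, "nodes.tsv"),
        "edges": os.path.join(out_dir, "edges.tsv"),
    }

    with open(paths["sif"], "w", encoding="utf-8") as fh:
        for source, target, edge_type, sign in export.edges:
            label = (
                "direct_target"
                if edge_type == "direct_target"
                else _interaction_label(InteractionEdge(source, target, edge_type, sign))
            )
            fh.write(f"{source}\t{label}\t{target}\n")

    pd.DataFrame(list(export.nodes), columns=["gene_id", "role", "tier"]).to_csv(
        paths["nodes"], sep="\t", index=False
    )
    pd.DataFrame(
        list(export.edges), columns=["source", "target", "edge_type", "sign"]
    ).to_csv(paths["edges"], sep="\t", index=False)
    return paths


def read_cytoscape(out_dir: str | os.PathLike) -> NetworkExport:
    """Parse a previous export back; inverse of :func:`export_cytoscape`."""
    out_dir = os.fspath(out_dir)
    nodes_df = pd.read_csv(os.path.join(out_dir, "nodes.tsv"), sep="\t", dtype=str)
    edges_df = pd.read_csv(os.path.join(out_dir, "edges.tsv"), sep="\t", dtype=str)
    nodes = tuple(sorted(map(tuple, nodes_df.itertuples(index=False))))
    edges = tuple(sorted(map(tuple, edges_df.itertuples(index=False))))
    export = NetworkExport(nodes=nodes, edges=edges)
    node_ids = {n[0] for n in nodes}
    for source, target, *_ in edges:
        if source not in node_ids or target not in node_ids:
            raise ValueError(f"edge endpoint missing from node table: {source}-{target}")
    return export
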