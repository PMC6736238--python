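"""Direct-target prediction and cascade expansion.

A direct target of a translational-regulator query gene is a gene that
(1) shows no expression-level fluctuation in the query mutant — the query
regulates its translation, not its mRNA level; (2) is a transcription
factor — otherwise there is nothing downstream to expand; (3) is expressed
at the same time as the query (shared life-stage terms); and (4) has a
similar mutant phenotype (shared phenotype terms).

Each direct target is then expanded into a cascade by a breadth-first
fixpoint over the interaction graph: from every accepted gene, the targets
of its outgoing regulatory edges and the partners of its genetic/physical
edges are candidates, and a candidate is accepted iff it carries an
embryonic life-stage term. The bottom genes — the cascade nodes with no
outgoing regulatory edge — carry the cascade's predicted function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io import AnnotationDB, InteractionEdge
from .fluctuation import FluctuationClassification

__all__ = [
    "Cascade",
    "DEFAULT_ALLOWED_STAGES",
    "EARLY_EMBRYO_STAGE",
    "DIRECT_TARGET_CRITERIA",
    "find_direct_targets",
    "expand_cascade",
    "find_bottom_genes",
    "build_all_cascades",
]

EARLY_EMBRYO_STAGE = "early embryo"
DEFAULT_ALLOWED_STAGES = frozenset({"early embryo", "embryo"})
DIRECT_TARGET_CRITERIA = ("stability", "tf", "stage", "phenotype")


@dataclass
class Cascade:
    """A rooted cascade graph.

    ``tiers`` maps each node to ``early_embryo`` (annotated with the
    "early embryo" stage term) or ``embryo`` (embryonic but not early —
    the presumptive-early-embryonic tier). ``edges`` is restricted to
    edges whose both endpoints were accepted.
    """

    cascade_id: str
    query_gene: str
    root_target: str
    nodes: set[str]
    edges: list[InteractionEdge]
    tiers: dict[str, str]
    bottom_genes: set[str] = field(default_factory=set)

    def regulatory_out_degree(self, gene: str) -> int:
        return sum(
            1 for e in self.edges if e.edge_type == "regulatory" and e.source == gene
        )


def find_direct_targets(
    query_gene: str,
    classification: FluctuationClassification,
    annotations: AnnotationDB,
    min_phenotype_overlap: int = 1,
    skip_criteria: frozenset[str] | set[str] = frozenset(),
) -> list[str]:
    """Return the predicted direct targets of ``query_gene``, sorted.

    All four criteria must hold: membership in the stable class, TF flag,
    non-empty stage intersection with the query, and at least
    ``min_phenotype_overlap`` shared phenotype terms. The query gene is
    never its own target. ``skip_criteria`` (subset of
    :data:`DIRECT_TARGET_CRITERIA`) disables individual filters — useful
    for ablation studies of the criteria, not for production runs.
    """
    unknown = set(skip_criteria) - set(DIRECT_TARGET_CRITERIA)
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    query_stages = annotations.stages_of(query_gene)
    if not query_stages and "stage" not in skip_criteria:
        raise ValueError(
            f"query gene {query_gene!r} has no life-stage annotation; "
            "simultaneous-expression criterion cannot be evaluated"
        )
    query_phenotypes = annotations.phenotypes_of(query_gene)
    candidates = (
        classification.stable
        if "stability" not in skip_criteria
        else classification.all_genes
    )
    targets = []
    for gene in candidates:
        if gene == query_gene:
            continue
        if "tf" not in skip_criteria and gene not in annotations.tf_genes:
            continue
        if "stage" not in skip_criteria and not (
            annotations.stages_of(gene) & query_stages
        ):
            continue
        if (
            "phenotype" not in skip_criteria
            and len(annotations.phenotypes_of(gene) & query_phenotypes)
            < min_phenotype_overlap
        ):
            continue
        targets.append(gene)
    return sorted(targets)


def _neighbors(gene: str, edges_by_gene: dict[str, list[InteractionEdge]]) -> set[str]:
    """Downstream candidates of one gene: regulatory out-targets plus
    genetic/physical partners (undirected)."""
    out = set()
    for e in edges_by_gene.get(gene, ()):
        if e.edge_type == "regulatory":
            if e.source == gene:
                out.add(e.target)
        else:
            out.add(e.target if e.source == gene else e.source)
    return out


def _index_edges(edges: list[InteractionEdge]) -> dict[str, list[InteractionEdge]]:
    idx: dict[str, list[InteractionEdge]] = {}
    for e in edges:
        idx.setdefault(e.source, []).append(e)
        if e.target != e.source:
            idx.setdefault(e.target, []).append(e)
    return idx


def expand_cascade(
    root_target: str,
    annotations: AnnotationDB,
    allowed_stages: frozenset[str] | set[str] = DEFAULT_ALLOWED_STAGES,
    cascade_id: str | None = None,
    query_gene: str = "",
) -> Cascade:
    """Breadth-first fixpoint expansion from one direct target.

    A candidate neighbour is accepted iff its stage terms intersect
    ``allowed_stages``; the visited set guarantees termination on any
    finite graph, cyclic or not. All interaction edges between accepted
    nodes (including cycle-closing ones) are retained.
    """
    allowed = frozenset(allowed_stages)
    if not (annotations.stages_of(root_target) & allowed):
        raise ValueError(
            f"root target {root_target!r} is not annotated with any allowed "
            f"stage term {sorted(allowed)}"
        )
    edges_by_gene = _index_edges(annotations.interactions)

    accepted = {root_target}
    frontier = [root_target]
    while frontier:
        next_frontier = []
        for gene in sorted(frontier):
            for cand in sorted(_neighbors(gene, edges_by_gene)):
                if cand in accepted:
                    continue
                if annotations.stages_of(cand) & allowed:
                    accepted.add(cand)
                    next_frontier.append(cand)
        frontier = next_frontier

    edges = sorted(
        (
            e
            for e in annotations.interactions
            if e.source in accepted and e.target in accepted
        ),
        key=InteractionEdge.key,
    )
    tiers = {
        g: "early_embryo" if EARLY_EMBRYO_STAGE in annotations.stages_of(g) else "embryo"
        for g in accepted
    }
    cascade = Cascade(
        cascade_id=cascade_id or root_target,
        query_gene=query_gene,
        root_target=root_target,
        nodes=accepted,
        edges=edges,
        tiers=tiers,
    )
    cascade.bottom_genes = find_bottom_genes(cascade)
    return cascade


def find_bottom_genes(cascade: Cascade) -> set[str]:
    """Nodes with zero outgoing regulatory edges within the cascade.

    Genetic/physical edges carry no downstream meaning and are ignored.
    If every node sits on a regulatory cycle (so none has out-degree 0),
    the nodes of the terminal strongly-connected components are returned
    instead.
    """
    if not cascade.nodes:
        raise ValueError("empty cascade")
    bottoms = {g for g in cascade.nodes if cascade.regulatory_out_degree(g) == 0}
    if bottoms:
        return bottoms
    # pure-regulatory-cycle fallback: terminal SCCs of the regulatory subgraph
    dg = nx.DiGraph()
    dg.add_nodes_from(cascade.nodes)
    dg.add_edges_from(
        (e.source, e.target) for e in cascade.edges if e.edge_type == "regulatory"
    )
    condensation = nx.condensation(dg)
    out = set()
    for scc_id in condensation.nodes:
        if condensation.out_degree(scc_id) == 0:
            out.update(condensation.nodes[scc_id]["members"])
    return out


def build_all_cascades(
    query_gene: str,
    classification: FluctuationClassification,
    annotations: AnnotationDB,
    allowed_stages: frozenset[str] | set[str] = DEFAULT_ALLOWED_STAGES,
    min_phenotype_overlap: int = 1,
) -> list[Cascade]:
    """One cascade per direct target, deterministically ordered and id'd.

    Cascade ids are ``C<k>_<root>`` with k following the lexicographic
    order of the root targets, so repeated runs on identical input produce
    identical output.
    """
    targets = find_direct_targets(
        query_gene, classification, annotations, min_phenotype_overlap
    )
    cascades = []
    for i, root in enumerate(targets, start=1):
        cascades.append(
            expand_cascade(
                root,
                annotations,
                allowed_stages=allowed_stages,
                cascade_id=f"C{i:03d}_{root}",
                query_gene=query_gene,
            )
        )
    return cascades
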