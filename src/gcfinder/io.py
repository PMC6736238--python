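"""Domain types and tab-separated readers/writers.

Every table the tool consumes or produces is UTF-8, tab-separated, with a
mandatory header row. Gene identifiers are opaque case-sensitive strings
(WormBase-style names such as ``spn-4`` in practice, but nothing is
validated against a nomenclature).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ExpressionRecord",
    "InteractionEdge",
    "AnnotationDB",
    "FormatError",
    "read_expression_table",
    "write_expression_table",
    "read_annotations",
    "write_cascade_tables",
    "EDGE_TYPES",
    "EDGE_SIGNS",
]

EDGE_TYPES = frozenset({"regulatory", "genetic", "physical"})
EDGE_SIGNS = frozenset({"positive", "negative", "unknown"})

EXPRESSION_COLUMNS = ("gene_id", "wt_rpkm", "mut_rpkm")

#: table-name -> expected header for the annotation bundle
ANNOTATION_SCHEMAS: dict[str, tuple[str, ...]] = {
    "tf_list": ("gene_id",),
    "stages": ("gene_id", "stage"),
    "phenotypes": ("gene_id", "phenotype"),
    "interactions": ("source", "target", "edge_type", "sign"),
    "gene_domains": ("gene_id", "domain_acc"),
    "domain_categories": ("domain_acc", "category"),
}


class FormatError(ValueError):
    """Raised when an input table violates its documented schema."""


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's paired wild-type/mutant expression levels (RPKM).

    ``wt_level`` and ``mut_level`` are the x_i and y_i of the ratio
    statistic: expression of gene i in the wild type and in the mutant of
    the query gene.
    """

    gene_id: str
    wt_level: float
    mut_level: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.wt_level < 0 or self.mut_level < 0:
            raise ValueError(
                f"expression levels must be non-negative for {self.gene_id!r}"
            )


@dataclass(frozen=True)
class InteractionEdge:
    """A typed gene-gene interaction.

    ``regulatory`` edges are directed source→target and may carry a sign
    (positive/negative activation semantics); ``genetic`` and ``physical``
    edges are undirected — the source/target order carries no meaning and
    the sign must be ``unknown``.
    """

    source: str
    target: str
    edge_type: str
    sign: str = "unknown"

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise FormatError(f"unknown edge_type {self.edge_type!r}")
        if self.sign not in EDGE_SIGNS:
            raise FormatError(f"unknown sign {self.sign!r}")
        if self.edge_type != "regulatory" and self.sign != "unknown":
            raise FormatError(
                f"sign {self.sign!r} given on undirected {self.edge_type} edge "
                f"{self.source}-{self.target}"
            )

    @property
    def directed(self) -> bool:
        return self.edge_type == "regulatory"

    def key(self) -> tuple:
        """Canonical sort/identity key; undirected edges order-normalised."""
        if self.directed:
            ends = (self.source, self.target)
        else:
            ends = tuple(sorted((self.source, self.target)))
        return (*ends, self.edge_type, self.sign)


@dataclass
class AnnotationDB:
    """Unified annotation lookup bundle.

    Genes absent from a mapping are treated as having the empty set; use
    the ``*_of`` accessors rather than indexing the raw dicts.
    """

    tf_genes: set[str] = field(default_factory=set)
    stages: dict[str, set[str]] = field(default_factory=dict)
    phenotypes: dict[str, set[str]] = field(default_factory=dict)
    interactions: list[InteractionEdge] = field(default_factory=list)
    domains: dict[str, set[str]] = field(default_factory=dict)
    domain_categories: dict[str, str] = field(default_factory=dict)

    def stages_of(self, gene: str) -> set[str]:
        return self.stages.get(gene, set())

    def phenotypes_of(self, gene: str) -> set[str]:
        return self.phenotypes.get(gene, set())

    def domains_of(self, gene: str) -> set[str]:
        return self.domains.get(gene, set())

    def category_of(self, domain_acc: str) -> str | None:
        return self.domain_categories.get(domain_acc)


def _read_tsv(path: str | os.PathLike, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{os.fspath(path)}: missing required column(s) {', '.join(missing)}"
        )
    return df


def read_expression_table(path: str | os.PathLike) -> list[ExpressionRecord]:
    """Read a wild-type vs. mutant expression table.

    Expected columns: ``gene_id``, ``wt_rpkm``, ``mut_rpkm``. Records are
    returned in file order. Errors name the offending column or data line
    (1-based, counting the header as line 1).
    """
    df = _read_tsv(path, EXPRESSION_COLUMNS)
    records: list[ExpressionRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        gene = row.gene_id
        if not gene:
            raise FormatError(f"{os.fspath(path)}:{line_no}: empty gene_id")
        if gene in seen:
            raise FormatError(
                f"{os.fspath(path)}:{line_no}: duplicate gene_id {gene!r}"
            )
        try:
            wt = float(row.wt_rpkm)
            mut = float(row.mut_rpkm)
        except ValueError as exc:
            raise FormatError(
                f"{os.fspath(path)}:{line_no}: unparseable expression level ({exc})"
            ) from None
        if wt < 0 or mut < 0:
            raise FormatError(
                f"{os.fspath(path)}:{line_no}: negative expression level for {gene!r}"
            )
        seen.add(gene)
        records.append(ExpressionRecord(gene, wt, mut))
    return records


def write_expression_table(
    records: Iterable[ExpressionRecord], path: str | os.PathLike
) -> None:
    """Inverse of :func:`read_expression_table` (exact round-trip)."""
    df = pd.DataFrame(
        [(r.gene_id, repr(r.wt_level), repr(r.mut_level)) for r in records],
        columns=list(EXPRESSION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(paths: Mapping[str, str | os.PathLike]) -> AnnotationDB:
    """Assemble an :class:`AnnotationDB` from flat-file extracts.

    ``paths`` maps table names (see :data:`ANNOTATION_SCHEMAS`) to file
    paths; any table may be omitted and yields an empty structure. Rows for
    the same gene are merged into sets; row order never matters.
    """
    unknown = set(paths) - set(ANNOTATION_SCHEMAS)
    if unknown:
        raise FormatError(f"unknown annotation table(s): {', '.join(sorted(unknown))}")

    db = AnnotationDB()

    if "tf_list" in paths:
        df = _read_tsv(paths["tf_list"], ANNOTATION_SCHEMAS["tf_list"])
        db.tf_genes = {g for g in df["gene_id"] if g}

    for name, attr, key_col, val_col in (
        ("stages", "stages", "gene_id", "stage"),
        ("phenotypes", "phenotypes", "gene_id", "phenotype"),
        ("gene_domains", "domains", "gene_id", "domain_acc"),
    ):
        if name not in paths:
            continue
        df = _read_tsv(paths[name], ANNOTATION_SCHEMAS[name])
        mapping: dict[str, set[str]] = {}
        for gene, term in zip(df[key_col], df[val_col]):
            if not gene:
                raise FormatError(f"{os.fspath(paths[name])}: empty gene identifier")
            mapping.setdefault(gene, set()).add(term)
        setattr(db, attr, mapping)

    if "interactions" in paths:
        df = _read_tsv(paths["interactions"], ANNOTATION_SCHEMAS["interactions"])
        edges = []
        for idx, row in enumerate(df.itertuples(index=False)):
            try:
                edges.append(
                    InteractionEdge(
                        row.source, row.target, row.edge_type, row.sign or "unknown"
                    )
                )
            except FormatError as exc:
                raise FormatError(
                    f"{os.fspath(paths['interactions'])}:{idx + 2}: {exc}"
                ) from None
        # canonical order so that file row order never leaks into results
        db.interactions = sorted(edges, key=InteractionEdge.key)

    if "domain_categories" in paths:
        df = _read_tsv(
            paths["domain_categories"], ANNOTATION_SCHEMAS["domain_categories"]
        )
        db.domain_categories = dict(zip(df["domain_acc"], df["category"]))

    return db


def write_cascade_tables(cascades, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the cascade summary and long-format membership tables.

    Returns ``{"summary": path, "membership": path}``. Row order is
    deterministic: cascade id, then gene id lexicographic; two identical
    runs produce byte-identical files.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    ordered = sorted(cascades, key=lambda c: c.cascade_id)

    summary_rows = []
    member_rows = []
    for c in ordered:
        summary_rows.append(
            (
                c.cascade_id,
                c.query_gene,
                c.root_target,
                len(c.nodes),
                ";".join(sorted(c.bottom_genes)),
            )
        )
        for gene in sorted(c.nodes):
            if gene == c.root_target:
                role = "direct_target"
            else:
                role = "downstream"
            member_rows.append((c.cascade_id, gene, role, c.tiers[gene]))

    summary = pd.DataFrame(
        summary_rows,
        columns=["cascade_id", "query_gene", "root_target", "n_nodes", "bottom_genes"],
    )
    membership = pd.DataFrame(
        member_rows, columns=["cascade_id", "gene_id", "role", "tier"]
    )
    paths = {
        "summary": os.path.join(out_dir, "cascade_summary.tsv"),
        "membership": os.path.join(out_dir, "cascade_membership.tsv"),
    }
    summary.to_csv(paths["summary"], sep="\t", index=False)
    membership.to_csv(paths["membership"], sep="\t", index=False)
    return paths
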