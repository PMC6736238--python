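"""Seeded synthetic-data generator with planted ground truth.

Emulates the flat-file extracts the tool consumes — an RPKM expression
table and WormBase-style annotation tables (TF list, life stages,
phenotypes, typed interaction edges, Pfam-like domain assignments) — with
known answers planted:

* ``n_direct_targets`` genes satisfy all four direct-target criteria by
  construction (stable ratio, TF, stage and phenotype shared with the
  query gene);
* one decoy gene per criterion violates exactly that criterion, so filter
  ablation is testable;
* each planted target roots a regulatory tree of embryo-annotated genes of
  known depth and branching, whose leaves are the ground-truth bottom
  genes; distractor edges lead to non-embryonic genes that the stage
  filter must drop;
* background genes draw log2 ratios from a normal distribution (a
  log-normal ratio distribution, so the median/quartile machinery sees a
  realistically skewed sample), with a fraction displaced by
  ``fluct_shift`` to plant clear fluctuation;
* bottom genes carry a signal domain that is rare in the background, so
  enrichment has a planted positive.

Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io import (
    AnnotationDB,
    ExpressionRecord,
    InteractionEdge,
    write_expression_table,
)

__all__ = ["FixtureSpec", "GroundTruth", "generate_fixture", "write_fixture"]

QUERY_GENE = "qry-1"
QUERY_STAGES = frozenset({"early embryo"})
QUERY_PHENOTYPES = frozenset({"embryonic lethal"})
SIGNAL_DOMAIN = "PF09001"  # planted enriched domain of the bottom genes
SIGNAL_CATEGORY = "Signal transduction"

_CRITERIA = ("stability", "tf", "stage", "phenotype")

_EMBRYONIC_CHOICES = (
    frozenset({"early embryo"}),
    frozenset({"embryo"}),
    frozenset({"early embryo", "embryo"}),
)
_NON_EMBRYONIC_CHOICES = (frozenset({"L1 larva"}), frozenset({"adult"}))

_CATEGORY_POOL = (
    "Transcription",
    "Signal transduction",
    "Development",
    "Cell cycle",
    "DNA replication",
    "Transport",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``stable_noise_sd`` is the standard deviation of the background log2
    ratios; ``fluct_shift`` the log2 displacement of planted-fluctuating
    genes (must be large relative to the noise so the classes separate);
    ``frac_embryonic`` the fraction of background genes given embryonic
    stage terms.
    """

    n_genes: int = 200
    n_direct_targets: int = 3
    cascade_depth: int = 4
    branching: float = 2.0
    frac_tf: float = 0.15
    stable_noise_sd: float = 0.5
    fluct_shift: float = 3.0
    frac_embryonic: float = 0.6
    frac_fluctuating: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_direct_targets <= 0:
            raise ValueError("counts must be positive")
        if self.cascade_depth < 0 or self.branching < 1:
            raise ValueError("cascade_depth must be >= 0 and branching >= 1")
        for frac in (self.frac_tf, self.frac_embryonic, self.frac_fluctuating):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.stable_noise_sd < 0 or self.fluct_shift < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class GroundTruth:
    """Planted answers: what a correct run must recover exactly."""

    direct_targets: set[str]
    cascade_membership: dict[str, set[str]]
    bottom_genes: dict[str, set[str]]
    #: criterion name -> the decoy gene violating exactly that criterion
    decoys: dict[str, str] = field(default_factory=dict)


def _tree_sizes(depth: int, branching: int) -> list[int]:
    """Nodes per level below the root of a uniform tree."""
    return [branching**level for level in range(1, depth + 1)]


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[list[ExpressionRecord], AnnotationDB, GroundTruth]:
    """Generate one synthetic dataset; deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    branching = max(1, int(round(spec.branching)))
    per_cascade = sum(_tree_sizes(spec.cascade_depth, branching))

    targets = [f"tgt-{i}" for i in range(1, spec.n_direct_targets + 1)]
    decoys = {c: f"dcy-{c}-1" for c in _CRITERIA}
    downstream: dict[str, list[list[str]]] = {}  # target -> nodes per level
    for t in targets:
        levels, counter = [], 0
        for size in _tree_sizes(spec.cascade_depth, branching):
            levels.append([f"dwn-{t[4:]}-{counter + j}" for j in range(size)])
            counter += size
        downstream[t] = levels

    n_named = (
        1 + len(targets) + len(decoys) + spec.n_direct_targets * per_cascade
    )
    n_background = spec.n_genes - n_named
    if n_background < 8:
        raise ValueError(
            f"infeasible spec: {n_named} planted genes plus a minimal background "
            f"of 8 exceed n_genes={spec.n_genes}"
        )
    n_tf_quota = int(spec.frac_tf * spec.n_genes)
    planted_tfs = len(targets) + 3  # targets + the three TF decoys
    if n_tf_quota < planted_tfs:
        raise ValueError(
            f"infeasible spec: frac_tf={spec.frac_tf} allows {n_tf_quota} TFs but "
            f"{planted_tfs} are planted"
        )
    background = [f"bgd-{i:04d}" for i in range(n_background)]

    # --- expression table -------------------------------------------------
    records: list[ExpressionRecord] = []

    def add_gene(gene: str, log2_ratio: float) -> None:
        wt = float(rng.lognormal(mean=3.0, sigma=1.0))
        records.append(ExpressionRecord(gene, wt, wt * 2.0**log2_ratio))

    add_gene(QUERY_GENE, -spec.fluct_shift)  # the mutant lacks the query mRNA
    for t in targets:
        add_gene(t, 0.0)  # translational target: mRNA level unchanged
    for crit, gene in decoys.items():
        if crit == "stability":
            shift = spec.fluct_shift * (1 if rng.random() < 0.5 else -1)
            add_gene(gene, shift)
        else:
            add_gene(gene, 0.0)
    for t in targets:
        for level in downstream[t]:
            for gene in level:
                add_gene(gene, float(rng.normal(0.0, spec.stable_noise_sd)))
    n_fluct = int(round(spec.frac_fluctuating * n_background))
    for i, gene in enumerate(background):
        lr = float(rng.normal(0.0, spec.stable_noise_sd))
        if i < n_fluct:
            lr += spec.fluct_shift * (1 if i % 2 == 0 else -1)
        add_gene(gene, lr)

    # --- annotations ------------------------------------------------------
    db = AnnotationDB()

    db.tf_genes = set(targets) | {
        decoys["stability"], decoys["stage"], decoys["phenotype"]
    }
    # fill the TF quota from non-embryonic background genes later if possible
    tf_fill = n_tf_quota - len(db.tf_genes)

    db.stages[QUERY_GENE] = set(QUERY_STAGES)
    db.phenotypes[QUERY_GENE] = set(QUERY_PHENOTYPES)
    for t in targets:
        db.stages[t] = {"early embryo"}
        db.phenotypes[t] = set(QUERY_PHENOTYPES)
    db.stages[decoys["stability"]] = {"early embryo"}
    db.phenotypes[decoys["stability"]] = set(QUERY_PHENOTYPES)
    db.stages[decoys["tf"]] = {"early embryo"}
    db.phenotypes[decoys["tf"]] = set(QUERY_PHENOTYPES)
    db.stages[decoys["stage"]] = {"L4 larva"}
    db.phenotypes[decoys["stage"]] = set(QUERY_PHENOTYPES)
    db.stages[decoys["phenotype"]] = {"early embryo"}
    db.phenotypes[decoys["phenotype"]] = {"larval arrest"}

    for t in targets:
        for level in downstream[t]:
            for gene in level:
                choice = int(rng.integers(len(_EMBRYONIC_CHOICES)))
                db.stages[gene] = set(_EMBRYONIC_CHOICES[choice])
                db.phenotypes[gene] = {"uncharacterised"}

    embryonic_background, non_embryonic_background = [], []
    for gene in background:
        if rng.random() < spec.frac_embryonic:
            choice = int(rng.integers(len(_EMBRYONIC_CHOICES)))
            db.stages[gene] = set(_EMBRYONIC_CHOICES[choice])
            embryonic_background.append(gene)
        else:
            choice = int(rng.integers(len(_NON_EMBRYONIC_CHOICES)))
            db.stages[gene] = set(_NON_EMBRYONIC_CHOICES[choice])
            non_embryonic_background.append(gene)
    # TF quota fill: embryonic background TFs would pass criteria 1–3, so
    # only non-embryonic background genes are flagged (they fail the stage
    # criterion and never pollute the planted direct-target set).
    db.tf_genes.update(non_embryonic_background[:tf_fill])

    # --- interactions -----------------------------------------------------
    edges: list[InteractionEdge] = []
    for t in targets:
        parents = [t]
        for level in downstream[t]:
            children = iter(level)
            per_parent = len(level) // len(parents)
            for parent in parents:
                for _ in range(per_parent):
                    child = next(children)
                    sign = "positive" if rng.random() < 0.7 else "negative"
                    edges.append(InteractionEdge(parent, child, "regulatory", sign))
            parents = level
        # undirected intra-cascade edges (membership unchanged, shape tested)
        first = downstream[t][0] if downstream[t] else []
        if len(first) >= 2:
            edges.append(InteractionEdge(first[0], first[1], "physical"))
        # distractor out-edges from leaves to non-embryonic genes: the stage
        # filter must drop these and keep the leaves as bottom genes
        leaves = downstream[t][-1] if downstream[t] else [t]
        for i, leaf in enumerate(leaves[:3]):
            if non_embryonic_background:
                sink = non_embryonic_background[i % len(non_embryonic_background)]
                edges.append(InteractionEdge(leaf, sink, "regulatory", "positive"))
    # noise edges among background genes (never reachable from a cascade)
    for i in range(0, len(background) - 1, 7):
        edges.append(InteractionEdge(background[i], background[i + 1], "genetic"))
    db.interactions = sorted(edges, key=InteractionEdge.key)

    # --- domains ----------------------------------------------------------
    pool = [f"PF{i:05d}" for i in range(1, 31)]
    db.domain_categories = {
        acc: _CATEGORY_POOL[i % len(_CATEGORY_POOL)]
        for i, acc in enumerate(pool)
        if i % 5 != 4  # every fifth domain left unmapped -> "Unknown"
    }
    db.domain_categories[SIGNAL_DOMAIN] = SIGNAL_CATEGORY

    all_bottom: set[str] = set()
    truth = GroundTruth(
        direct_targets=set(targets),
        cascade_membership={
            t: {t} | {g for level in downstream[t] for g in level} for t in targets
        },
        bottom_genes={
            t: set(downstream[t][-1]) if downstream[t] else {t} for t in targets
        },
        decoys=dict(decoys),
    )
    for t in targets:
        all_bottom |= truth.bottom_genes[t]

    for rec in records:
        gene = rec.gene_id
        doms: set[str] = set()
        if gene in all_bottom:
            doms.add(SIGNAL_DOMAIN)
        if rng.random() < 0.8:
            picks = rng.integers(len(pool), size=int(rng.integers(1, 4)))
            doms.update(pool[p] for p in picks)
        # the signal domain stays rare outside bottom genes: background
        # carriers come only from the deterministic trickle below
        if gene.startswith("bgd-") and int(gene[4:]) % 37 == 0:
            doms.add(SIGNAL_DOMAIN)
        if doms:
            db.domains[gene] = doms

    return records, db, truth


def write_fixture(spec: FixtureSpec, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the fixture as the flat-file tables the readers consume.

    Also writes ``ground_truth.tsv`` (long format: target, gene, role).
    Byte-identical across runs with the same spec.
    """
    records, db, truth = generate_fixture(spec)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {"expression": os.path.join(out_dir, "expression.tsv")}
    write_expression_table(records, paths["expression"])

    def dump(name: str, header: list[str], rows: list[tuple]) -> None:
        paths[name] = os.path.join(out_dir, f"{name}.tsv")
        with open(paths[name], "w", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(v) for v in row) + "\n")

    dump("tf_list", ["gene_id"], [(g,) for g in sorted(db.tf_genes)])
    dump(
        "stages",
        ["gene_id", "stage"],
        [(g, s) for g in sorted(db.stages) for s in sorted(db.stages[g])],
    )
    dump(
        "phenotypes",
        ["gene_id", "phenotype"],
        [(g, p) for g in sorted(db.phenotypes) for p in sorted(db.phenotypes[g])],
    )
    dump(
        "interactions",
        ["source", "target", "edge_type", "sign"],
        [(e.source, e.target, e.edge_type, e.sign) for e in db.interactions],
    )
    dump(
        "gene_domains",
        ["gene_id", "domain_acc"],
        [(g, d) for g in sorted(db.domains) for d in sorted(db.domains[g])],
    )
    dump(
        "domain_categories",
        ["domain_acc", "category"],
        [(d, c) for d, c in sorted(db.domain_categories.items())],
    )
    dump(
        "ground_truth",
        ["target", "gene_id", "role"],
        [
            (t, g, "bottom" if g in truth.bottom_genes[t] else "member")
            for t in sorted(truth.direct_targets)
            for g in sorted(truth.cascade_membership[t])
        ],
    )
    return paths
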