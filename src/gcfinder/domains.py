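"""Bottom-gene domain over-representation and functional-category scoring.

The over-representation statistic is the classic PANTHER-style binomial
tail: with n bottom genes carrying at least one domain annotation and a
background frequency p0 = K/N_bg for a given domain, the p-value is
P(X >= k) for X ~ Binomial(n, p0). Fisher's exact test (hypergeometric,
sampling without replacement) is available as an alternative.

Cascades whose significant bottom-gene domains include a
transcription-related domain can be filtered out: such a cascade would be
acting only after the early-embryo stage, which is outside the biological
window of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as sps

from .io import AnnotationDB
from .cascade import Cascade

__all__ = [
    "EnrichmentResult",
    "CategoryScore",
    "domain_enrichment",
    "filter_transcription_cascades",
    "categorize_domains",
    "DEFAULT_ALPHA",
    "DEFAULT_CATEGORY_ORDER",
]

DEFAULT_ALPHA = 0.05

#: canonical reporting order for functional categories; unlisted categories
#: sort alphabetically after these, with Others and Unknown always last.
DEFAULT_CATEGORY_ORDER = (
    "Transcription",
    "Signal transduction",
    "Development",
    "Cell cycle",
    "Cell division",
    "DNA replication",
    "Transport",
)


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation statistics for one domain.

    k of n annotated bottom genes carry the domain; K of N_bg annotated
    background genes carry it. ``genes`` lists the bottom genes hit.
    """

    domain_acc: str
    k: int
    n: int
    K: int
    N_bg: int
    p_value: float
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n <= self.N_bg and 0 <= self.K <= self.N_bg):
            raise ValueError(f"inconsistent counts for {self.domain_acc}")
        if self.k > self.K:
            raise ValueError(
                f"{self.domain_acc}: bottom-gene hits exceed background hits"
            )
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of (0, 1] for {self.domain_acc}")


@dataclass(frozen=True)
class CategoryScore:
    category: str
    score: int


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0)."""
    if k <= 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p0))


def fisher_tail(k: int, n: int, K: int, N_bg: int) -> float:
    """One-sided Fisher exact p-value for over-representation."""
    table = [[k, n - k], [K - k, (N_bg - n) - (K - k)]]
    return float(sps.fisher_exact(table, alternative="greater")[1])


def domain_enrichment(
    bottom_genes: set[str],
    annotations: AnnotationDB,
    background: set[str],
    test: str = "binomial",
) -> list[EnrichmentResult]:
    """Score every domain present among the bottom genes.

    ``background`` is the gene universe (typically all genes of the input
    expression table); only genes with at least one domain annotation enter
    the counts on either side. Results are sorted by p-value, ties broken
    by accession.
    """
    if test not in ("binomial", "fisher"):
        raise ValueError(f"unknown enrichment test {test!r}")
    if not background >= bottom_genes:
        raise ValueError("background must contain all bottom genes")
    bg_annotated = {g for g in background if annotations.domains_of(g)}
    if not bg_annotated:
        raise ValueError("no background gene carries a domain annotation")
    bottom_annotated = {g for g in bottom_genes if annotations.domains_of(g)}
    if not bottom_genes:
        return []

    n = len(bottom_annotated)
    N_bg = len(bg_annotated)

    candidate_domains: set[str] = set()
    for g in bottom_annotated:
        candidate_domains |= annotations.domains_of(g)

    results = []
    for dom in sorted(candidate_domains):
        hits = frozenset(g for g in bottom_annotated if dom in annotations.domains_of(g))
        k = len(hits)
        K = sum(1 for g in bg_annotated if dom in annotations.domains_of(g))
        if test == "binomial":
            p = binomial_tail(k, n, K / N_bg)
        else:
            p = fisher_tail(k, n, K, N_bg)
        # clamp numerical round-off into (0, 1]
        p = min(max(p, math.ulp(0.0)), 1.0)
        results.append(EnrichmentResult(dom, k, n, K, N_bg, p, hits))
    results.sort(key=lambda r: (r.p_value, r.domain_acc))
    return results


def filter_transcription_cascades(
    cascades: list[Cascade],
    enrichments: dict[str, list[EnrichmentResult]],
    transcription_domains: set[str],
    alpha: float = DEFAULT_ALPHA,
    log: list[tuple[str, str]] | None = None,
) -> list[Cascade]:
    """Drop cascades whose significant bottom-gene domains include a
    transcription-related domain.

    ``enrichments`` maps cascade_id to that cascade's enrichment results.
    Each removal is recorded in ``log`` (if given) as
    ``(cascade_id, triggering accession)``.
    """
    kept = []
    for c in cascades:
        trigger = None
        for r in enrichments.get(c.cascade_id, []):
            if r.p_value < alpha and r.domain_acc in transcription_domains:
                trigger = r.domain_acc
                break
        if trigger is None:
            kept.append(c)
        elif log is not None:
            log.append((c.cascade_id, trigger))
    return kept


def _category_sort_key(category: str) -> tuple:
    if category in DEFAULT_CATEGORY_ORDER:
        return (0, DEFAULT_CATEGORY_ORDER.index(category), category)
    if category == "Others":
        return (2, 0, category)
    if category == "Unknown":
        return (3, 0, category)
    return (1, 0, category)


def categorize_domains(
    enrichments: list[EnrichmentResult],
    category_map: dict[str, str],
    alpha: float = DEFAULT_ALPHA,
    min_score: int = 1,
) -> list[CategoryScore]:
    """Aggregate significant domains into functional-category scores.

    A category's score is the number of distinct bottom genes hit by its
    significant (p < alpha) domains. Domains without a category mapping are
    tallied under "Unknown"; categories scoring below ``min_score`` are
    folded into "Others". Output follows the canonical category order with
    Others and Unknown last.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    genes_by_category: dict[str, set[str]] = {}
    for r in enrichments:
        if r.p_value >= alpha:
            continue
        cat = category_map.get(r.domain_acc, "Unknown")
        genes_by_category.setdefault(cat, set()).update(r.genes)

    scores: dict[str, int] = {}
    folded = 0
    for cat, genes in genes_by_category.items():
        score = len(genes)
        if cat != "Others" and cat != "Unknown" and score < min_score:
            folded += score
        else:
            scores[cat] = scores.get(cat, 0) + score
    if folded:
        scores["Others"] = scores.get("Others", 0) + folded

    return [
        CategoryScore(cat, scores[cat])
        for cat in sorted(scores, key=_category_sort_key)
    ]
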