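import pytest

from gcfinder import AnnotationDB, ExpressionRecord, InteractionEdge
from gcfinder.fixtures import FixtureSpec, generate_fixture


def make_db(
    tf_genes=(),
    stages=None,
    phenotypes=None,
    interactions=(),
    domains=None,
    domain_categories=None,
) -> AnnotationDB:
    """Small-literal AnnotationDB builder for toy cases."""
    return AnnotationDB(
        tf_genes=set(tf_genes),
        stages={g: set(v) for g, v in (stages or {}).items()},
        phenotypes={g: set(v) for g, v in (phenotypes or {}).items()},
        interactions=[InteractionEdge(*e) for e in interactions],
        domains={g: set(v) for g, v in (domains or {}).items()},
        domain_categories=dict(domain_categories or {}),
    )


def records_from_ratios(ratios) -> list[ExpressionRecord]:
    """Expression records with wt=1 so mutant level equals the ratio."""
    return [ExpressionRecord(f"g{i}", 1.0, r) for i, r in enumerate(ratios)]


@pytest.fixture(scope="session")
def planted():
    """The standard planted dataset: 200 genes, 3 targets, depth 4."""
    spec = FixtureSpec(n_genes=200, n_direct_targets=3, cascade_depth=4, seed=7)
    records, db, truth = generate_fixture(spec)
    return spec, records, db, truth
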