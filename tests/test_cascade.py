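import numpy as np
import pytest

from gcfinder import (
    FluctuationClassification,
    InteractionEdge,
    build_all_cascades,
    expand_cascade,
    find_bottom_genes,
    find_direct_targets,
)
from gcfinder.cascade import Cascade
from conftest import make_db

EMB = frozenset({"early embryo", "embryo"})


def classification(stable=(), fluctuating=(), boundary=(), undefined=()):
    return FluctuationClassification(
        frozenset(stable), frozenset(fluctuating), frozenset(boundary), frozenset(undefined)
    )


def closure_oracle(root, edges, stage_ok, max_nodes=64):
    """Reachability by boolean matrix powers over the stage-respecting move
    graph — independent of the BFS implementation under test."""
    genes = sorted({g for e in edges for g in (e[0], e[1])} | {root})
    idx = {g: i for i, g in enumerate(genes)}
    moves = np.zeros((len(genes), len(genes)), dtype=bool)
    for s, t, etype in edges:
        if stage_ok(t):
            moves[idx[s], idx[t]] = True
        if etype != "regulatory" and stage_ok(s):
            moves[idx[t], idx[s]] = True
    reach = np.zeros(len(genes), dtype=bool)
    reach[idx[root]] = True
    for _ in range(len(genes)):
        reach = reach | (reach @ moves)
    return {g for g in genes if reach[idx[g]]}


class TestDirectTargets:
    def db(self):
        stages = {
            "qry": {"early embryo"},
            "hit": {"early embryo"},
            "wrong-stage": {"adult"},
            "not-tf": {"early embryo"},
            "wrong-phen": {"early embryo"},
        }
        phen = {
            "qry": {"lethal"},
            "hit": {"lethal", "slow growth"},
            "wrong-stage": {"lethal"},
            "not-tf": {"lethal"},
            "wrong-phen": {"dumpy"},
        }
        return make_db(
            tf_genes={"hit", "wrong-stage", "wrong-phen", "qry"},
            stages=stages,
            phenotypes=phen,
        )

    def test_only_gene_meeting_all_four_criteria_is_returned(self):
        cls = classification(stable={"hit", "wrong-stage", "not-tf", "wrong-phen"})
        assert find_direct_targets("qry", cls, self.db()) == ["hit"]

    def test_empty_tf_set_yields_no_targets(self):
        db = self.db()
        db.tf_genes = set()
        cls = classification(stable={"hit"})
        assert find_direct_targets("qry", cls, db) == []

    def test_query_gene_never_targets_itself(self):
        cls = classification(stable={"qry", "hit"})
        assert "qry" not in find_direct_targets("qry", cls, self.db())

    def test_unstable_gene_excluded(self):
        cls = classification(fluctuating={"hit"})
        assert find_direct_targets("qry", cls, self.db()) == []

    def test_query_without_stage_annotation_is_an_error(self):
        db = self.db()
        del db.stages["qry"]
        with pytest.raises(ValueError, match="life-stage"):
            find_direct_targets("qry", classification(stable={"hit"}), db)

    def test_min_phenotype_overlap_is_enforced(self):
        cls = classification(stable={"hit"})
        assert find_direct_targets("qry", cls, self.db(), min_phenotype_overlap=2) == []


class TestExpandCascade:
    def test_isolated_root_is_its_own_bottom_gene(self):
        db = make_db(stages={"a": {"embryo"}})
        c = expand_cascade("a", db)
        assert c.nodes == {"a"} and c.bottom_genes == {"a"}

    def test_cycle_terminates_and_keeps_all_edges(self):
        edges = [
            ("a", "b", "regulatory", "positive"),
            ("b", "c", "regulatory", "positive"),
            ("c", "a", "regulatory", "negative"),
        ]
        db = make_db(
            stages={g: {"embryo"} for g in "abc"},
            interactions=edges,
        )
        c = expand_cascade("a", db)
        assert c.nodes == {"a", "b", "c"}
        assert len(c.edges) == 3

    def test_stage_filter_drops_node_and_its_edge(self):
        db = make_db(
            stages={"a": {"embryo"}, "d": {"adult"}},
            interactions=[("a", "d", "regulatory", "positive")],
        )
        c = expand_cascade("a", db)
        assert c.nodes == {"a"} and c.edges == []

    def test_undirected_edges_traverse_both_ways(self):
        db = make_db(
            stages={"a": {"embryo"}, "b": {"embryo"}},
            interactions=[("b", "a", "physical", "unknown")],
        )
        assert expand_cascade("a", db).nodes == {"a", "b"}

    def test_regulatory_edges_are_not_followed_upstream(self):
        db = make_db(
            stages={"a": {"embryo"}, "up": {"embryo"}},
            interactions=[("up", "a", "regulatory", "positive")],
        )
        assert expand_cascade("a", db).nodes == {"a"}

    def test_root_failing_stage_filter_is_an_error(self):
        db = make_db(stages={"a": {"adult"}})
        with pytest.raises(ValueError, match="allowed"):
            expand_cascade("a", db)

    def test_tier_reflects_early_embryo_annotation(self):
        db = make_db(
            stages={"a": {"early embryo"}, "b": {"embryo"}},
            interactions=[("a", "b", "regulatory", "positive")],
        )
        c = expand_cascade("a", db)
        assert c.tiers == {"a": "early_embryo", "b": "embryo"}

    def test_enlarging_allowed_stages_never_shrinks_the_cascade(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 10))
            genes = [f"g{i}" for i in range(n)]
            edges = []
            for _ in range(int(rng.integers(1, 2 * n))):
                s, t = rng.integers(n, size=2)
                kind = ["regulatory", "genetic", "physical"][int(rng.integers(3))]
                if genes[s] != genes[t]:
                    edges.append((genes[s], genes[t], kind, "unknown"))
            stages = {
                g: {["early embryo", "embryo", "larva"][int(rng.integers(3))]}
                for g in genes
            }
            stages[genes[0]] = {"early embryo"}
            db = make_db(stages=stages, interactions=edges)
            small = expand_cascade(genes[0], db, allowed_stages={"early embryo"})
            big = expand_cascade(
                genes[0], db, allowed_stages={"early embryo", "embryo"}
            )
            assert small.nodes <= big.nodes


class TestBottomGenes:
    def chain(self, *edges, nodes=None):
        nodes = set(nodes or {g for e in edges for g in e[:2]})
        return Cascade(
            "c", "q", sorted(nodes)[0], nodes,
            [InteractionEdge(*e) for e in edges],
            {g: "embryo" for g in nodes},
        )

    def test_chain_leaf(self):
        c = self.chain(("a", "b", "regulatory", "positive"),
                       ("b", "c", "regulatory", "positive"))
        assert find_bottom_genes(c) == {"c"}

    def test_fan_out_has_two_leaves(self):
        c = self.chain(("a", "b", "regulatory", "positive"),
                       ("a", "c", "regulatory", "positive"))
        assert find_bottom_genes(c) == {"b", "c"}

    def test_cycle_with_exit_bottoms_at_the_exit(self):
        c = self.chain(("a", "b", "regulatory", "positive"),
                       ("b", "a", "regulatory", "positive"),
                       ("a", "c", "regulatory", "positive"))
        assert find_bottom_genes(c) == {"c"}

    def test_pure_cycle_falls_back_to_terminal_scc(self):
        c = self.chain(("a", "b", "regulatory", "positive"),
                       ("b", "a", "regulatory", "positive"))
        assert find_bottom_genes(c) == {"a", "b"}

    def test_physical_edges_do_not_count_as_downstream(self):
        c = self.chain(("a", "b", "regulatory", "positive"),
                       ("b", "c", "physical", "unknown"))
        assert find_bottom_genes(c) == {"b", "c"}


class TestOracleEquivalence:
    def test_node_sets_match_transitive_closure_on_random_digraphs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            genes = [f"g{i}" for i in range(n)]
            embryonic = {g for g in genes if rng.random() < 0.7}
            embryonic.add(genes[0])
            edges = []
            for _ in range(int(rng.integers(0, 3 * n))):
                s, t = rng.integers(n, size=2)
                if s == t:
                    continue
                kind = ["regulatory", "genetic", "physical"][int(rng.integers(3))]
                edges.append((genes[s], genes[t], kind))
            db = make_db(
                stages={g: {"embryo"} if g in embryonic else {"adult"} for g in genes},
                interactions=[(s, t, k, "unknown") for s, t, k in edges],
            )
            got = expand_cascade(genes[0], db).nodes
            want = closure_oracle(genes[0], edges, lambda g: g in embryonic)
            assert got == want


class TestBuildAll:
    def test_zero_targets_gives_empty_list(self):
        db = make_db(stages={"qry": {"early embryo"}})
        assert build_all_cascades("qry", classification(), db) == []

    def test_planted_targets_each_get_one_cascade(self, planted):
        _, records, db, truth = planted
        from gcfinder import classify_genes, compute_ratios, fluctuation_stats

        ratios = compute_ratios(records)
        cls = classify_genes(ratios, fluctuation_stats(ratios))
        cascades = build_all_cascades("qry-1", cls, db)
        assert [c.root_target for c in cascades] == sorted(truth.direct_targets)

    def test_repeated_runs_identical(self, planted):
        _, records, db, truth = planted
        from gcfinder import classify_genes, compute_ratios, fluctuation_stats

        ratios = compute_ratios(records)
        cls = classify_genes(ratios, fluctuation_stats(ratios))
        a = build_all_cascades("qry-1", cls, db)
        b = build_all_cascades("qry-1", cls, db)
        assert [(c.cascade_id, sorted(c.nodes), c.edges) for c in a] == [
            (c.cascade_id, sorted(c.nodes), c.edges) for c in b
        ]
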