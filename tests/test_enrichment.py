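import numpy as np
import pandas as pd
import pytest

from ledkit.enrichment import (
    AnnotationSet,
    GoDag,
    filter_significant,
    ks_enrichment,
    parse_obo_subset,
    propagate_annotations,
    read_annotations,
)
from ledkit.simulate import simulate_go, write_obo

CHAIN_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: a
namespace: biological_process

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0000001 ! a

[Term]
id: GO:0000003
name: c
namespace: biological_process
is_a: GO:0000002 ! b

[Term]
id: GO:0000004
name: gone
namespace: biological_process
is_obsolete: true
"""


class TestParseObo:
    def test_chain_and_obsolete(self, write_tsv):
        dag = parse_obo_subset(write_tsv("chain.obo", CHAIN_OBO))
        assert len(dag) == 3
        assert dag.graph.number_of_edges() == 2
        assert "GO:0000004" not in dag
        assert dag.ancestors("GO:0000003") == {"GO:0000002", "GO:0000001"}

    def test_cycle_detected(self, write_tsv):
        cyc = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: a\nnamespace: biological_process\n"
            "is_a: GO:2 ! b\n\n"
            "[Term]\nid: GO:2\nname: b\nnamespace: biological_process\n"
            "is_a: GO:1 ! a\n"
        )
        with pytest.raises(ValueError, match="cycle"):
            parse_obo_subset(write_tsv("cyc.obo", cyc))

    def test_dangling_target(self, write_tsv):
        bad = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: a\nnamespace: biological_process\n"
            "is_a: GO:9 ! ghost\n"
        )
        with pytest.raises(ValueError, match="dangling"):
            parse_obo_subset(write_tsv("bad.obo", bad))

    def test_round_trip_through_writer(self, tmp_path):
        scores = pd.Series(np.linspace(1, 0, 50), index=[f"g{i}" for i in range(50)])
        dag, _, _ = simulate_go(scores, n_background_terms=10, seed=0)
        p = tmp_path / "rt.obo"
        write_obo(dag, p)
        back = parse_obo_subset(p)
        assert set(back.terms) == set(dag.terms)
        assert set(back.graph.edges) == set(dag.graph.edges)


class TestPropagate:
    def _chain_dag(self, write_tsv):
        return parse_obo_subset(write_tsv("chain.obo", CHAIN_OBO))

    def test_chain_closure(self, write_tsv):
        dag = self._chain_dag(write_tsv)
        direct = AnnotationSet({"g": frozenset({"GO:0000003"})})
        prop = propagate_annotations(dag, direct)
        assert prop.mapping["g"] == {"GO:0000003", "GO:0000002", "GO:0000001"}
        assert prop.propagated

    def test_idempotent(self, write_tsv):
        dag = self._chain_dag(write_tsv)
        direct = AnnotationSet({"g": frozenset({"GO:0000002"})})
        once = propagate_annotations(dag, direct)
        twice = propagate_annotations(dag, once)
        assert once.mapping == twice.mapping

    def test_unknown_term_named(self, write_tsv):
        dag = self._chain_dag(write_tsv)
        with pytest.raises(KeyError, match="GO:9999999"):
            propagate_annotations(
                dag, AnnotationSet({"g": frozenset({"GO:9999999"})})
            )

    def test_matches_transitive_closure_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(11)
        for trial in range(5):
            # random DAG on 12 nodes: edges only low -> high index
            n = 12
            g = nx.DiGraph()
            names = [f"GO:{i:07d}" for i in range(n)]
            g.add_nodes_from(names)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.2:
                        g.add_edge(names[i], names[j])
            dag = GoDag(
                graph=g,
                terms={t: {"name": t, "namespace": "bp"} for t in names},
            )
            closure = nx.transitive_closure(g)
            term = names[int(rng.integers(0, n))]
            prop = propagate_annotations(
                dag, AnnotationSet({"g": frozenset({term})})
            )
            oracle = {term} | set(closure.successors(term))
            assert prop.mapping["g"] == oracle

    def test_parent_counts_dominate_children(self):
        scores = pd.Series(
            np.linspace(1, 0, 200), index=[f"g{i}" for i in range(200)]
        )
        dag, direct, _ = simulate_go(scores, n_background_terms=30, seed=1)
        prop = propagate_annotations(dag, direct)
        by_term = prop.genes_by_term()
        for child, parent in dag.graph.edges:
            assert len(by_term.get(child, set())) <= len(
                by_term.get(parent, set())
            )


def _flat_dag(n_terms: int):
    """Independent terms under one root (no topology effects)."""
    import networkx as nx

    g = nx.DiGraph()
    terms = {"GO:0000000": {"name": "root", "namespace": "biological_process"}}
    g.add_node("GO:0000000")
    for i in range(1, n_terms + 1):
        t = f"GO:{i:07d}"
        terms[t] = {"name": t, "namespace": "biological_process"}
        g.add_edge(t, "GO:0000000")
    return GoDag(graph=g, terms=terms)


class TestKsEnrichment:
    def test_planted_top_term_ranks_first(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i:04d}" for i in range(1000)]
        scores = pd.Series(rng.random(1000), index=genes)
        dag, direct, planted = simulate_go(
            scores, n_background_terms=50, planted_term_size=20, seed=2
        )
        prop = propagate_annotations(dag, direct)
        rows = ks_enrichment(dag, prop, scores.to_dict(), algorithm="classic")
        assert rows.iloc[0]["term"] == planted
        assert rows.iloc[0]["p_value"] < 1e-3

    def test_node_size_threshold(self):
        dag = _flat_dag(1)
        genes = [f"g{i}" for i in range(100)]
        scores = dict(zip(genes, np.linspace(0, 1, 100)))
        ann = propagate_annotations(
            dag,
            AnnotationSet({g: frozenset({"GO:0000001"}) for g in genes[:9]}),
        )
        rows = ks_enrichment(dag, ann, scores, node_size=10)
        assert rows.empty

    def test_elim_equals_classic_when_nothing_passes(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i:04d}" for i in range(300)]
        scores = pd.Series(rng.random(300), index=genes)
        dag, direct, _ = simulate_go(
            scores, n_background_terms=20, planted_term_size=20, seed=3
        )
        prop = propagate_annotations(dag, direct)
        # alpha_elim = 0 can never be passed (strict inequality)
        elim = ks_enrichment(dag, prop, scores.to_dict(), algorithm="elim",
                             alpha_elim=0.0)
        classic = ks_enrichment(dag, prop, scores.to_dict(), algorithm="classic")
        pd.testing.assert_frame_equal(
            elim.drop(columns="algorithm"), classic.drop(columns="algorithm")
        )

    def test_elim_removes_child_signal_from_parent(self):
        # parent annotated only via a significant child: elim should null it
        import networkx as nx

        g = nx.DiGraph()
        terms = {}
        for t in ("GO:0000001", "GO:0000002"):
            terms[t] = {"name": t, "namespace": "biological_process"}
            g.add_node(t)
        g.add_edge("GO:0000002", "GO:0000001")  # child -> parent
        dag = GoDag(graph=g, terms=terms)
        genes = [f"g{i:03d}" for i in range(200)]
        scores = dict(zip(genes, np.linspace(1.0, 0.0, 200)))
        direct = AnnotationSet(
            {g_: frozenset({"GO:0000002"}) for g_ in genes[:15]}
        )
        prop = propagate_annotations(dag, direct)
        elim = ks_enrichment(dag, prop, scores, algorithm="elim").set_index("term")
        classic = ks_enrichment(dag, prop, scores, algorithm="classic").set_index("term")
        assert classic.loc["GO:0000001", "p_value"] < 0.01
        assert elim.loc["GO:0000002", "p_value"] < 0.01
        assert elim.loc["GO:0000001", "p_value"] == 1.0

    def test_missing_score_for_annotated_gene(self):
        dag = _flat_dag(1)
        ann = propagate_annotations(
            dag, AnnotationSet({"ghost": frozenset({"GO:0000001"})})
        )
        with pytest.raises(ValueError, match="ghost"):
            ks_enrichment(dag, ann, {"g1": 0.5})


class TestFilterSignificant:
    def _rows(self, ps):
        return pd.DataFrame(
            {"term": [f"GO:{i}" for i in range(len(ps))], "p_value": ps}
        )

    def test_strict_boundary(self):
        out = filter_significant(self._rows([0.01, 0.0099]), alpha=0.01)
        assert list(out["p_value"]) == [0.0099]

    def test_empty_in_empty_out(self):
        assert filter_significant(self._rows([])).empty

    def test_retains_and_sorts(self):
        out = filter_significant(self._rows([0.05, 0.001]), alpha=0.01)
        assert list(out["p_value"]) == [0.001]


def test_read_annotations_round_trip(write_tsv):
    p = write_tsv("ann.tsv", "gene\tterm\ng1\tGO:1\ng1\tGO:2\ng2\tGO:1\n")
    ann = read_annotations(p)
    assert ann.mapping == {
        "g1": frozenset({"GO:1", "GO:2"}),
        "g2": frozenset({"GO:1"}),
    }
    assert not ann.propagated
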