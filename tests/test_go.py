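from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gammatc import go as go_mod
from gammatc.errors import DataError
from gammatc.simulate import SimConfig, generate_go


def toy_graph(extra_edges=()):
    """Linear worked chain plus optional extra edges."""
    terms = pd.DataFrame([
        {"id": "root", "name": "biological_process", "namespace": "biological_process"},
        {"id": "sig", "name": "signaling", "namespace": "biological_process"},
        {"id": "cyt", "name": "cytokine production", "namespace": "biological_process"},
        {"id": "ifn", "name": "type I interferon production", "namespace": "biological_process"},
    ])
    edges = pd.DataFrame(
        [{"child": "sig", "parent": "root"},
         {"child": "cyt", "parent": "sig"},
         {"child": "ifn", "parent": "cyt"}]
        + [{"child": c, "parent": p} for c, p in extra_edges])
    return go_mod.GOGraph.from_tables(terms, edges)


def random_dag(rng, n_nodes):
    """Random rooted DAG: each node gets >=1 parent among earlier nodes."""
    terms = pd.DataFrame([{"id": f"t{i}", "name": f"term {i}",
                           "namespace": "biological_process"}
                          for i in range(n_nodes)])
    edges = []
    for i in range(1, n_nodes):
        parents = rng.choice(i, size=min(i, 1 + rng.integers(2)),
                             replace=False)
        edges.extend({"child": f"t{i}", "parent": f"t{int(p)}"}
                     for p in parents)
    return go_mod.GOGraph.from_tables(terms, pd.DataFrame(edges))


class TestComputeLevels:
    def test_worked_chain_levels(self):
        levels, _ = go_mod.compute_levels(toy_graph())
        assert [levels[t] for t in ("root", "sig", "cyt", "ifn")] == [1, 2, 3, 4]

    def test_multi_parent_takes_shortest_path(self):
        terms = pd.DataFrame([
            {"id": t, "name": t, "namespace": "biological_process"}
            for t in ("root", "a2", "b2", "b3", "x")])
        edges = pd.DataFrame([
            {"child": "a2", "parent": "root"},
            {"child": "b2", "parent": "root"},
            {"child": "b3", "parent": "b2"},
            {"child": "x", "parent": "a2"},   # level-2 parent
            {"child": "x", "parent": "b3"},   # level-3 parent
        ])
        g = go_mod.GOGraph.from_tables(terms, edges)
        levels, _ = go_mod.compute_levels(g)
        assert levels["x"] == 3

    def test_matches_bfs_oracle_on_random_dags(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            g = random_dag(rng, int(rng.integers(5, 30)))
            levels, disconnected = go_mod.compute_levels(g)
            assert not disconnected
            oracle = nx.single_source_shortest_path_length(
                g.graph.reverse(), g.root)
            assert levels == {t: d + 1 for t, d in oracle.items()}


class TestAnnotateGenes:
    def test_leaf_annotation_carries_all_ancestors(self):
        g = toy_graph()
        out = go_mod.annotate_genes({"gene": {"ifn"}}, g)
        assert out["gene"] == {"ifn", "cyt", "sig", "root"}

    def test_root_only_stays_root_only(self):
        out = go_mod.annotate_genes({"gene": {"root"}}, toy_graph())
        assert out["gene"] == {"root"}

    def test_unknown_terms_are_skipped(self):
        out = go_mod.annotate_genes({"gene": {"nope", "sig"}}, toy_graph())
        assert out["gene"] == {"sig", "root"}

    def test_closure_matches_networkx_ancestry_oracle(self):
        rng = np.random.default_rng(8)
        g = random_dag(rng, 25)
        nodes = list(g.graph.nodes)
        direct = {f"gene{i}": set(rng.choice(nodes, size=3, replace=False))
                  for i in range(10)}
        out = go_mod.annotate_genes(direct, g)
        for gene, terms in direct.items():
            expect = set(terms)
            for t in terms:
                expect |= nx.descendants(g.graph, t)
            assert out[gene] == expect


class TestUmbrellaAbundance:
    UMBRELLAS = {"t1": "U1", "t2": "U1", "t3": "U2"}

    def test_two_terms_same_umbrella_count_once(self):
        ann = {"g": {"t1", "t2"}}
        assert go_mod.umbrella_abundance({"g"}, ann, self.UMBRELLAS)["U1"] == 1

    def test_gene_counts_in_multiple_umbrellas(self):
        ann = {"g": {"t1", "t3"}}
        counts = go_mod.umbrella_abundance({"g"}, ann, self.UMBRELLAS)
        assert counts == {"U1": 1, "U2": 1}
        assert sum(counts.values()) > 1  # exceeds the one-gene cluster size

    def test_empty_cluster_all_zero(self):
        counts = go_mod.umbrella_abundance(set(), {}, self.UMBRELLAS)
        assert set(counts.values()) == {0}

    def test_adding_a_gene_never_decreases_counts(self):
        ann = {"g1": {"t1"}, "g2": {"t3"}}
        before = go_mod.umbrella_abundance({"g1"}, ann, self.UMBRELLAS)
        after = go_mod.umbrella_abundance({"g1", "g2"}, ann, self.UMBRELLAS)
        assert all(after[u] >= before[u] for u in before)


class TestOverrepresentation:
    def test_cluster_equals_background_is_null(self):
        ann = {f"g{i}": ({"t1"} if i < 4 else {"t3"}) for i in range(10)}
        genes = set(ann)
        res = go_mod.overrepresentation(genes, genes, ann,
                                        TestUmbrellaAbundance.UMBRELLAS)
        assert np.allclose(res["enrichment_factor"], 1.0)
        assert np.allclose(res["p"], 1.0)

    def test_matches_exhaustive_subset_enumeration(self):
        # N=20, K=5 annotated, n=5 cluster, k=4 observed
        background = [f"g{i}" for i in range(20)]
        ann = {g: ({"t1"} if i < 5 else {"t3"})
               for i, g in enumerate(background)}
        cluster = set(background[:4]) | {background[10]}  # k=4
        res = go_mod.overrepresentation(cluster, set(background), ann,
                                        TestUmbrellaAbundance.UMBRELLAS)
        p_impl = float(res.loc[res["umbrella"] == "U1", "p"].iloc[0])
        annotated = set(background[:5])
        hits = sum(1 for sub in combinations(background, 5)
                   if len(set(sub) & annotated) >= 4)
        total = sum(1 for _ in combinations(background, 5))
        assert p_impl == pytest.approx(hits / total, abs=1e-12)

    def test_zero_overlap_gives_zero_enrichment(self):
        background = [f"g{i}" for i in range(100)]
        ann = {g: ({"t1"} if i < 10 else {"t3"})
               for i, g in enumerate(background)}
        cluster = set(background[50:60])  # none annotated with t1
        res = go_mod.overrepresentation(cluster, set(background), ann,
                                        TestUmbrellaAbundance.UMBRELLAS)
        row = res[res["umbrella"] == "U1"].iloc[0]
        assert row["enrichment_factor"] == 0.0 and row["p"] == pytest.approx(1.0)

    def test_cluster_outside_background_rejected(self):
        with pytest.raises(DataError):
            go_mod.overrepresentation({"x"}, {"y"}, {}, {"t": "U"})


class TestWordcloudSizes:
    @pytest.mark.parametrize("abund,expected", [
        ({"a": 1, "b": 5}, {"a": 10.0, "b": 30.0}),
        ({"a": 1, "b": 3, "c": 5}, {"a": 10.0, "b": 20.0, "c": 30.0}),
        ({"a": 4, "b": 4, "c": 4}, {"a": 20.0, "b": 20.0, "c": 20.0}),
    ])
    def test_linear_scaling_with_degenerate_midpoint(self, abund, expected):
        assert go_mod.wordcloud_sizes(abund) == pytest.approx(expected)


class TestWordMine:
    def test_substring_match_selects_gene(self):
        terms = pd.DataFrame([
            {"id": "root", "name": "biological_process",
             "namespace": "biological_process"},
            {"id": "apo", "name": "intrinsic apoptotic signaling pathway",
             "namespace": "biological_process"}])
        edges = pd.DataFrame([{"child": "apo", "parent": "root"}])
        g = go_mod.GOGraph.from_tables(terms, edges)
        ann = {"geneA": {"apo", "root"}, "geneB": {"root"}}
        assert go_mod.word_mine(ann, g, ("apopto",)) == {"geneA"}
        assert go_mod.word_mine(ann, g, ("lipid",)) == set()

    def test_planted_keyword_genes_exactly_recovered(self):
        bundle = generate_go(SimConfig(seed=21, n_genes=151),
                             n_keyword_genes=19)
        mined = go_mod.word_mine(bundle["annotation"], bundle["graph"])
        assert mined == bundle["keyword_genes"] and len(mined) == 19

    def test_keyword_union_distributes_over_mining(self):
        bundle = generate_go(SimConfig(seed=22, n_genes=60))
        g, ann = bundle["graph"], bundle["annotation"]
        a, b = ("apoptosis", "necroptosis"), ("DNA repair",)
        assert (go_mod.word_mine(ann, g, a + b)
                == go_mod.word_mine(ann, g, a) | go_mod.word_mine(ann, g, b))
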