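"""Tissue-specific interactomes, disease modules and the bipartite map."""

import math

import networkx as nx
import numpy as np
import pytest

from tissuemod.data_io import DiseaseGeneSet
from tissuemod.disease_tissue import (
    build_disease_tissue_network,
    build_tissue_interactome,
    disease_module_in_tissue,
    filter_diseases,
    gwas_expression_filter,
    links_to_table,
    module_genes_in_tissue,
)
from tissuemod.expression import TissueGeneSet, expressed_gene_set, expression_zscores
from tissuemod.synthetic import SyntheticConfig, generate_interactome


def _tissue_set(genes, tissue="t0"):
    return TissueGeneSet(tissue=tissue, genes=frozenset(genes), threshold=1.0)


class TestTissueInteractome:
    def test_all_expressed_gives_identical_graph(self, triangle):
        tg = build_tissue_interactome(triangle, _tissue_set(triangle.nodes))
        assert set(tg.edges) == set(triangle.edges)

    def test_nothing_expressed_gives_empty_graph(self, triangle):
        tg = build_tissue_interactome(triangle, _tissue_set([]))
        assert tg.number_of_nodes() == 0

    def test_induced_edges_match_filter_oracle(self):
        g = generate_interactome(SyntheticConfig(n_genes=100), seed=1)
        expressed = set(sorted(g.nodes)[::3])
        tg = build_tissue_interactome(g, _tissue_set(expressed))
        oracle = {
            tuple(sorted((u, v)))
            for u, v in g.edges
            if u in expressed and v in expressed
        }
        assert {tuple(sorted(e)) for e in tg.edges} == oracle
        assert set(tg.nodes) == expressed & set(g.nodes)


class TestDiseaseModule:
    def test_no_expressed_gene_is_untestable(self, triangle):
        d = DiseaseGeneSet("D", frozenset({"zz"}))
        link = disease_module_in_tissue(triangle, d, n_reps=10, seed=0)
        assert link.s_total == 0 and not link.testable and not link.significant

    def test_single_expressed_gene_is_untestable(self, triangle):
        d = DiseaseGeneSet("D", frozenset({"a", "zz"}))
        link = disease_module_in_tissue(triangle, d, n_reps=10, seed=0)
        assert link.s_total == 1 and not link.testable

    def test_planted_connected_module_is_significant(self):
        g = generate_interactome(SyntheticConfig(n_genes=300), seed=2)
        # a clique planted on sparse background: fully expressed and connected
        clique = [f"M{i}" for i in range(8)]
        g.add_edges_from(
            (a, b) for i, a in enumerate(clique) for b in clique[i + 1 :]
        )
        g.add_edge(clique[0], sorted(n for n in g.nodes if not n.startswith("M"))[0])
        d = DiseaseGeneSet("D", frozenset(clique))
        link = disease_module_in_tissue(g, d, n_reps=500, seed=3)
        assert link.s == link.s_total == 8
        assert link.z >= 1.6 and link.significant

    def test_s_bounds(self):
        g = generate_interactome(SyntheticConfig(n_genes=100), seed=4)
        d = DiseaseGeneSet("D", frozenset(sorted(g.nodes)[:10]))
        link = disease_module_in_tissue(g, d, n_reps=50, seed=5)
        assert 1 <= link.s <= link.s_total <= d.n

    def test_same_seed_identical_z(self):
        g = generate_interactome(SyntheticConfig(n_genes=100), seed=4)
        d = DiseaseGeneSet("D", frozenset(sorted(g.nodes)[:10]))
        l1 = disease_module_in_tissue(g, d, n_reps=100, seed=6)
        l2 = disease_module_in_tissue(g, d, n_reps=100, seed=6)
        assert l1.z == pytest.approx(l2.z, abs=1e-12)

    def test_s_nonincreasing_in_expression_threshold(self, default_bundle):
        """Raising z_E shrinks the tissue graph, so S and S_total cannot grow."""
        sig = expression_zscores(default_bundle.expression)
        g = default_bundle.interactome
        d = default_bundle.disease_sets[0]
        tissue = default_bundle.truth.hosts[d.disease]
        previous = None
        for th in (1.0, 1.5, 2.0):
            ts = expressed_gene_set(sig, tissue, th, restrict_to=g)
            tg = build_tissue_interactome(g, ts)
            link = disease_module_in_tissue(tg, d, n_reps=10, seed=0, tissue=tissue)
            if previous is not None:
                assert link.s <= previous.s
                assert link.s_total <= previous.s_total
            previous = link


class TestBipartiteNetwork:
    def _link(self, disease, tissue, z):
        from tissuemod.disease_tissue import DiseaseTissueLink

        return DiseaseTissueLink(
            disease=disease, tissue=tissue, s=3, s_total=5,
            z=z, p=0.05, p_empirical=0.05,
            significant=z >= 1.6, testable=True,
        )

    def test_no_significant_pairs_gives_empty_network(self):
        links = [self._link("D1", "t1", 0.2), self._link("D2", "t1", -1.0)]
        net = build_disease_tissue_network(links)
        assert net.n_links == 0
        assert net.unlinked_diseases == ["D1", "D2"]

    def test_raising_threshold_never_adds_links(self):
        links = [
            self._link("D1", "t1", 2.5),
            self._link("D1", "t2", 1.7),
            self._link("D2", "t1", 1.61),
        ]
        lo = build_disease_tissue_network(links, z_sig=1.6)
        hi = build_disease_tissue_network(links, z_sig=2.0)
        lo_pairs = {(l.disease, l.tissue) for l in lo.links}
        hi_pairs = {(l.disease, l.tissue) for l in hi.links}
        assert hi_pairs <= lo_pairs

    def test_duplicate_pair_rejected(self):
        links = [self._link("D1", "t1", 2.0), self._link("D1", "t1", 2.1)]
        with pytest.raises(ValueError, match="duplicate"):
            build_disease_tissue_network(links)

    def test_degree_conservation(self):
        links = [
            self._link("D1", "t1", 2.0),
            self._link("D1", "t2", 2.0),
            self._link("D2", "t1", 2.0),
            self._link("D3", "t3", 0.0),
        ]
        net = build_disease_tissue_network(links)
        assert sum(net.disease_degree.values()) == net.n_links == 3
        assert sum(net.tissue_degree.values()) == net.n_links

    def test_mean_tissues_both_conventions(self):
        links = [
            self._link("D1", "t1", 2.0),
            self._link("D1", "t2", 2.0),
            self._link("D2", "t1", 2.0),
            self._link("D3", "t1", 0.0),
        ]
        net = build_disease_tissue_network(links)
        assert net.mean_tissues_per_disease(linked_only=True) == pytest.approx(1.5)
        assert net.mean_tissues_per_disease(linked_only=False) == pytest.approx(1.0)

    def test_links_table_has_bh_column(self):
        links = [self._link("D1", "t1", 2.0), self._link("D2", "t1", 0.5)]
        df = links_to_table(links)
        assert "q_bh" in df.columns
        assert (df["q_bh"] >= df["p"] - 1e-12).all()


class TestGwasFilter:
    @pytest.fixture
    def setup(self, default_bundle):
        bundle = default_bundle
        sig = expression_zscores(bundle.expression)
        d = bundle.disease_sets[0]
        tissue = bundle.truth.hosts[d.disease]
        ts = expressed_gene_set(sig, tissue, 1.0, restrict_to=bundle.interactome)
        tg = build_tissue_interactome(bundle.interactome, ts)
        return bundle, sig, d, tissue, tg

    def test_unexpressed_genes_never_in_module(self, setup):
        bundle, sig, d, tissue, tg = setup
        records = gwas_expression_filter(d, bundle.gwas, sig, tissue, tg)
        for r in records:
            if not r.expressed:
                assert not r.in_module

    def test_p_one_maps_to_zero(self, setup):
        bundle, sig, d, tissue, tg = setup
        gwas = {gene: 1.0 for gene in d.genes}
        records = gwas_expression_filter(d, gwas, sig, tissue, tg)
        assert all(r.neg_log10_p == 0.0 for r in records)

    def test_missing_gwas_entry_tolerated(self, setup):
        bundle, sig, d, tissue, tg = setup
        records = gwas_expression_filter(d, {}, sig, tissue, tg)
        assert all(r.neg_log10_p is None for r in records)

    def test_module_genes_carry_stronger_gwas_signal(self, setup):
        """Planted module members have higher -log10 p than the padding."""
        bundle, sig, d, tissue, tg = setup
        records = gwas_expression_filter(d, bundle.gwas, sig, tissue, tg)
        in_mod = [r.neg_log10_p for r in records if r.in_module]
        out_mod = [r.neg_log10_p for r in records if not r.in_module]
        assert np.mean(in_mod) > np.mean(out_mod)

    def test_sorted_by_significance(self, setup):
        bundle, sig, d, tissue, tg = setup
        records = gwas_expression_filter(d, bundle.gwas, sig, tissue, tg)
        ps = [r.neg_log10_p for r in records if r.neg_log10_p is not None]
        assert ps == sorted(ps, reverse=True)

    def test_module_matches_component_oracle(self, setup):
        bundle, sig, d, tissue, tg = setup
        module = module_genes_in_tissue(tg, d)
        sub = tg.subgraph(set(d.genes) & set(tg.nodes))
        oracle = max(nx.connected_components(sub), key=len) if sub else set()
        assert module == frozenset(oracle)


class TestFilterDiseases:
    def test_boundary_at_min_genes(self):
        small = DiseaseGeneSet("S", frozenset(f"g{i}" for i in range(19)))
        big = DiseaseGeneSet("B", frozenset(f"g{i}" for i in range(20)))
        kept = filter_diseases([small, big], min_genes=20)
        assert [s.disease for s in kept] == ["B"]

    def test_empty_input(self):
        assert filter_diseases([], min_genes=20) == []

    def test_survivor_count_matches_counting_oracle(self):
        rng = np.random.default_rng(7)
        sets = [
            DiseaseGeneSet(f"D{i}", frozenset(f"g{j}" for j in range(int(k))))
            for i, k in enumerate(rng.integers(5, 40, size=30))
        ]
        kept = filter_diseases(sets, min_genes=20)
        assert len(kept) == sum(1 for s in sets if s.n >= 20)
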