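"""Parsing, validation and round-trip behavior of the standard formats."""

import random

import dendropy
import pandas as pd
import pytest

from tissuemod import data_io
from tissuemod.data_io import ParseError
from tissuemod.synthetic import write_bundle


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestInteractome:
    def test_self_loops_and_duplicates_dropped(self, tmp_path):
        p = _write(tmp_path, "net.tsv", "a\tb\nb\tc\nb\ta\nc\tc\n")
        g = data_io.read_interactome(p)
        assert set(g.nodes) == {"a", "b", "c"}
        assert {tuple(sorted(e)) for e in g.edges} == {("a", "b"), ("b", "c")}

    def test_empty_file_is_an_error(self, tmp_path):
        p = _write(tmp_path, "net.tsv", "")
        with pytest.raises(ParseError):
            data_io.read_interactome(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, "net.tsv", "a\tb\nx\ty\tz\n")
        with pytest.raises(ParseError, match=":2"):
            data_io.read_interactome(p)

    def test_header_detected_and_skipped(self, tmp_path):
        p = _write(tmp_path, "net.tsv", "gene1\tgene2\na\tb\n")
        g = data_io.read_interactome(p)
        assert set(g.nodes) == {"a", "b"}

    def test_counts_match_stream_oracle(self, tmp_path, small_bundle):
        """A pre-deduped file loads to exactly the counts a line-count gives."""
        p = tmp_path / "net.tsv"
        data_io.write_interactome(small_bundle.interactome, p)
        lines = [l for l in p.read_text().splitlines()[1:] if l.strip()]
        n_edges_oracle = len(lines)
        n_nodes_oracle = len({f for l in lines for f in l.split("\t")})
        g = data_io.read_interactome(p)
        assert g.number_of_edges() == n_edges_oracle
        assert g.number_of_nodes() == n_nodes_oracle

    def test_load_is_order_independent(self, tmp_path):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]
        rows = [f"{u}\t{v}" for u, v in edges]
        shuffled = rows[:]
        random.Random(0).shuffle(shuffled)
        g1 = data_io.read_interactome(_write(tmp_path, "a.tsv", "\n".join(rows) + "\n"))
        g2 = data_io.read_interactome(_write(tmp_path, "b.tsv", "\n".join(shuffled) + "\n"))
        assert {frozenset(e) for e in g1.edges} == {frozenset(e) for e in g2.edges}
        assert set(g1.nodes) == set(g2.nodes)

    def test_reduced_to_largest_component_by_default(self, tmp_path):
        p = _write(tmp_path, "net.tsv", "a\tb\nb\tc\nx\ty\n")
        g = data_io.read_interactome(p)
        assert set(g.nodes) == {"a", "b", "c"}
        g_all = data_io.read_interactome(p, keep_all_components=True)
        assert set(g_all.nodes) == {"a", "b", "c", "x", "y"}

    def test_sif_format(self, tmp_path):
        p = _write(tmp_path, "net.sif", "a\tpp\tb\tc\nb\tpp\tc\n")
        g = data_io.read_interactome(p, fmt="sif")
        assert {tuple(sorted(e)) for e in g.edges} == {
            ("a", "b"), ("a", "c"), ("b", "c"),
        }


class TestExpressionMatrix:
    def test_toy_matrix_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [[1.0, 2.0], [3.5, 4.0]],
            index=pd.Index(["g1", "g2"], name="gene"),
            columns=["liver", "lung"],
        )
        p = tmp_path / "expr.tsv"
        data_io.write_expression_matrix(df, p)
        back = data_io.read_expression_matrix(p)
        pd.testing.assert_frame_equal(df, back, check_names=False)

    def test_duplicate_gene_row_rejected(self, tmp_path):
        p = _write(tmp_path, "expr.tsv", "gene\tt1\tt2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ParseError, match="duplicated gene"):
            data_io.read_expression_matrix(p)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = _write(tmp_path, "expr.tsv", "gene\tt1\tt2\ng1\t1\toops\n")
        with pytest.raises(ParseError, match="g1.*t2"):
            data_io.read_expression_matrix(p)

    def test_missing_cell_rejected(self, tmp_path):
        p = _write(tmp_path, "expr.tsv", "gene\tt1\tt2\ng1\t1\t\n")
        with pytest.raises(ParseError):
            data_io.read_expression_matrix(p)


class TestGeneSets:
    def test_within_set_duplicates_collapsed(self, tmp_path):
        p = _write(tmp_path, "d.gmt", "D1\tdesc\tg1\tg2\tg2\n")
        (s,) = data_io.read_gene_sets(p)
        assert s.genes == {"g1", "g2"}
        assert s.n == 2

    def test_file_order_preserved(self, tmp_path):
        p = _write(tmp_path, "d.gmt", "D1\t.\tg1\tg2\nD2\t.\tg3\tg4\n")
        sets = data_io.read_gene_sets(p)
        assert [s.disease for s in sets] == ["D1", "D2"]

    def test_min_size_filter_matches_counting_oracle(self, tmp_path):
        rng = random.Random(5)
        lines, n_big = [], 0
        for i in range(40):
            k = rng.randint(10, 30)
            n_big += k >= 20
            genes = "\t".join(f"g{i}_{j}" for j in range(k))
            lines.append(f"D{i}\t.\t{genes}")
        p = _write(tmp_path, "d.gmt", "\n".join(lines) + "\n")
        sets = data_io.read_gene_sets(p, min_genes=20)
        assert len(sets) == n_big

    def test_too_few_fields_rejected(self, tmp_path):
        p = _write(tmp_path, "d.gmt", "D1\tdesc-only\n")
        with pytest.raises(ParseError):
            data_io.read_gene_sets(p)


GAF_HEADER = "!gaf-version: 2.2\n"


def _gaf_row(symbol, qualifier, go_id, aspect):
    cols = ["DB", "ID", symbol, qualifier, go_id, "REF", "EV", "", aspect, "", "",
            "protein", "taxon:9606", "20240101", "DB"]
    return "\t".join(cols)


class TestGOAnnotations:
    def test_three_aspects_parsed(self, tmp_path):
        text = GAF_HEADER + "\n".join(
            [
                _gaf_row("g1", "", "GO:1", "P"),
                _gaf_row("g1", "", "GO:2", "F"),
                _gaf_row("g1", "", "GO:3", "C"),
            ]
        )
        table = data_io.read_go_annotations(_write(tmp_path, "a.gaf", text))
        assert table.get("g1", "bp") == {"GO:1"}
        assert table.get("g1", "mf") == {"GO:2"}
        assert table.get("g1", "cc") == {"GO:3"}

    def test_not_qualifier_excluded(self, tmp_path):
        text = GAF_HEADER + "\n".join(
            [
                _gaf_row("g1", "NOT|involved_in", "GO:1", "P"),
                _gaf_row("g1", "involved_in", "GO:2", "P"),
            ]
        )
        table = data_io.read_go_annotations(_write(tmp_path, "a.gaf", text))
        assert table.get("g1", "bp") == {"GO:2"}

    def test_accumulation_matches_group_by_oracle(self, tmp_path):
        rng = random.Random(9)
        rows, expected = [], {}
        for _ in range(60):
            gene = f"g{rng.randint(0, 5)}"
            aspect = rng.choice("PFC")
            term = f"GO:{rng.randint(0, 20):04d}"
            rows.append(_gaf_row(gene, "", term, aspect))
            expected.setdefault(gene, {"P": set(), "F": set(), "C": set()})[aspect].add(term)
        table = data_io.read_go_annotations(_write(tmp_path, "a.gaf", GAF_HEADER + "\n".join(rows)))
        for gene, by_aspect in expected.items():
            assert table.get(gene, "bp") == by_aspect["P"]
            assert table.get(gene, "mf") == by_aspect["F"]
            assert table.get(gene, "cc") == by_aspect["C"]

    def test_unknown_aspect_rejected(self, tmp_path):
        text = GAF_HEADER + _gaf_row("g1", "", "GO:1", "Q")
        with pytest.raises(ParseError, match="aspect"):
            data_io.read_go_annotations(_write(tmp_path, "a.gaf", text))

    def test_tsv_dialect_round_trip(self, tmp_path, small_bundle):
        p = tmp_path / "go.tsv"
        data_io.write_go_annotations(small_bundle.go, p)
        back = data_io.read_go_annotations(p, fmt="tsv2col")
        assert back.terms == small_bundle.go.terms

    def test_unannotated_gene_returns_empty_flagged(self):
        table = data_io.GOAnnotationTable()
        assert table.get("nope", "bp") == frozenset()
        assert not table.annotated("nope")


class TestGWAS:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        data_io.write_gwas_pvalues({"g1": 1e-8, "g2": 0.5}, p)
        back = data_io.read_gwas_pvalues(p)
        assert back["g2"] == pytest.approx(0.5)
        assert back["g1"] == pytest.approx(1e-8)

    def test_out_of_range_p_rejected(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "g1\t1.5\n")
        with pytest.raises(ParseError):
            data_io.read_gwas_pvalues(p)


class TestBundleRoundTrip:
    def test_written_bundle_passes_all_readers(self, tmp_path, small_bundle):
        paths = write_bundle(small_bundle, tmp_path)
        g = data_io.read_interactome(paths["interactome"])
        assert {frozenset(e) for e in g.edges} == {
            frozenset(e) for e in small_bundle.interactome.edges
        }
        expr = data_io.read_expression_matrix(paths["expression"])
        assert expr.shape == small_bundle.expression.shape
        sets = data_io.read_gene_sets(paths["diseases"])
        assert {s.disease: s.genes for s in sets} == {
            s.disease: s.genes for s in small_bundle.disease_sets
        }
        gwas = data_io.read_gwas_pvalues(paths["gwas"])
        assert set(gwas) == set(small_bundle.gwas)


class TestNewick:
    def test_reparsed_by_independent_reader(self, tmp_path):
        from tissuemod.separation import tissue_dendrogram

        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=["x", "y", "z"], columns=["x", "y", "z"], dtype=float,
        )
        nwk = tissue_dendrogram(d)
        p = tmp_path / "t.nwk"
        data_io.write_newick(nwk, p)
        tree = dendropy.Tree.get(path=str(p), schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"x", "y", "z"}
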