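"""Readers and writers for the standard input/output formats.

The interactome is an undirected :class:`networkx.Graph` over gene
identifiers; expression matrices are gene x tissue pandas DataFrames;
disease gene sets come from GMT files; GO annotations from GAF 2.x or a
two-column TSV dialect. Gene identifiers are matched by exact,
case-sensitive string equality across all inputs — identifier mapping is
dataset-specific and deliberately out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_ASPECT_CODES = {"P": "bp", "F": "mf", "C": "cc"}
ASPECTS = ("bp", "mf", "cc")

# header tokens commonly found in the first line of interactome edge lists
_HEADER_TOKENS = {
    "gene", "gene1", "gene2", "genea", "geneb", "protein", "protein1",
    "protein2", "source", "target", "node1", "node2", "interactor_a",
    "interactor_b", "from", "to", "symbol_a", "symbol_b",
}


class ParseError(ValueError):
    """A malformed line or cell in one of the standard input formats."""


@dataclass(frozen=True)
class DiseaseGeneSet:
    """A named disease with its set of associated genes (N(d) = len)."""

    disease: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"disease set {self.disease!r} is empty")

    @property
    def n(self) -> int:
        return len(self.genes)


@dataclass
class GOAnnotationTable:
    """Per-gene GO term sets, one set per ontology aspect (bp/mf/cc).

    Lookups for unannotated genes return empty sets; ``annotated``
    distinguishes a gene that was seen with an empty aspect from one never
    seen at all.
    """

    terms: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def get(self, gene: str, aspect: str) -> frozenset[str]:
        if aspect not in ASPECTS:
            raise ValueError(f"unknown GO aspect {aspect!r}")
        return self.terms.get(gene, {}).get(aspect, frozenset())

    def annotated(self, gene: str) -> bool:
        return gene in self.terms

    @property
    def genes(self) -> set[str]:
        return set(self.terms)


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower().lstrip("#") in _HEADER_TOKENS for f in fields)


def read_interactome(
    path: str | Path,
    fmt: str = "edge-list-tsv",
    keep_all_components: bool = False,
) -> nx.Graph:
    """Load an undirected interactome from a TSV edge list or SIF file.

    Self-loops and duplicate edges are dropped (logged). By default the
    graph is reduced to its largest connected component, because shortest
    path statistics are undefined across components; pass
    ``keep_all_components=True`` to retain everything.
    """
    path = Path(path)
    if fmt not in ("edge-list-tsv", "sif"):
        raise ValueError(f"unknown interactome format {fmt!r}")
    g = nx.Graph()
    n_self, n_dup, n_rows = 0, 0, 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate whitespace-delimited lists
                fields = line.split()
            if fmt == "edge-list-tsv":
                if len(fields) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                    )
                if lineno == 1 and _looks_like_header(fields):
                    continue
                pairs = [(fields[0], fields[1])]
            else:  # sif: node <relation> partner [partner ...]
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: SIF row needs >= 3 fields"
                    )
                pairs = [(fields[0], other) for other in fields[2:]]
            for u, v in pairs:
                n_rows += 1
                if u == v:
                    n_self += 1
                    continue
                if g.has_edge(u, v):
                    n_dup += 1
                    continue
                g.add_edge(u, v)
    if n_rows == 0:
        raise ParseError(f"{path}: no edges found")
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loops and %d duplicate edges", path, n_self, n_dup
        )
    if not keep_all_components and g.number_of_nodes():
        components = list(nx.connected_components(g))
        if len(components) > 1:
            largest = max(components, key=lambda c: (len(c), min(c)))
            dropped = g.number_of_nodes() - len(largest)
            g = g.subgraph(largest).copy()
            logger.info(
                "%s: reduced to largest connected component (%d nodes dropped)",
                path,
                dropped,
            )
    return g


def write_interactome(g: nx.Graph, path: str | Path) -> None:
    """Write an interactome as a two-column TSV edge list (sorted)."""
    with Path(path).open("w") as fh:
        fh.write("gene1\tgene2\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue expression TSV (first column gene id).

    All cells must parse as numbers; duplicated gene rows or tissue
    columns, and missing cells, are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated gene row {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicated tissue column {dup!r}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ParseError(
                f"{path}: non-numeric cell at gene {bad[0]!r}, tissue {col!r}"
            ) from exc
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing value in gene row {gene!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(Path(path), sep="\t", index_label="gene")


def read_gene_sets(path: str | Path, min_genes: int = 1) -> list[DiseaseGeneSet]:
    """Read disease gene sets from a GMT file (name, description, genes...).

    Duplicate genes within a set are collapsed; sets smaller than
    ``min_genes`` after deduplication are dropped with a log message.
    """
    path = Path(path)
    sets: list[DiseaseGeneSet] = []
    n_dropped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT row needs >= 3 fields, got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            if len(genes) < min_genes:
                n_dropped += 1
                continue
            sets.append(DiseaseGeneSet(disease=name, genes=genes, description=desc))
    if n_dropped:
        logger.info("%s: dropped %d sets smaller than %d genes", path, n_dropped, min_genes)
    return sets


def write_gene_sets(sets: Iterable[DiseaseGeneSet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.disease}\t{s.description}\t{genes}\n")


def read_go_annotations(path: str | Path, fmt: str = "gaf") -> GOAnnotationTable:
    """Read gene -> GO term annotations from GAF 2.x or a 3-column TSV.

    GAF: comment lines (!) skipped, NOT-qualified rows dropped, aspect
    column (P/F/C) mapped to bp/mf/cc. TSV dialect: gene, term, aspect
    with aspect either P/F/C or bp/mf/cc.
    """
    path = Path(path)
    if fmt not in ("gaf", "tsv2col"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    table: dict[str, dict[str, set[str]]] = {}

    def _add(gene: str, term: str, aspect_code: str, lineno: int) -> None:
        aspect = _ASPECT_CODES.get(aspect_code, aspect_code.lower())
        if aspect not in ASPECTS:
            raise ParseError(f"{path}:{lineno}: unknown aspect code {aspect_code!r}")
        table.setdefault(gene, {a: set() for a in ASPECTS})[aspect].add(term)

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.split("\t")
            if fmt == "gaf":
                if len(fields) < 9:
                    raise ParseError(f"{path}:{lineno}: GAF row needs >= 9 columns")
                symbol, qualifier, go_id, aspect = (
                    fields[2], fields[3], fields[4], fields[8],
                )
                if "NOT" in qualifier.split("|"):
                    continue
                _add(symbol, go_id, aspect, lineno)
            else:
                if len(fields) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 3 fields")
                if lineno == 1 and fields[2].strip().lower() == "aspect":
                    continue
                _add(fields[0], fields[1], fields[2], lineno)
    frozen = {
        gene: {a: frozenset(terms[a]) for a in ASPECTS} for gene, terms in table.items()
    }
    return GOAnnotationTable(terms=frozen)


def write_go_annotations(table: GOAnnotationTable, path: str | Path) -> None:
    """Write annotations in the 3-column TSV dialect (gene, term, aspect)."""
    with Path(path).open("w") as fh:
        fh.write("gene\tterm\taspect\n")
        for gene in sorted(table.terms):
            for aspect in ASPECTS:
                for term in sorted(table.terms[gene][aspect]):
                    fh.write(f"{gene}\t{term}\t{aspect}\n")


def read_gwas_pvalues(path: str | Path) -> dict[str, float]:
    """Read per-gene GWAS p-values from a two-column TSV (gene, p)."""
    path = Path(path)
    pvals: dict[str, float] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            gene, p_str = fields
            if lineno == 1 and p_str.strip().lower() in ("p", "pvalue", "p_value"):
                continue
            try:
                p = float(p_str)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric p-value") from exc
            if not (0.0 < p <= 1.0):
                raise ParseError(f"{path}:{lineno}: p-value {p} outside (0, 1]")
            pvals[gene] = p
    return pvals


def write_gwas_pvalues(pvals: Mapping[str, float], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tp\n")
        for gene in sorted(pvals):
            fh.write(f"{gene}\t{pvals[gene]:.6g}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with a deterministic column order."""
    df.to_csv(Path(path), sep="\t", index=index, float_format="%.6g")


def write_json(obj: object, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_newick(newick: str, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(newick.rstrip("\n") + "\n")
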