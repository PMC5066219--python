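"""Disease modules in tissue-specific interactomes and the bipartite map.

For each (disease, tissue) pair the tissue-specific interactome is the
subgraph induced by the genes expressed in the tissue (z_E >= threshold).
The disease's expressed genes are mapped onto it; S is the size of their
largest connected component and S_total the number of disease genes
present in the tissue graph. The null hypothesis — disease genes do not
preferentially interact in the tissue-specific interactome — is simulated
by drawing S_total genes at random *from the tissue graph* and
recomputing the component size; significance is the z-score against that
null, with pairs declared linked at z >= 1.6. Significant pairs form a
disease-tissue bipartite network.

No multiple-testing correction is applied across the disease x tissue
grid (the raw z threshold is the decision rule); a Benjamini-Hochberg
column is available for users who want one.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from tissuemod._bfs import adjacency, largest_component
from tissuemod.data_io import DiseaseGeneSet
from tissuemod.expression import SignificanceMatrix, TissueGeneSet
from tissuemod.localization import (
    localization_significance,
    random_set_null,
)


@dataclass
class DiseaseTissueLink:
    """One tested (disease, tissue) pair of the bipartite map."""

    disease: str
    tissue: str
    s: int  # largest connected component of expressed disease genes
    s_total: int  # disease genes present in the tissue interactome
    z: float
    p: float
    p_empirical: float
    significant: bool
    testable: bool  # False when s_total < 2


@dataclass
class BipartiteNetwork:
    """Significant disease-tissue links with per-side degree summaries."""

    links: list[DiseaseTissueLink]
    diseases: list[str]
    tissues: list[str]
    z_sig: float

    disease_degree: Counter = field(init=False)
    tissue_degree: Counter = field(init=False)

    def __post_init__(self) -> None:
        self.disease_degree = Counter(l.disease for l in self.links)
        self.tissue_degree = Counter(l.tissue for l in self.links)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def unlinked_diseases(self) -> list[str]:
        return [d for d in self.diseases if d not in self.disease_degree]

    @property
    def unlinked_tissues(self) -> list[str]:
        return [t for t in self.tissues if t not in self.tissue_degree]

    def mean_tissues_per_disease(self, linked_only: bool = True) -> float:
        """Average number of tissues a disease manifests in.

        With ``linked_only`` the denominator is the diseases that appear
        in the network; otherwise all tested diseases. Both conventions
        are meaningful summaries of the same link list.
        """
        denom = len(self.disease_degree) if linked_only else len(self.diseases)
        if denom == 0:
            return 0.0
        return self.n_links / denom

    def has_link(self, disease: str, tissue: str) -> bool:
        return any(l.disease == disease and l.tissue == tissue for l in self.links)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.diseases, bipartite="disease")
        g.add_nodes_from(self.tissues, bipartite="tissue")
        for l in self.links:
            g.add_edge(l.disease, l.tissue, z=l.z, s=l.s, s_total=l.s_total)
        return g


@dataclass
class GeneFilterRecord:
    """Per-gene classification used for GWAS filtering (module vs rest)."""

    gene: str
    z_e: float
    expressed: bool
    in_module: bool
    neg_log10_p: float | None

    def __post_init__(self) -> None:
        if self.in_module and not self.expressed:
            raise ValueError("a module gene must be expressed")


def build_tissue_interactome(g: nx.Graph, tissue_set: TissueGeneSet) -> nx.Graph:
    """Subgraph induced by the tissue's expressed genes (all components kept)."""
    members = set(tissue_set.genes) & set(g.nodes)
    return g.subgraph(members).copy()


def disease_module_in_tissue(
    tissue_graph: nx.Graph,
    disease: DiseaseGeneSet,
    n_reps: int = 1000,
    seed: int | None = None,
    z_sig: float = 1.6,
    tissue: str = "",
    adj=None,
    null_cache: dict | None = None,
) -> DiseaseTissueLink:
    """Largest connected component of a disease's expressed genes vs null.

    Pairs with fewer than 2 expressed disease genes are untestable: they
    are reported with ``significant=False`` and ``testable=False`` rather
    than dropped, so downstream counts of diseases with no module in any
    tissue remain computable. ``null_cache`` (keyed by S_total) lets a
    caller reuse the null across diseases in the same tissue.
    """
    if adj is None:
        adj = adjacency(tissue_graph)
    members = set(disease.genes) & set(adj)
    s_total = len(members)
    s = largest_component(adj, members) if members else 0
    if s_total < 2:
        return DiseaseTissueLink(
            disease=disease.disease, tissue=tissue, s=s, s_total=s_total,
            z=math.nan, p=math.nan, p_empirical=math.nan,
            significant=False, testable=False,
        )
    if null_cache is not None and s_total in null_cache:
        null = null_cache[s_total]
    else:
        null = random_set_null(
            tissue_graph, s_total, "lcc_size", n_reps=n_reps, seed=seed, adj=adj
        )
        if null_cache is not None:
            null_cache[s_total] = null
    res = localization_significance(
        float(s), null, direction="greater", set_id=disease.disease, n_used=s_total
    )
    return DiseaseTissueLink(
        disease=disease.disease, tissue=tissue, s=s, s_total=s_total,
        z=res.z, p=res.p, p_empirical=res.p_empirical,
        significant=bool(res.z >= z_sig), testable=True,
    )


def build_disease_tissue_network(
    links: list[DiseaseTissueLink], z_sig: float = 1.6
) -> BipartiteNetwork:
    """Assemble the bipartite network of significant disease-tissue links.

    Expects one record per (disease, tissue) pair (duplicates are an
    error). Significance is re-derived from each record's z so the
    network can be rebuilt at a different threshold.
    """
    seen = set()
    for l in links:
        key = (l.disease, l.tissue)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
    diseases = sorted({l.disease for l in links})
    tissues = sorted({l.tissue for l in links})
    significant = [
        l for l in links if l.testable and not math.isnan(l.z) and l.z >= z_sig
    ]
    return BipartiteNetwork(
        links=significant, diseases=diseases, tissues=tissues, z_sig=z_sig
    )


def links_to_table(links: list[DiseaseTissueLink], bh: bool = True) -> pd.DataFrame:
    """Flatten link records into a tidy table, optionally with BH q-values."""
    df = pd.DataFrame(
        [
            {
                "disease": l.disease,
                "tissue": l.tissue,
                "s": l.s,
                "s_total": l.s_total,
                "z": l.z,
                "p": l.p,
                "p_empirical": l.p_empirical,
                "significant": l.significant,
                "testable": l.testable,
            }
            for l in links
        ]
    )
    if bh and len(df) and df["testable"].any():
        testable = df["testable"] & df["p"].notna()
        p = df.loc[testable, "p"].to_numpy()
        order = np.argsort(p, kind="stable")
        m = len(p)
        q = np.empty(m)
        ranked = p[order] * m / (np.arange(m) + 1)
        q[order[::-1]] = np.minimum.accumulate(ranked[::-1])
        df.loc[testable, "q_bh"] = np.minimum(q, 1.0)
    return df


def module_genes_in_tissue(
    tissue_graph: nx.Graph, disease: DiseaseGeneSet
) -> frozenset[str]:
    """Members of the largest connected component of expressed disease genes."""
    members = set(disease.genes) & set(tissue_graph.nodes)
    if not members:
        return frozenset()
    sub = tissue_graph.subgraph(members)
    components = list(nx.connected_components(sub))
    largest = max(components, key=lambda c: (len(c), sorted(c)[0]))
    return frozenset(largest)


def gwas_expression_filter(
    disease: DiseaseGeneSet,
    gwas_p: dict[str, float],
    sig: SignificanceMatrix,
    tissue: str,
    tissue_graph: nx.Graph,
    z_threshold: float = 1.0,
) -> list[GeneFilterRecord]:
    """Classify each disease gene by expression, module membership and GWAS.

    The tissue-specific disease module (the largest connected component
    of the disease genes inside the tissue interactome) acts as a filter:
    genes inside it are the candidates the network supports, genes
    expressed but outside it are weaker candidates, unexpressed genes are
    filtered out entirely. Records are sorted by -log10 GWAS p
    (descending, missing values last).
    """
    module = module_genes_in_tissue(tissue_graph, disease)
    records = []
    for gene in sorted(disease.genes):
        z_e = (
            float(sig.z.at[gene, tissue])
            if gene in sig.z.index
            else float("-inf")
        )
        expressed = z_e >= z_threshold
        p = gwas_p.get(gene)
        if p is not None and not (0.0 < p <= 1.0):
            raise ValueError(f"GWAS p-value for {gene!r} outside (0, 1]")
        records.append(
            GeneFilterRecord(
                gene=gene,
                z_e=z_e,
                expressed=expressed,
                in_module=gene in module,
                neg_log10_p=None if p is None else -math.log10(p),
            )
        )
    records.sort(
        key=lambda r: (r.neg_log10_p is None, -(r.neg_log10_p or 0.0), r.gene)
    )
    return records


def filter_diseases(
    sets: list[DiseaseGeneSet], min_genes: int = 20
) -> list[DiseaseGeneSet]:
    """Keep diseases with at least ``min_genes`` associated genes."""
    kept = [s for s in sets if s.n >= min_genes]
    return kept
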