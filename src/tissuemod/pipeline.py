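"""End-to-end orchestration: z-scores -> expressed sets -> localization ->
separation -> disease-tissue map -> GO coherence.

The in-memory entry point is :func:`run_pipeline`; :func:`run_all` wraps
it with file input/output and a reproducibility manifest (config hash,
seed, per-stage wall times). Randomized stages draw sub-seeds derived
deterministically from the master seed and a stable label (CRC32 of the
tissue/pair name), so results do not depend on evaluation order and a
rerun with the same config is result-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from tissuemod import data_io
from tissuemod.data_io import DiseaseGeneSet, GOAnnotationTable
from tissuemod.disease_tissue import (
    BipartiteNetwork,
    DiseaseTissueLink,
    build_disease_tissue_network,
    build_tissue_interactome,
    disease_module_in_tissue,
    filter_diseases,
    gwas_expression_filter,
    links_to_table,
)
from tissuemod.expression import (
    SignificanceMatrix,
    TissueGeneSet,
    expressed_gene_set,
    expression_summary,
    expression_zscores,
)
from tissuemod.go_similarity import (
    DiseaseSimilarity,
    GroupComparison,
    compare_linked_vs_unlinked,
    similarity_deviation,
)
from tissuemod.localization import (
    largest_component_size,
    localization_significance,
    mean_nearest_member_distance,
    random_set_null,
)
from tissuemod.separation import all_pairs_separation, distance_matrix, tissue_dendrogram
from tissuemod._bfs import adjacency


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    interactome_path: str | None = None
    expression_path: str | None = None
    gmt_path: str | None = None
    go_path: str | None = None
    go_format: str = "tsv2col"
    gwas_path: str | None = None
    out_dir: str = "results"
    z_threshold: float = 1.0
    z_sig: float = 1.6
    n_reps: int = 1000
    ddof: int = 1
    sampling: str = "uniform"
    min_genes: int = 20
    measure: str = "simpson"
    seed: int = 0
    run_separation: bool = True
    keep_all_components: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.z_threshold) and math.isfinite(self.z_sig)):
            raise ValueError("thresholds must be finite")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    """All tables and objects produced by one pipeline run."""

    significance: SignificanceMatrix
    tissue_sets: list[TissueGeneSet]  # interactome-restricted
    expressed_sets: list[TissueGeneSet]  # unrestricted (for GO similarity)
    summary: pd.DataFrame
    localization: pd.DataFrame
    separation: pd.DataFrame | None
    dendrogram: str | None
    link_records: list[DiseaseTissueLink]
    links_table: pd.DataFrame
    network: BipartiteNetwork
    deviations: dict[str, list[DiseaseSimilarity]]  # aspect -> records
    comparisons: dict[str, GroupComparison]
    timings: dict[str, float] = field(default_factory=dict)


def _sub_seed(seed: int, label: str) -> int:
    return int(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(
    interactome: nx.Graph,
    expression: pd.DataFrame,
    disease_sets: list[DiseaseGeneSet],
    go: GOAnnotationTable | None = None,
    cfg: RunConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory inputs."""
    cfg = cfg or RunConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    sig = expression_zscores(expression, ddof=cfg.ddof)
    tissues = list(sig.tissues)
    tissue_sets = [
        expressed_gene_set(sig, t, cfg.z_threshold, restrict_to=interactome)
        for t in tissues
    ]
    expressed_sets = [expressed_gene_set(sig, t, cfg.z_threshold) for t in tissues]
    summary = expression_summary(expressed_sets, len(sig.genes))
    timings["expression"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    adj = adjacency(interactome)
    loc_rows = []
    for ts in tissue_sets:
        if ts.n < 2:
            continue
        s = largest_component_size(interactome, ts.genes)
        d_s = mean_nearest_member_distance(interactome, ts.genes, adj=adj)
        for stat, observed, direction in (
            ("lcc_size", float(s), "greater"),
            ("mean_distance", d_s, "less"),
        ):
            null = random_set_null(
                interactome,
                ts.n,
                stat,
                n_reps=cfg.n_reps,
                seed=_sub_seed(cfg.seed, f"loc:{stat}:{ts.tissue}"),
                sampling=cfg.sampling,
                reference_set=ts.genes if cfg.sampling == "degree-binned" else None,
                adj=adj,
            )
            res = localization_significance(
                observed, null, direction=direction, set_id=ts.tissue, n_used=ts.n
            )
            loc_rows.append(
                {
                    "tissue": ts.tissue,
                    "statistic": stat,
                    "n_expressed": ts.n,
                    "observed": res.observed,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "z": res.z,
                    "p": res.p,
                    "p_empirical": res.p_empirical,
                }
            )
    localization = pd.DataFrame(loc_rows)
    timings["localization"] = time.perf_counter() - t0

    separation = None
    dendrogram = None
    if cfg.run_separation and len(tissue_sets) >= 2:
        t0 = time.perf_counter()
        separation = all_pairs_separation(
            interactome,
            tissue_sets,
            n_reps=cfg.n_reps,
            seed=_sub_seed(cfg.seed, "separation"),
            z_sig=cfg.z_sig,
        )
        dmat = distance_matrix(interactome, tissue_sets)
        dendrogram = tissue_dendrogram(dmat)
        timings["separation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    diseases = filter_diseases(disease_sets, cfg.min_genes)
    link_records: list[DiseaseTissueLink] = []
    tissue_graphs: dict[str, nx.Graph] = {}
    for ts in tissue_sets:
        tg = build_tissue_interactome(interactome, ts)
        tissue_graphs[ts.tissue] = tg
        tg_adj = adjacency(tg)
        null_cache: dict = {}
        for d in diseases:
            s_total = len(set(d.genes) & set(tg_adj))
            link = disease_module_in_tissue(
                tg,
                d,
                n_reps=cfg.n_reps,
                seed=_sub_seed(cfg.seed, f"dt:{ts.tissue}:{s_total}"),
                z_sig=cfg.z_sig,
                tissue=ts.tissue,
                adj=tg_adj,
                null_cache=null_cache,
            )
            link_records.append(link)
    network = build_disease_tissue_network(link_records, z_sig=cfg.z_sig)
    links_table = links_to_table(link_records)
    timings["disease_tissue"] = time.perf_counter() - t0

    deviations: dict[str, list[DiseaseSimilarity]] = {}
    comparisons: dict[str, GroupComparison] = {}
    if go is not None:
        t0 = time.perf_counter()
        expr_by_tissue = {s.tissue: s.genes for s in expressed_sets}
        for aspect in data_io.ASPECTS:
            records = [
                similarity_deviation(
                    d,
                    expr_by_tissue[ts.tissue],
                    go,
                    aspect,
                    measure=cfg.measure,
                    tissue=ts.tissue,
                )
                for d in diseases
                for ts in tissue_sets
            ]
            deviations[aspect] = records
            try:
                comparisons[aspect] = compare_linked_vs_unlinked(records, network)
            except ValueError:
                pass  # a group may be empty on tiny inputs
        timings["go_similarity"] = time.perf_counter() - t0

    return PipelineResult(
        significance=sig,
        tissue_sets=tissue_sets,
        expressed_sets=expressed_sets,
        summary=summary,
        localization=localization,
        separation=separation,
        dendrogram=dendrogram,
        link_records=link_records,
        links_table=links_table,
        network=network,
        deviations=deviations,
        comparisons=comparisons,
        timings=timings,
    )


def deviations_table(deviations: dict[str, list[DiseaseSimilarity]]) -> pd.DataFrame:
    rows = [
        {
            "disease": r.disease,
            "tissue": r.tissue,
            "aspect": aspect,
            "measure": r.measure,
            "value": r.value,
            "deviation": r.deviation,
            "n_genes": r.n_genes,
            "n_excluded": r.n_excluded,
        }
        for aspect, records in deviations.items()
        for r in records
    ]
    return pd.DataFrame(rows)


def comparisons_table(comparisons: dict[str, GroupComparison]) -> pd.DataFrame:
    rows = [
        {
            "aspect": aspect,
            "measure": c.measure,
            "u": c.u,
            "z": c.z,
            "p": c.p,
            "n_cc": c.n_cc,
            "n_ncc": c.n_ncc,
            "frac_positive_cc": c.frac_positive_cc,
            "frac_negative_cc": c.frac_negative_cc,
            "frac_positive_ncc": c.frac_positive_ncc,
            "frac_negative_ncc": c.frac_negative_ncc,
        }
        for aspect, c in comparisons.items()
    ]
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> PipelineResult:
    """File-driven pipeline run: read inputs, compute, write all outputs.

    Writes under ``cfg.out_dir``: the z-score matrix, expressed sets
    (GMT), expression summary, localization and separation tables, the
    tissue dendrogram (Newick), the disease-tissue link table and
    bipartite network (TSV + GraphML), GO deviation/comparison tables,
    per-link GWAS filter tables when GWAS p-values are given, and a JSON
    manifest with the config hash, seed and per-stage timings.
    """
    if not (cfg.interactome_path and cfg.expression_path and cfg.gmt_path):
        raise ValueError("interactome, expression and GMT paths are required")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = data_io.read_interactome(
        cfg.interactome_path, keep_all_components=cfg.keep_all_components
    )
    expr = data_io.read_expression_matrix(cfg.expression_path)
    sets = data_io.read_gene_sets(cfg.gmt_path)
    go = (
        data_io.read_go_annotations(cfg.go_path, fmt=cfg.go_format)
        if cfg.go_path
        else None
    )
    gwas = data_io.read_gwas_pvalues(cfg.gwas_path) if cfg.gwas_path else None

    result = run_pipeline(g, expr, sets, go=go, cfg=cfg)

    data_io.write_expression_matrix(result.significance.z, out / "zscores.tsv")
    with (out / "expressed_sets.gmt").open("w") as fh:
        for ts in result.tissue_sets:
            genes = "\t".join(sorted(ts.genes))
            fh.write(f"{ts.tissue}\tz>={ts.threshold}\t{genes}\n")
    data_io.write_table(result.summary, out / "expression_summary.tsv")
    data_io.write_table(result.localization, out / "localization.tsv")
    if result.separation is not None:
        data_io.write_table(result.separation, out / "tissue_pairs.tsv")
    if result.dendrogram is not None:
        data_io.write_newick(result.dendrogram, out / "tissue_dendrogram.nwk")
    data_io.write_table(result.links_table, out / "disease_tissue_links.tsv")
    nx.write_graphml(result.network.to_graph(), out / "disease_tissue_network.graphml")
    if result.deviations:
        data_io.write_table(deviations_table(result.deviations), out / "go_deviations.tsv")
    if result.comparisons:
        data_io.write_table(comparisons_table(result.comparisons), out / "go_comparisons.tsv")
    if gwas is not None:
        sig_by_tissue: dict[str, TissueGeneSet] = {
            ts.tissue: ts for ts in result.tissue_sets
        }
        disease_by_name = {d.disease: d for d in sets}
        rows = []
        for link in result.network.links:
            d = disease_by_name[link.disease]
            tg = build_tissue_interactome(g, sig_by_tissue[link.tissue])
            for rec in gwas_expression_filter(
                d, gwas, result.significance, link.tissue, tg, cfg.z_threshold
            ):
                rows.append(
                    {
                        "disease": link.disease,
                        "tissue": link.tissue,
                        "gene": rec.gene,
                        "z_e": rec.z_e,
                        "expressed": rec.expressed,
                        "in_module": rec.in_module,
                        "neg_log10_p": rec.neg_log10_p,
                    }
                )
        data_io.write_table(pd.DataFrame(rows), out / "gwas_filter.tsv")
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
        "n_links": result.network.n_links,
    }
    data_io.write_json(manifest, out / "manifest.json")
    return result
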