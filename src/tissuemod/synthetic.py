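"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the structure the analysis is designed to detect,
without pretending to be a real transcriptome:

* a sparse scale-free-like interactome (preferential attachment);
* tissue expression programs that are *network-localized*: each tissue
  elevates a connected neighborhood grown around a seed node (a fraction
  ``kappa`` of the program) plus uniformly scattered genes (the rest), so
  localization strength is a single tunable knob;
* genes not elevated anywhere are suppressed in one random tissue, which
  keeps their standardized profiles below the expression-significance
  threshold everywhere — per-tissue expressed fractions therefore land on
  the configured target;
* disease gene sets, a subset of which carry a planted module: a
  connected subgraph grown inside a host tissue's expressed subgraph,
  padded with random genes from outside the host program;
* GO annotations whose coherence is boosted inside planted modules (a
  per-disease core term pool shared by module members), and GWAS
  p-values that are systematically stronger for module members.

Everything is deterministic under a master seed; each stage draws from a
sub-seed derived from (seed, stage index) so regeneration is
order-independent and byte-identical.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from tissuemod import data_io
from tissuemod.data_io import DiseaseGeneSet, GOAnnotationTable

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic bundle.

    The defaults describe the reference study conditions used by the
    analysis scripts and the acceptance checks: a 2,000-gene
    preferential-attachment interactome, 8 tissues each expressing 10% of
    genes with localization strength kappa = 0.9, 12 diseases of 25 genes
    of which 4 carry a planted module of 8 connected expressed genes, GO
    coherence boost 0.6 inside planted modules, and 200-replicate
    randomization nulls downstream.
    """

    n_genes: int = 2000
    edge_model: str = "preferential-attachment"  # or "erdos-renyi"
    pa_m: int = 2
    er_p: float = 0.002
    n_tissues: int = 8
    expressed_fraction: float = 0.10
    kappa: float = 0.9  # share of a tissue program drawn from its neighborhood
    tissue_seed_nodes: tuple[str, ...] | None = None
    n_diseases: int = 12
    genes_per_disease: int = 25
    module_size: int = 8
    n_planted_links: int = 4
    go_terms_per_aspect: int = 150
    terms_per_gene: int = 5
    coherence_boost: float = 0.6
    baseline: float = 5.0
    elevated: float = 10.0
    suppressed: float = 1.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("expressed_fraction", "kappa", "coherence_boost"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_planted_links > min(self.n_diseases, self.n_tissues):
            raise ValueError("more planted links than diseases or tissues")
        if self.module_size > self.genes_per_disease:
            raise ValueError("module_size cannot exceed genes_per_disease")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue_{i:02d}" for i in range(self.n_tissues)]

    @property
    def diseases(self) -> list[str]:
        return [f"disease_{i:02d}" for i in range(self.n_diseases)]


@dataclass
class GroundTruth:
    """What was planted: tissue neighborhoods and disease modules."""

    tissue_seeds: dict[str, str]
    programs: dict[str, frozenset[str]]  # tissue -> elevated genes
    modules: dict[str, frozenset[str]]  # planted disease -> module genes
    hosts: dict[str, str]  # planted disease -> host tissue
    true_links: frozenset[tuple[str, str]]  # (disease, tissue)

    def to_json(self) -> dict:
        return {
            "tissue_seeds": self.tissue_seeds,
            "programs": {t: sorted(g) for t, g in self.programs.items()},
            "modules": {d: sorted(g) for d, g in self.modules.items()},
            "hosts": self.hosts,
            "true_links": sorted(map(list, self.true_links)),
        }


@dataclass
class SyntheticBundle:
    """A complete, self-consistent input bundle plus its ground truth."""

    config: SyntheticConfig
    seed: int
    interactome: nx.Graph
    expression: pd.DataFrame
    disease_sets: list[DiseaseGeneSet]
    go: GOAnnotationTable
    gwas: dict[str, float]
    truth: GroundTruth


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_interactome(cfg: SyntheticConfig, seed: int) -> nx.Graph:
    """Simple connected interactome under the configured edge model.

    Preferential attachment gives the heavy-tailed degree distribution
    typical of protein-interaction maps; the Erdos-Renyi option is a
    homogeneous control. Only the largest connected component is kept.
    """
    rng = _stage_rng(seed, 0)
    nx_seed = int(rng.integers(2**31))
    if cfg.edge_model == "preferential-attachment":
        g = nx.barabasi_albert_graph(cfg.n_genes, cfg.pa_m, seed=nx_seed)
    elif cfg.edge_model == "erdos-renyi":
        g = nx.gnp_random_graph(cfg.n_genes, cfg.er_p, seed=nx_seed)
    else:
        raise ValueError(f"unknown edge model {cfg.edge_model!r}")
    g.remove_edges_from(nx.selfloop_edges(g))
    if not nx.is_connected(g):
        largest = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
        g = g.subgraph(largest).copy()
    return nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})


def _bfs_order(g: nx.Graph, start: str) -> list[str]:
    """Deterministic BFS enumeration (neighbors visited in sorted order).

    Every prefix of the returned list induces a connected subgraph.
    """
    seen = {start}
    order = [start]
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in sorted(g.adj[u]):
            if v not in seen:
                seen.add(v)
                order.append(v)
                queue.append(v)
    return order


def _grow_regions(
    g: nx.Graph, seeds: list[str], target: int
) -> dict[str, list[str]]:
    """Grow balanced, disjoint connected regions around distinct seed nodes.

    Regions expand round-robin, one node per region per round (each new
    node adjacent to an already-claimed node of the same region), until
    every region holds ``target`` nodes or cannot grow further. The
    round-robin schedule keeps region sizes balanced even when one seed
    sits next to a hub that would dominate a plain nearest-seed
    partition; every claim-order prefix of a region is connected.
    Deterministic: seeds in given order, neighbors in sorted order.
    """
    claimed: dict[str, str] = {}
    order: dict[str, list[str]] = {}
    queues: dict[str, deque] = {}
    for s in seeds:
        if s in claimed:
            raise ValueError(f"duplicate seed node {s!r}")
        claimed[s] = s
        order[s] = [s]
        queues[s] = deque([s])
    active = [s for s in seeds if len(order[s]) < target]
    while active:
        still_active = []
        for s in active:
            grew = False
            queue = queues[s]
            while queue and not grew:
                u = queue[0]
                for v in sorted(g.adj[u]):
                    if v not in claimed:
                        claimed[v] = s
                        order[s].append(v)
                        queue.append(v)
                        grew = True
                        break
                if not grew:
                    queue.popleft()
            if grew and len(order[s]) < target:
                still_active.append(s)
        active = still_active
    return order


def plant_tissue_programs(
    g: nx.Graph, cfg: SyntheticConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Expression matrix with network-localized tissue programs.

    Each tissue's program has ``round(expressed_fraction * n_genes)``
    genes: a connected neighborhood around the tissue's seed node (the
    prefix of its balanced-growth region) supplies the ``kappa`` share,
    uniformly drawn genes the rest. Regions of distinct seeds are
    disjoint, so a gene is rarely elevated in more than two tissues and
    its standardized profile clears the significance threshold wherever
    it is elevated. Program genes are elevated in their tissue; genes
    elevated nowhere are suppressed in one random tissue so that their
    flat profiles never reach the threshold anywhere. Gaussian noise is
    added everywhere and values are clipped at zero.

    Tissues listed with the same entry in ``tissue_seed_nodes`` share one
    neighborhood (a way to plant "closer" tissue pairs); if a region is
    smaller than the neighborhood target the shortfall is made up from
    the uniform pool.
    """
    rng = _stage_rng(seed, 1)
    nodes = sorted(g.nodes)
    n = len(nodes)
    tissues = cfg.tissues
    n_target = round(cfg.expressed_fraction * n)
    if n_target < 1 or n_target > n:
        raise ValueError("expressed-fraction target infeasible for this graph")
    ball_count = round(cfg.kappa * n_target)
    if cfg.tissue_seed_nodes is not None:
        if len(cfg.tissue_seed_nodes) != len(tissues):
            raise ValueError("tissue_seed_nodes must match n_tissues")
        seeds = list(cfg.tissue_seed_nodes)
        missing = [s for s in seeds if s not in g]
        if missing:
            raise ValueError(f"seed nodes not in interactome: {missing}")
    else:
        seeds = list(
            rng.choice(np.array(nodes, dtype=object), size=len(tissues), replace=False)
        )
    unique_seeds = list(dict.fromkeys(seeds))
    regions = (
        _grow_regions(g, unique_seeds, ball_count)
        if ball_count
        else {s: [s] for s in unique_seeds}
    )
    balls = {s: regions[s][:ball_count] for s in unique_seeds}
    # uniform parts avoid genes claimed by any neighborhood or earlier tissue:
    # a gene elevated in several tissues has a flatter profile and can miss
    # the significance threshold, which would erode the size target
    claimed = set().union(*balls.values()) if ball_count else set()
    programs: dict[str, frozenset[str]] = {}
    for t, seed_node in zip(tissues, seeds):
        ball = balls[seed_node]
        if len(ball) < ball_count:
            logger.info(
                "tissue %s: region of %s has only %d of %d neighborhood genes; "
                "padding from the uniform pool", t, seed_node, len(ball), ball_count,
            )
        n_uniform = n_target - len(ball)
        uniform: list = []
        if n_uniform > 0:
            pool = np.array(sorted(set(nodes) - claimed), dtype=object)
            if len(pool) < n_uniform:  # exhausted: allow reuse across tissues
                pool = np.array(sorted(set(nodes) - set(ball)), dtype=object)
                logger.info("tissue %s: uniform pool exhausted, reusing genes", t)
            uniform = list(rng.choice(pool, size=n_uniform, replace=False))
            claimed.update(uniform)
        programs[t] = frozenset(ball) | frozenset(uniform)
    covered = set().union(*programs.values()) if programs else set()
    uncovered = sorted(set(nodes) - covered)
    suppress_tissue = {
        gene: tissues[rng.integers(len(tissues))] for gene in uncovered
    }
    index = {gene: i for i, gene in enumerate(nodes)}
    values = np.full((n, len(tissues)), cfg.baseline)
    for j, t in enumerate(tissues):
        for gene in programs[t]:
            values[index[gene], j] = cfg.elevated
    for gene, t in suppress_tissue.items():
        values[index[gene], tissues.index(t)] = cfg.suppressed
    values += rng.normal(0.0, cfg.noise_sd, size=values.shape)
    np.clip(values, 0.0, None, out=values)
    expr = pd.DataFrame(values, index=pd.Index(nodes, name="gene"), columns=tissues)
    truth = GroundTruth(
        tissue_seeds=dict(zip(tissues, seeds)),
        programs=programs,
        modules={},
        hosts={},
        true_links=frozenset(),
    )
    return expr, truth


def plant_disease_modules(
    g: nx.Graph, truth: GroundTruth, cfg: SyntheticConfig, seed: int
) -> tuple[list[DiseaseGeneSet], GroundTruth]:
    """Disease gene sets with planted tissue-specific modules.

    The first ``n_planted_links`` diseases each get a connected module of
    ``module_size`` genes grown by BFS inside the host tissue's expressed
    subgraph, padded to ``genes_per_disease`` with random genes from
    outside the host program. Remaining diseases are uniform random gene
    sets — connected components they form anywhere are chance.
    """
    rng = _stage_rng(seed, 2)
    nodes = np.array(sorted(g.nodes), dtype=object)
    tissues = cfg.tissues
    diseases = cfg.diseases
    hosts: dict[str, str] = {}
    modules: dict[str, frozenset[str]] = {}
    sets: list[DiseaseGeneSet] = []
    host_order = [tissues[i % len(tissues)] for i in range(cfg.n_planted_links)]
    for d, host in zip(diseases[: cfg.n_planted_links], host_order):
        program = truth.programs[host]
        sub = g.subgraph(program)
        # grow inside the largest connected piece of the expressed subgraph,
        # from the tissue seed when it lies there
        components = sorted(
            nx.connected_components(sub), key=lambda c: (-len(c), min(c))
        )
        comp = components[0]
        start = truth.tissue_seeds[host]
        if start not in comp:
            start = min(comp)
        order = _bfs_order(sub, start)
        if len(order) < cfg.module_size:
            raise ValueError(
                f"cannot grow {cfg.module_size} connected expressed genes in {host}"
            )
        module = frozenset(order[: cfg.module_size])
        pad_pool = np.array(sorted(set(g.nodes) - set(program) - module), dtype=object)
        padding = rng.choice(
            pad_pool, size=cfg.genes_per_disease - len(module), replace=False
        )
        genes = module | frozenset(padding)
        sets.append(DiseaseGeneSet(disease=d, genes=frozenset(genes), description=f"planted:{host}"))
        hosts[d] = host
        modules[d] = module
    for d in diseases[cfg.n_planted_links :]:
        genes = frozenset(rng.choice(nodes, size=cfg.genes_per_disease, replace=False))
        sets.append(DiseaseGeneSet(disease=d, genes=genes, description="background"))
    new_truth = GroundTruth(
        tissue_seeds=truth.tissue_seeds,
        programs=truth.programs,
        modules=modules,
        hosts=hosts,
        true_links=frozenset(hosts.items()),
    )
    return sets, new_truth


def generate_go_and_gwas(
    sets: list[DiseaseGeneSet],
    truth: GroundTruth,
    cfg: SyntheticConfig,
    seed: int,
    genes=None,
) -> tuple[GOAnnotationTable, dict[str, float]]:
    """GO annotations with planted coherence, and GWAS p-values.

    Background genes draw ``terms_per_gene`` terms per aspect uniformly
    from a global pool. Module members of a planted disease instead draw
    ``round(boost * terms_per_gene)`` of their terms from a per-disease
    core pool of size ``terms_per_gene`` — at boost 1 every module member
    carries the identical core set, at boost 0 modules are
    indistinguishable from background. Module members get GWAS
    -log10 p ~ U(8, 30), every other disease gene ~ U(0, 6).
    """
    rng = _stage_rng(seed, 3)
    aspects = ("bp", "mf", "cc")
    if genes is None:
        genes = sorted(set().union(*(s.genes for s in sets)))
    else:
        genes = sorted(set(genes) | set().union(*(s.genes for s in sets)))
    pools = {
        a: np.array([f"GO:{a}:{i:04d}" for i in range(cfg.go_terms_per_aspect)], dtype=object)
        for a in aspects
    }
    module_of: dict[str, str] = {}
    for d, module in truth.modules.items():
        for gene in module:
            module_of[gene] = d
    core_pools = {
        (d, a): rng.choice(pools[a], size=cfg.terms_per_gene, replace=False)
        for d in sorted(truth.modules)
        for a in aspects
    }
    n_core = round(cfg.coherence_boost * cfg.terms_per_gene)
    table: dict[str, dict[str, frozenset[str]]] = {}
    for gene in genes:
        per_aspect = {}
        d = module_of.get(gene)
        for a in aspects:
            if d is not None and n_core > 0:
                core = rng.choice(core_pools[(d, a)], size=n_core, replace=False)
                background = rng.choice(
                    pools[a], size=cfg.terms_per_gene - n_core, replace=False
                )
                terms = frozenset(core) | frozenset(background)
            else:
                terms = frozenset(
                    rng.choice(pools[a], size=cfg.terms_per_gene, replace=False)
                )
            per_aspect[a] = terms
        table[gene] = per_aspect
    gwas: dict[str, float] = {}
    for s in sets:
        for gene in sorted(s.genes):
            if gene in gwas:
                continue
            if gene in module_of:
                neg_log_p = rng.uniform(8.0, 30.0)
            else:
                neg_log_p = rng.uniform(0.0, 6.0)
            gwas[gene] = float(10.0 ** (-neg_log_p))
    return GOAnnotationTable(terms=table), gwas


def generate_bundle(cfg: SyntheticConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Generate a complete bundle (interactome, expression, diseases, GO, GWAS)."""
    cfg = cfg or SyntheticConfig()
    g = generate_interactome(cfg, seed)
    expr, truth = plant_tissue_programs(g, cfg, seed)
    sets, truth = plant_disease_modules(g, truth, cfg, seed)
    go, gwas = generate_go_and_gwas(sets, truth, cfg, seed, genes=g.nodes)
    return SyntheticBundle(
        config=cfg, seed=seed, interactome=g, expression=expr,
        disease_sets=sets, go=go, gwas=gwas, truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the standard input formats plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactome": out / "interactome.tsv",
        "expression": out / "expression.tsv",
        "diseases": out / "diseases.gmt",
        "go": out / "go_annotations.tsv",
        "gwas": out / "gwas_pvalues.tsv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "config.json",
    }
    data_io.write_interactome(bundle.interactome, paths["interactome"])
    data_io.write_expression_matrix(bundle.expression, paths["expression"])
    data_io.write_gene_sets(bundle.disease_sets, paths["diseases"])
    data_io.write_go_annotations(bundle.go, paths["go"])
    data_io.write_gwas_pvalues(bundle.gwas, paths["gwas"])
    data_io.write_json(bundle.truth.to_json(), paths["ground_truth"])
    cfg = asdict(bundle.config)
    cfg["seed"] = bundle.seed
    data_io.write_json(cfg, paths["config"])
    return paths
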