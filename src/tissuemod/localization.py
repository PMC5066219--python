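"""Network localization of a gene set against a random-set null.

Two statistics measure whether a set of genes agglomerates in one
neighborhood of the interactome:

* ``S`` — the size of the largest connected component of the subgraph
  induced by the set (a localized set concentrates into one component);
* ``d_S`` — the mean, over set members, of the shortest-path distance to
  the nearest *other* member (a localized set has small ``d_S``).

Significance is assessed against sets of the same size drawn uniformly at
random from the graph's nodes: the null distribution of the statistic is
summarized by its mean and standard deviation, and the observed value is
expressed as a z-score with a one-sided normal-tail p-value (the
randomization distribution is treated as approximately normal). An
empirical p-value, (r + 1) / (n + 1), is reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from tissuemod._bfs import adjacency, largest_component, nearest_member_distance

STATISTICS = ("lcc_size", "mean_distance")


@dataclass
class NullDistribution:
    """Randomization null for one statistic at one set size."""

    statistic: str
    samples: np.ndarray
    n_reps: int
    seed: int | None
    set_size: int

    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != self.n_reps:
            raise ValueError("sample count does not match n_reps")
        self.mean = float(np.mean(self.samples))
        self.sd = float(np.std(self.samples, ddof=1)) if self.n_reps > 1 else 0.0


@dataclass
class LocalizationResult:
    """Observed statistic with its null summary and significance."""

    set_id: str
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    p_empirical: float
    n_used: int
    direction: str
    degenerate_null: bool = False


def largest_component_size(g: nx.Graph, genes) -> int:
    """Size S of the largest connected component induced by ``genes``.

    Genes absent from the graph are silently intersected away; an empty
    intersection gives 0.
    """
    members = set(genes) & set(g.nodes)
    if not members:
        return 0
    return largest_component(g.adj, members)


def mean_nearest_member_distance(g: nx.Graph, genes, adj=None) -> float:
    """Mean shortest distance d_S from each member to its nearest other member.

    Members with no reachable other member are excluded from the average
    (their count is available via :func:`nearest_member_distances`).
    """
    distances, _ = nearest_member_distances(g, genes, adj=adj)
    if not distances:
        raise ValueError("no member has a reachable other member")
    return float(np.mean(distances))


def nearest_member_distances(g: nx.Graph, genes, adj=None) -> tuple[list[int], int]:
    """Per-member nearest-other-member distances and the unreachable count."""
    if adj is None:
        adj = g.adj
    members = frozenset(genes) & frozenset(adj)
    if len(members) < 2:
        raise ValueError("need at least 2 usable members for d_S")
    distances: list[int] = []
    n_unreachable = 0
    for m in members:
        d = nearest_member_distance(adj, members, m)
        if d is None:
            n_unreachable += 1
        else:
            distances.append(d)
    return distances, n_unreachable


def _evaluate(statistic: str, adj, members: set) -> float:
    if statistic == "lcc_size":
        return float(largest_component(adj, members))
    if statistic == "mean_distance":
        fs = frozenset(members)
        dists = [
            d for m in fs if (d := nearest_member_distance(adj, fs, m)) is not None
        ]
        if not dists:
            return math.nan
        return float(np.mean(dists))
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def _degree_bins(degrees: np.ndarray, min_bin_size: int = 50) -> list[np.ndarray]:
    """Log2 degree bins, merged upward until each holds >= min_bin_size nodes."""
    order = np.argsort(degrees, kind="stable")
    log_deg = np.floor(np.log2(np.maximum(degrees[order], 1))).astype(int)
    bins: list[np.ndarray] = []
    current: list[int] = []
    last_level = log_deg[0]
    for idx, level in zip(order, log_deg):
        if level != last_level and len(current) >= min_bin_size:
            bins.append(np.array(current))
            current = []
        current.append(idx)
        last_level = level
    if current:
        if bins and len(current) < min_bin_size:
            bins[-1] = np.concatenate([bins[-1], np.array(current)])
        else:
            bins.append(np.array(current))
    return bins


def random_set_null(
    g: nx.Graph,
    set_size: int,
    statistic: str,
    n_reps: int = 1000,
    seed: int | None = None,
    sampling: str = "uniform",
    reference_set=None,
    adj=None,
) -> NullDistribution:
    """Null distribution of a statistic over random same-size gene sets.

    ``sampling='uniform'`` draws ``set_size`` nodes uniformly without
    replacement (the default randomization). ``sampling='degree-binned'``
    draws, for each gene of ``reference_set``, a node from the same log2
    degree bin — an option that corrects for hub genes inflating the
    connected-component statistic.
    """
    if adj is None:
        adj = adjacency(g)
    nodes = sorted(adj)
    if set_size > len(nodes):
        raise ValueError(f"set_size {set_size} exceeds node count {len(nodes)}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    node_arr = np.array(nodes, dtype=object)
    samples = np.empty(n_reps)
    if sampling == "uniform":
        for r in range(n_reps):
            members = set(rng.choice(node_arr, size=set_size, replace=False))
            samples[r] = _evaluate(statistic, adj, members)
    elif sampling == "degree-binned":
        if reference_set is None:
            raise ValueError("degree-binned sampling needs reference_set")
        reference = sorted(set(reference_set) & set(nodes))
        degrees = np.array([len(adj[n]) for n in nodes])
        bins = _degree_bins(degrees)
        bin_of = np.empty(len(nodes), dtype=int)
        for b, idx in enumerate(bins):
            bin_of[idx] = b
        index_of = {n: i for i, n in enumerate(nodes)}
        ref_bins = [bin_of[index_of[n]] for n in reference]
        for r in range(n_reps):
            members: set = set()
            for b in ref_bins:
                pool = bins[b]
                while True:
                    cand = node_arr[pool[rng.integers(len(pool))]]
                    if cand not in members:
                        members.add(cand)
                        break
            samples[r] = _evaluate(statistic, adj, members)
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")
    return NullDistribution(
        statistic=statistic, samples=samples, n_reps=n_reps, seed=seed,
        set_size=set_size,
    )


def localization_significance(
    observed: float,
    null: NullDistribution,
    direction: str = "greater",
    set_id: str = "",
    n_used: int = 0,
) -> LocalizationResult:
    """z-score and one-sided p-value of an observed statistic under a null.

    ``direction='greater'`` tests for values larger than random (the
    connected-component statistic); ``'less'`` for smaller (the distance
    statistic). A zero-sd null is degenerate: p collapses to 0 or 1 by
    direct comparison and the result is flagged.
    """
    from scipy.stats import norm

    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    degenerate = null.sd == 0.0
    if degenerate:
        if direction == "greater":
            extreme = observed > null.mean
        else:
            extreme = observed < null.mean
        z = math.inf if extreme else (0.0 if observed == null.mean else -math.inf)
        p = 0.0 if extreme else (0.5 if observed == null.mean else 1.0)
    else:
        z = (observed - null.mean) / null.sd
        p = float(norm.sf(z)) if direction == "greater" else float(norm.cdf(z))
    if direction == "greater":
        r = int(np.sum(null.samples >= observed))
    else:
        r = int(np.sum(null.samples <= observed))
    p_emp = (r + 1) / (null.n_reps + 1)
    return LocalizationResult(
        set_id=set_id,
        statistic=null.statistic,
        observed=float(observed),
        null_mean=null.mean,
        null_sd=null.sd,
        z=float(z),
        p=p,
        p_empirical=p_emp,
        n_used=n_used,
        direction=direction,
        degenerate_null=degenerate,
    )
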