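"""Pairwise comparison of tissue-expressed gene sets.

For two tissues A and B the cross-set network distance d_AB is the mean,
over all genes of both sets, of the shortest-path distance to the nearest
gene of the *other* set; a gene shared by both sets contributes 0. Small
d_AB means the two expression neighborhoods co-localize in the
interactome, large d_AB means they are separated. Significance comes from
re-sampling both sets uniformly at their observed sizes. Set overlap is
tested separately with the hypergeometric distribution (expected overlap
n_A * n_B / N for random sets in a universe of N genes), reported with
the Jaccard index. An average-linkage (UPGMA) dendrogram over the d_AB
matrix summarizes the hierarchy of tissue clusters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, norm

from tissuemod._bfs import adjacency, multi_source_distances
from tissuemod.expression import TissueGeneSet


@dataclass
class OverlapResult:
    """Overlap of two gene sets against the hypergeometric expectation."""

    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    expected: float
    expected_int: int
    jaccard: float
    p_hypergeom: float


@dataclass
class SeparationResult:
    """d_AB of one tissue pair with its resampling null and classification."""

    set_a: str
    set_b: str
    d_ab: float
    null_mean: float
    null_sd: float
    z: float
    p_closer: float
    p_separated: float
    classification: str  # closer | separated | non-significant
    n_unreachable: int = 0


def cross_set_distance(g: nx.Graph, set_a, set_b, adj=None) -> float:
    """Mean nearest-cross-member distance d_AB between two gene sets.

    Every gene of A contributes its distance to the nearest gene of B (0
    if it is itself in B) and vice versa; the mean is over |A| + |B|
    contributions. Unreachable genes are excluded from the average.
    """
    d, _ = _cross_set_distance(g, set_a, set_b, adj=adj)
    return d


def _cross_set_distance(g: nx.Graph, set_a, set_b, adj=None) -> tuple[float, int]:
    if adj is None:
        adj = g.adj
    a = set(set_a) & set(adj)
    b = set(set_b) & set(adj)
    if not a or not b:
        raise ValueError("both sets must be non-empty after intersection with graph")
    dist_to_b = multi_source_distances(adj, b)
    dist_to_a = multi_source_distances(adj, a)
    values = [dist_to_b[x] for x in a if x in dist_to_b]
    values += [dist_to_a[x] for x in b if x in dist_to_a]
    n_unreachable = (len(a) + len(b)) - len(values)
    if not values:
        raise ValueError("no reachable cross-set pairs")
    return float(np.mean(values)), n_unreachable


def overlap_statistics(set_a, set_b, universe_size: int) -> OverlapResult:
    """Observed overlap, Jaccard index and two-sided hypergeometric p.

    The expected overlap of two random sets of sizes n_A, n_B in a
    universe of N genes is n_A * n_B / N. The two-sided p-value doubles
    the smaller hypergeometric tail (capped at 1).
    """
    a, b = set(set_a), set(set_b)
    n_a, n_b, n_ov = len(a), len(b), len(a & b)
    if len(a | b) > universe_size:
        raise ValueError("universe smaller than the union of the two sets")
    expected = n_a * n_b / universe_size
    union = n_a + n_b - n_ov
    jaccard = n_ov / union if union else 0.0
    rv = hypergeom(universe_size, n_a, n_b)
    upper = float(rv.sf(n_ov - 1))  # P(X >= n_ov)
    lower = float(rv.cdf(n_ov))  # P(X <= n_ov)
    p = min(1.0, 2.0 * min(upper, lower))
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        n_overlap=n_ov,
        universe=universe_size,
        expected=expected,
        expected_int=round(expected),
        jaccard=jaccard,
        p_hypergeom=p,
    )


def separation_significance(
    g: nx.Graph,
    set_a,
    set_b,
    n_reps: int = 1000,
    seed: int | None = None,
    z_sig: float = 1.6,
    name_a: str = "A",
    name_b: str = "B",
    adj=None,
) -> SeparationResult:
    """Test whether two gene sets are closer or farther than random pairs.

    The null draws both sets independently and uniformly without
    replacement at their observed sizes (chance overlap allowed) and
    recomputes d_AB. Classification at the default |z| >= 1.6:
    ``closer`` when z <= -z_sig, ``separated`` when z >= +z_sig.
    """
    if adj is None:
        adj = adjacency(g)
    nodes = np.array(sorted(adj), dtype=object)
    a = set(set_a) & set(adj)
    b = set(set_b) & set(adj)
    observed, n_unreachable = _cross_set_distance(g, a, b, adj=adj)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_reps)
    for r in range(n_reps):
        ra = set(rng.choice(nodes, size=len(a), replace=False))
        rb = set(rng.choice(nodes, size=len(b), replace=False))
        samples[r], _ = _cross_set_distance(g, ra, rb, adj=adj)
    null_mean = float(np.mean(samples))
    null_sd = float(np.std(samples, ddof=1))
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
        p_sep = float(norm.sf(z))
        p_clo = float(norm.cdf(z))
    else:
        z = 0.0 if observed == null_mean else math.copysign(math.inf, observed - null_mean)
        p_sep = 0.0 if observed > null_mean else 1.0
        p_clo = 0.0 if observed < null_mean else 1.0
    if z >= z_sig:
        classification = "separated"
    elif z <= -z_sig:
        classification = "closer"
    else:
        classification = "non-significant"
    return SeparationResult(
        set_a=name_a,
        set_b=name_b,
        d_ab=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_closer=p_clo,
        p_separated=p_sep,
        classification=classification,
        n_unreachable=n_unreachable,
    )


def all_pairs_separation(
    g: nx.Graph,
    sets: list[TissueGeneSet],
    n_reps: int = 1000,
    seed: int | None = None,
    z_sig: float = 1.6,
) -> pd.DataFrame:
    """Evaluate d_AB significance for all T(T-1)/2 unordered tissue pairs.

    Sub-seeds are derived deterministically from (seed, pair index) so the
    result does not depend on evaluation order. Returns one row per pair;
    the classification counts are in ``df.attrs['counts']``.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 tissue sets")
    adj = adjacency(g)
    rows = []
    for k, (sa, sb) in enumerate(itertools.combinations(sets, 2)):
        sub_seed = (
            None
            if seed is None
            else int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        )
        res = separation_significance(
            g,
            sa.genes,
            sb.genes,
            n_reps=n_reps,
            seed=sub_seed,
            z_sig=z_sig,
            name_a=sa.tissue,
            name_b=sb.tissue,
            adj=adj,
        )
        rows.append(
            {
                "tissue_a": res.set_a,
                "tissue_b": res.set_b,
                "d_ab": res.d_ab,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "z": res.z,
                "p_closer": res.p_closer,
                "p_separated": res.p_separated,
                "classification": res.classification,
            }
        )
    df = pd.DataFrame(rows)
    counts = df["classification"].value_counts().to_dict()
    for key in ("closer", "separated", "non-significant"):
        counts.setdefault(key, 0)
    df.attrs["counts"] = counts
    return df


def distance_matrix(g: nx.Graph, sets: list[TissueGeneSet]) -> pd.DataFrame:
    """Symmetric d_AB matrix over tissue sets (zero diagonal)."""
    adj = adjacency(g)
    names = [s.tissue for s in sets]
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for sa, sb in itertools.combinations(sets, 2):
        d = cross_set_distance(g, sa.genes, sb.genes, adj=adj)
        mat.loc[sa.tissue, sb.tissue] = d
        mat.loc[sb.tissue, sa.tissue] = d
    return mat


def tissue_dendrogram(distances: pd.DataFrame) -> str:
    """Average-linkage (UPGMA) dendrogram over a tissue distance matrix.

    Returns a Newick string whose leaves are the tissue names; merge
    heights are monotone non-decreasing as guaranteed by average linkage
    on a proper dissimilarity. Branch lengths follow the ultrametric
    convention (a node sits at half its merge distance from its leaves).
    """
    mat = distances.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 tissues")
    lm = linkage(squareform(mat, checks=False), method="average")
    return _linkage_to_newick(lm, list(distances.index))


def _linkage_to_newick(lm: np.ndarray, labels: list[str]) -> str:
    """Convert a scipy linkage matrix to Newick with ultrametric heights."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    newick = {i: _quote_label(labels[i]) for i in range(n)}
    for k, (i, j, dist, _) in enumerate(lm):
        i, j = int(i), int(j)
        h = dist / 2.0
        left = f"{newick[i]}:{h - height[i]:.10g}"
        right = f"{newick[j]}:{h - height[j]:.10g}"
        node = n + k
        newick[node] = f"({left},{right})"
        height[node] = h
    return newick[n + len(lm) - 1] + ";"


def _quote_label(label: str) -> str:
    if any(c in label for c in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label
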