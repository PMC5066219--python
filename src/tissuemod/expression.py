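"""Expression significance z-scores and tissue-specific expressed gene sets.

The expression significance of gene *i* in tissue *t* is the standardized
deviation of its expression from the gene's own mean across all tissues:

    z_E(i, t) = (E(i, t) - <E(i)>) / sigma_E(i)

with the mean and standard deviation taken over all tissues (including
*t*). A gene is called expressed in a tissue when z_E meets a threshold
(default 1.0). Genes with zero variance across tissues get z = 0
everywhere and are flagged — by this convention they are never expressed,
so flat housekeeping rows pass through without error.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class SignificanceMatrix:
    """Per-gene, per-tissue expression z-scores with row mean/sd."""

    z: pd.DataFrame  # genes x tissues
    mean: pd.Series  # <E(i)> per gene
    sd: pd.Series  # sigma_E(i) per gene
    zero_variance: pd.Index  # genes with sd == 0 (z forced to 0)
    ddof: int = 1

    @property
    def genes(self) -> pd.Index:
        return self.z.index

    @property
    def tissues(self) -> pd.Index:
        return self.z.columns


@dataclass(frozen=True)
class TissueGeneSet:
    """Genes expressed in one tissue at a given z_E threshold."""

    tissue: str
    genes: frozenset[str]
    threshold: float

    @property
    def n(self) -> int:
        return len(self.genes)


def expression_zscores(matrix: pd.DataFrame, ddof: int = 1) -> SignificanceMatrix:
    """Standardize each gene's expression profile across tissues.

    Parameters
    ----------
    matrix:
        Gene x tissue expression values (any non-negative platform units).
    ddof:
        Delta degrees of freedom for the standard deviation. The default 1
        (sample convention) is a documented choice; 0 gives the population
        convention.
    """
    if matrix.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 tissues")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    flat = sd == 0.0
    safe_sd = np.where(flat, 1.0, sd)
    z = (values - mean[:, None]) / safe_sd[:, None]
    z[flat, :] = 0.0
    return SignificanceMatrix(
        z=pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        mean=pd.Series(mean, index=matrix.index, name="mean"),
        sd=pd.Series(sd, index=matrix.index, name="sd"),
        zero_variance=matrix.index[flat],
        ddof=ddof,
    )


def expressed_gene_set(
    sig: SignificanceMatrix,
    tissue: str,
    z_threshold: float = 1.0,
    restrict_to: nx.Graph | None = None,
) -> TissueGeneSet:
    """Genes with z_E(i, t) >= threshold in one tissue.

    When ``restrict_to`` is given the set is intersected with the
    interactome's nodes, so that downstream network statistics operate on
    genes that actually appear in the graph.
    """
    if tissue not in sig.z.columns:
        raise KeyError(f"unknown tissue {tissue!r}")
    if not np.isfinite(z_threshold):
        raise ValueError("z threshold must be finite")
    col = sig.z[tissue]
    genes = set(col.index[col >= z_threshold])
    if restrict_to is not None:
        genes &= set(restrict_to.nodes)
    return TissueGeneSet(tissue=tissue, genes=frozenset(genes), threshold=z_threshold)


def expression_summary(sets: list[TissueGeneSet], n_genes: int) -> pd.DataFrame:
    """Per-tissue expressed counts and fractions, plus the overall mean.

    Returns one row per tissue with columns ``tissue``, ``n_expressed``
    and ``fraction`` (n_t / n_genes); the mean fraction across tissues is
    stored in ``df.attrs['mean_fraction']``.
    """
    if not sets:
        raise ValueError("no tissue gene sets given")
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rows = [
        {"tissue": s.tissue, "n_expressed": s.n, "fraction": s.n / n_genes}
        for s in sets
    ]
    df = pd.DataFrame(rows, columns=["tissue", "n_expressed", "fraction"])
    df.attrs["mean_fraction"] = float(df["fraction"].mean())
    return df
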