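"""Gene Ontology functional coherence of disease gene sets.

The functional similarity of two genes is a set-overlap coefficient on
their GO term sets for one aspect (biological process bp, molecular
function mf, cellular component cc):

* Simpson: |A ∩ B| / min(|A|, |B|)
* Jaccard: |A ∩ B| / |A ∪ B|

The coherence of a disease d is the average pairwise similarity over its
genes — bp(d), mf(d), cc(d) — and bp(d, t) is the same average
restricted to the disease genes expressed in tissue t. The deviation
Δbp(d, t) = bp(d, t) − bp(d) is positive when tissue restriction makes
the gene set functionally more uniform. Deviations of disease-tissue
pairs with a significant connected component (set CC) are compared to
those without (set N−CC) by the Mann-Whitney U test.

Term sets are used as annotated (no propagation to ancestor terms in the
ontology DAG). Genes with no annotation for an aspect are excluded from
the pair enumeration by default rather than scored zero, so annotation
sparsity does not masquerade as incoherence; ``unannotated='zero'``
switches to scoring them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, tiecorrect, rankdata

from tissuemod.data_io import ASPECTS, DiseaseGeneSet, GOAnnotationTable
from tissuemod.disease_tissue import BipartiteNetwork

MEASURES = ("simpson", "jaccard")


@dataclass
class DiseaseSimilarity:
    """Average pairwise GO similarity of a disease gene set."""

    disease: str
    aspect: str
    measure: str
    value: float  # nan when undefined (< 2 annotated genes)
    n_genes: int  # genes contributing pairs
    n_excluded: int  # unannotated genes left out
    tissue: str | None = None
    deviation: float = math.nan  # value(d, t) - value(d), tissue-restricted only

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass
class GroupComparison:
    """CC vs N-CC comparison of GO similarity deviations for one aspect."""

    aspect: str
    measure: str
    u: float  # Mann-Whitney U of the CC group
    z: float  # tie-corrected normal approximation; >0 = CC larger
    p: float  # two-sided
    n_cc: int
    n_ncc: int
    frac_positive_cc: float  # fraction of Δ > 0 among non-zero Δ
    frac_negative_cc: float
    frac_positive_ncc: float
    frac_negative_ncc: float
    n_zero_cc: int
    n_zero_ncc: int


def simpson_similarity(terms_a, terms_b) -> float:
    """Simpson overlap coefficient |A∩B| / min(|A|,|B|); 0 if either empty."""
    a, b = set(terms_a), set(terms_b)
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def jaccard_similarity(terms_a, terms_b) -> float:
    """Jaccard index |A∩B| / |A∪B|; 0 when both sets are empty."""
    a, b = set(terms_a), set(terms_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


_MEASURE_FN = {"simpson": simpson_similarity, "jaccard": jaccard_similarity}


def disease_similarity(
    disease: DiseaseGeneSet,
    go: GOAnnotationTable,
    aspect: str,
    measure: str = "simpson",
    restrict_to=None,
    unannotated: str = "exclude",
    tissue: str | None = None,
) -> DiseaseSimilarity:
    """Average pairwise GO similarity of a disease's genes for one aspect.

    ``restrict_to`` narrows the gene set (e.g. to the genes expressed in
    a tissue) before the pair enumeration. Fewer than 2 contributing
    genes makes the value undefined (nan, flagged via ``defined``).
    """
    if aspect not in ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if unannotated not in ("exclude", "zero"):
        raise ValueError("unannotated must be 'exclude' or 'zero'")
    genes = set(disease.genes)
    if restrict_to is not None:
        genes &= set(restrict_to)
    term_sets = {g: go.get(g, aspect) for g in genes}
    if unannotated == "exclude":
        usable = sorted(g for g, t in term_sets.items() if t)
    else:
        usable = sorted(genes)
    n_excluded = len(genes) - len(usable)
    if len(usable) < 2:
        return DiseaseSimilarity(
            disease=disease.disease, aspect=aspect, measure=measure,
            value=math.nan, n_genes=len(usable), n_excluded=n_excluded,
            tissue=tissue,
        )
    fn = _MEASURE_FN[measure]
    values = [
        fn(term_sets[g1], term_sets[g2])
        for g1, g2 in itertools.combinations(usable, 2)
    ]
    return DiseaseSimilarity(
        disease=disease.disease, aspect=aspect, measure=measure,
        value=float(np.mean(values)), n_genes=len(usable),
        n_excluded=n_excluded, tissue=tissue,
    )


def similarity_deviation(
    disease: DiseaseGeneSet,
    tissue_genes,
    go: GOAnnotationTable,
    aspect: str,
    measure: str = "simpson",
    tissue: str | None = None,
    unannotated: str = "exclude",
) -> DiseaseSimilarity:
    """Δ = similarity(d, t) − similarity(d) for one disease-tissue pair.

    Undefined terms (too few annotated genes on either side) yield a
    flagged record with nan value and deviation.
    """
    whole = disease_similarity(
        disease, go, aspect, measure, unannotated=unannotated
    )
    restricted = disease_similarity(
        disease, go, aspect, measure, restrict_to=tissue_genes,
        unannotated=unannotated, tissue=tissue,
    )
    delta = (
        restricted.value - whole.value
        if restricted.defined and whole.defined
        else math.nan
    )
    return DiseaseSimilarity(
        disease=disease.disease, aspect=aspect, measure=measure,
        value=restricted.value, n_genes=restricted.n_genes,
        n_excluded=restricted.n_excluded, tissue=tissue, deviation=delta,
    )


def mann_whitney_u(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U of sample x vs y with tie-corrected normal z.

    Returns (U_x, z, two-sided p); positive z means x is stochastically
    larger than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = tiecorrect(ranks)
    if tie == 0:
        return float(u1), 0.0, 1.0
    sd = math.sqrt(tie * n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (u1 - mu) / sd if sd > 0 else 0.0
    p = 2.0 * float(norm.sf(abs(z)))
    return float(u1), float(z), min(1.0, p)


def compare_linked_vs_unlinked(
    deviations: list[DiseaseSimilarity],
    network: BipartiteNetwork,
) -> GroupComparison:
    """Compare Δ distributions of linked (CC) vs unlinked (N−CC) pairs.

    Each deviation record is assigned to CC when its (disease, tissue)
    pair is a link of the bipartite network, to N−CC otherwise. The
    fractions of Δ > 0 / Δ < 0 are over non-zero deviations (zeros
    counted separately), mirroring the binary view of the insets the
    comparison summarizes.
    """
    defined = [r for r in deviations if not math.isnan(r.deviation)]
    if not defined:
        raise ValueError("no defined deviation records")
    aspects = {r.aspect for r in defined}
    measures = {r.measure for r in defined}
    if len(aspects) != 1 or len(measures) != 1:
        raise ValueError("deviations must share one aspect and one measure")
    linked = {(l.disease, l.tissue) for l in network.links}
    cc = [r.deviation for r in defined if (r.disease, r.tissue) in linked]
    ncc = [r.deviation for r in defined if (r.disease, r.tissue) not in linked]
    if not cc or not ncc:
        raise ValueError("both CC and N-CC groups must be non-empty")
    u, z, p = mann_whitney_u(cc, ncc)

    def _fracs(vals):
        pos = sum(1 for v in vals if v > 0)
        neg = sum(1 for v in vals if v < 0)
        zero = len(vals) - pos - neg
        nz = pos + neg
        return (pos / nz if nz else math.nan, neg / nz if nz else math.nan, zero)

    fp_cc, fn_cc, z0_cc = _fracs(cc)
    fp_ncc, fn_ncc, z0_ncc = _fracs(ncc)
    return GroupComparison(
        aspect=aspects.pop(), measure=measures.pop(),
        u=u, z=z, p=p, n_cc=len(cc), n_ncc=len(ncc),
        frac_positive_cc=fp_cc, frac_negative_cc=fn_cc,
        frac_positive_ncc=fp_ncc, frac_negative_ncc=fn_ncc,
        n_zero_cc=z0_cc, n_zero_ncc=z0_ncc,
    )
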