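# Methods

This note documents the statistical models behind `tissuemod`, the
parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical conventions adopted where the
underlying method leaves room.

## Expression significance

The expression significance of gene *i* in tissue *t* is

    z_E(i, t) = (E(i, t) − ⟨E(i)⟩) / σ_E(i)

with the mean and standard deviation taken over **all** tissues,
including *t* itself. The standard deviation uses the sample convention
(divisor *n* − 1) by default; `ddof=0` switches to the population
convention. The choice shifts every z by a factor √((n−1)/n) — at 64
tissues a ~0.8% rescaling, at 8 tissues ~7% — so it is exposed rather
than hidden. A gene is *expressed* in a tissue when `z_E ≥ 1.0`; the
threshold is a parameter (`z_threshold`) because the downstream link
structure is usefully examined at 1.5 as a robustness check (stricter
thresholds shrink every tissue graph, so S and S_total are
non-increasing in the threshold and the link set at 1.5 nests
approximately inside the set at 1.0).

Genes with zero variance across tissues have no defined z; they are
assigned z = 0 everywhere, flagged, and are therefore never expressed.
This lets matrices with flat housekeeping rows run through without
erroring. Whether the input is raw or log-scale expression is the
caller's decision; the matrix is taken at face value.

## Localization statistics

Two statistics quantify whether a gene set agglomerates in one
interactome neighborhood:

* **S** — the size of the largest connected component of the subgraph
  induced by the set. Genes absent from the graph are intersected away
  (and counted); an empty intersection gives S = 0.
* **d_S** — the mean over members of the shortest-path distance to the
  nearest *other* member. Members with no reachable other member are
  excluded from the average rather than assigned a pseudo-distance;
  their count is reported. The nearest-member form (not the all-pairs
  mean) is the standard interactome-localization convention: observed
  values near 1.2 for thousands of genes are only possible when each
  gene is scored against its nearest neighbor.

Significance comes from sets of the same size drawn uniformly without
replacement from the graph's nodes (default 1,000 replicates; the
reference synthetic analyses use 200). The null is summarized by mean
and SD and the observed value expressed as a z-score with a one-sided
normal-tail p-value; an empirical p-value `(r + 1)/(n + 1)` is reported
alongside for when the normality assumption is doubtful. A zero-SD null
(e.g. the set is the whole graph) is flagged and resolved by direct
comparison. Uniform sampling is the stated randomization; a
`degree-binned` option (sample each reference gene's replacement from
its log2-degree bin) is provided because hubs inflate the
connected-component statistic, but it is not the default.

The normal approximation is exactly the thing the calibration check
exercises: on a 500-node graph, z-scores of sets drawn from the null
itself should be standard normal, with ≈5.5% crossing |z| = 1.6. The
calibration uses the **distance** statistic, which is an average and
hence close to normal; the component-size statistic is integer-valued
and visibly lattice-like at small set sizes, so its tail frequencies
wobble around the nominal level even when its mean/SD summary is fine.

## Tissue separation and overlap

For tissues A and B, every gene of A contributes its distance to the
nearest gene of B (0 if it is itself in B), and vice versa; d_AB is the
mean over |A| + |B| contributions. Shared genes contributing zero is
required for highly overlapping tissue pairs to come out closer than
random. The null resamples both sets independently and uniformly at
their observed sizes — overlap is free to occur by chance; nothing in
the underlying method constrains the pair null further. Classification
at |z| ≥ 1.6: `closer` (z ≤ −1.6), `separated` (z ≥ +1.6), else
`non-significant`.

Set overlap is tested with the hypergeometric distribution: expected
overlap `n_A·n_B/N` in a universe of N genes, two-sided p by doubling
the smaller tail (capped at 1). The Jaccard index is reported with it.
The tissue dendrogram is average-linkage (UPGMA) on the raw d_AB
matrix — the simplest linkage consistent with a dissimilarity that is
not guaranteed metric — with Newick branch lengths under the
ultrametric convention (a node sits at half its merge distance).

## Disease–tissue associations

The tissue-specific interactome is the subgraph induced by the tissue's
expressed genes, **not** reduced to its largest component. For each
disease, S_total counts its genes present in that graph and S the
largest connected component they form. The null draws S_total genes
uniformly **from the tissue graph** (not the global interactome) and
recomputes S, 1,000 times by default. Pairs reach the bipartite network
at z ≥ 1.6. Decisions taken where the procedure is underdetermined:

* Pairs with S_total < 2 are untestable; they are kept in the output
  with a flag (rather than dropped) so that counts of "diseases with no
  module in any tissue" remain computable.
* No multiple-testing correction is applied across the disease × tissue
  grid — the raw z threshold is the decision rule. A Benjamini–Hochberg
  column is emitted for users who want one.
* Because the null depends only on (tissue, S_total), null
  distributions are cached per tissue and S_total and shared across
  diseases; their seeds derive from (master seed, tissue, S_total), so
  results are independent of evaluation order.
* The mean number of tissues per disease is reported under both
  denominators (linked diseases only, and all tested diseases), since
  the two conventions answer different questions and are easy to
  conflate.

## GO coherence

Functional similarity of two genes is a set-overlap coefficient on
their GO term sets per aspect: Simpson `|A∩B|/min(|A|,|B|)` (primary)
or Jaccard `|A∩B|/|A∪B|` (robustness; Jaccard ≤ Simpson always). The
coherence of a gene set is the mean over all unordered pairs. Term sets
are used exactly as annotated — no propagation to ancestor terms in the
ontology DAG; propagation would raise all similarities and is a
separate modeling decision. Genes with no annotation for an aspect are
excluded from the pair enumeration (and counted) rather than scored
zero, so annotation sparsity is not mistaken for incoherence; a flag
switches to score-as-zero. Fewer than two usable genes makes the value
undefined (flagged), not zero.

The deviation `Δ = value(d, t) − value(d)` compares the
tissue-restricted coherence to the whole-disease coherence. Linked (CC)
versus unlinked (N−CC) pairs are compared with the Mann–Whitney U test
using the tie-corrected normal approximation; positive z means CC
deviations are stochastically larger. The Δ > 0 / Δ < 0 fractions are
computed over non-zero deviations with zeros counted separately.

## Synthetic data generator

The generator produces the structures the pipeline is designed to
detect, with ground truth:

* **Interactome** — preferential attachment (Barabási–Albert, m = 2),
  giving a heavy-tailed degree distribution and mean degree ≈ 2m; an
  Erdős–Rényi option serves as a homogeneous control. Largest component
  kept.
* **Tissue programs** — each tissue elevates a *connected
  neighborhood*: disjoint regions are grown around randomly chosen seed
  nodes in round-robin fashion (one node per region per round, each new
  node adjacent to its region). Plain nearest-seed partitions were
  rejected because in a scale-free graph the region containing the hub
  swallows most of the network, leaving other tissues without a
  neighborhood; balanced growth gives every tissue a full-size
  connected program. A fraction κ (default 0.9) of each program is the
  neighborhood, the rest uniform genes drawn from the unclaimed pool —
  κ is the single localization knob (κ = 0: uniform sets, localization
  z centered at zero; κ = 1, zero noise: the expressed set equals the
  neighborhood exactly).
* **Expression values** — program genes get a high level (10), others
  background (5), plus Gaussian noise (SD 0.3); genes elevated nowhere
  are instead *suppressed* (level 1) in one random tissue. Suppression
  matters: a flat profile standardizes to pure noise and would cross
  z = 1 in roughly one tissue in seven, destroying the expressed-
  fraction target; one low value pins the rest of the profile near
  +0.35 SD, below threshold. With these levels the per-tissue expressed
  fraction lands on the 10% target to within ±0.005.
* **Disease sets** — planted diseases grow a connected module
  (default 8 genes) by BFS inside the largest connected piece of the
  host tissue's expressed subgraph, then pad to 25 genes with random
  genes outside the host program; other diseases are uniform random
  sets.
* **GO and GWAS** — every gene draws 5 terms per aspect from a
  150-term pool; module members draw `round(boost × 5)` of them from a
  per-disease 5-term core pool instead (boost 1 ⇒ identical sets,
  Simpson 1; boost 0 ⇒ background). Module members get
  −log10 p ~ U(8, 30), other disease genes U(0, 6).

Everything is deterministic under a master seed, with stage sub-seeds
derived from (seed, stage index); regenerated bundles are
byte-identical.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: realistic transcriptome marginals
(expression is a three-level signal plus noise, not a log-normal
continuum), probe-level artifacts and normalization, correlated tissue
programs (programs are disjoint unless seeds are shared, so real
brain-region-style nested overlaps are absent), incomplete and biased
interactome coverage, GO annotation depth heterogeneity, and linkage
disequilibrium structure in GWAS p-values. Recovery of planted modules
shows the statistics detect the structure they define; it does not
certify performance on any particular real atlas.

## Reference conditions and problem sizes

The reference bundle is 2,000 genes, 8 tissues at a 10% expressed
fraction with κ = 0.9, 12 diseases × 25 genes with 4 planted
disease–tissue modules of 8 genes, coherence boost 0.6, and 200-
replicate nulls; a full pipeline run takes ~15 s on one CPU, so the
whole test suite and the acceptance script run comfortably on a laptop.
Null calibration uses a 500-node graph with 50-gene sets, a 1,000-
replicate null and 200 scored draws. File-driven runs record config
hash, seed and per-stage timings in `manifest.json`.

## Known limitations

* The normal approximation for the component-size null is rough for
  small S_total (discrete, skewed); the empirical p-value is the honest
  companion there.
* d_S and d_AB ignore edge weights and directions by design.
* Gene identifiers are matched as exact strings; no mapping layer.
* With few planted links, CC-group fractions in the GO comparison rest
  on a handful of pairs and are reported with their group sizes for
  that reason.
* In a small-world interactome, full-size tissue neighborhoods
  necessarily abut; "separated" tissue pairs in synthetic data are
  separated relative to the resampling null, not geodesically distant
  in any absolute sense.
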