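# Methods

This note documents the models, statistical procedures and numerical
choices behind `admodnet`, in the order the pipeline applies them, and
states what the synthetic validation does and does not establish.

## Synthetic data model

The generator emulates a multi-study, two-condition expression compendium
with a planted differentially co-expressed module.

**Expression.** For each study, samples of both conditions are drawn from
a single-factor Gaussian model: gene g in sample j has
`x_gj = b_g + delta_g + lambda_c * f_j + eps_gj`, with `eps ~ N(0, 1)`, a
per-study per-gene batch shift `b_g ~ N(0, batch_sd^2)`, and a shared
latent factor `f_j ~ N(0, 1)` loading only on the planted module genes.
The loading is `lambda = sqrt(rho / (1 - rho))`, so the expected pairwise
correlation of two module genes is exactly `rho` — this closed form is
what the correlation assertions in the tests rely on. The lesional
condition uses `rho_in` (default 0.8), the non-lesional `rho_out`
(default 0), creating differential co-expression; module genes
additionally receive a standardised lesional mean shift `delta` (default
1.0), so the planted genes are also differentially expressed.

**Defaults** are the package's study conditions and are fixed once: 200
genes, a 20-gene module, a 10-gene knowledge core, 2 studies with 25
samples per condition each (50 per condition overall), `batch_sd = 0.5`.
They represent a deliberately strong-signal, desk-scale regime: large
enough for every stage to have signal, small enough that the full
pipeline runs in seconds.

**Knowledge bases.** Each prior source (GWAS hits, disease genes, drug
targets) contains the knowledge core, optional extra planted genes up to
`overlap_frac * |module|`, and decoys drawn uniformly from non-module
genes (an unbiased null for evidence counting). With the default
`overlap_frac = 0.5` each source is exactly the core, so the core genes
are the designed seed set. The disease catalog holds the query disease
plus decoy diseases on a graded similarity ladder (monotonically
decreasing gene-set overlap with the query); triples link diseases to
drugs with both module and off-module targets, so the module filter and
the query-first ordering are both exercised.

**What the generator does not model:** probe-level effects, saturation,
heavy-tailed noise, correlated batch-by-condition confounding, or
module overlap structure. Passing tests therefore demonstrate the
correctness and calibration of the pipeline's machinery under its own
assumptions — not performance on real microarray compendia.

## Batch adjustment

Per gene and batch, `x' = x - batch_mean + grand_mean`. The per-gene
grand mean is preserved to 1e-12 (asserted). Singleton batches are left
unchanged with a warning, since a one-sample mean adjustment would only
move noise.

## Network inference

Associations are computed pairwise on the batch-adjusted, per-condition
matrix. Correlations are stored as absolute values so strong negative
co-expression ranks as strong association. Mutual information uses
equal-frequency discretisation with `floor(sqrt(n_samples))` bins by
default, and four entropy estimators: maximum likelihood, Miller–Madow
(`H_ML + (m - 1) / 2n`, m = occupied cells), James–Stein shrinkage toward
the uniform with the closed-form optimal intensity, and a
Dirichlet-smoothed estimator with pseudocount 1/m per cell. Constant
genes get association 0 with every partner (flagged, not fatal).

CLR z-scores each entry against the mean/sd of its row's *off-diagonal*
entries (including the structural zero diagonal would make a constant
association background appear informative); negative z-scores are
clipped at 0. ARACNE removes edge (i,j) whenever some triangle partner k
has `min(a_ik, a_jk) > a_ij + eps` (default eps 0; strict inequality, so
exact ties survive). MRNET performs greedy maximum-relevance
minimum-redundancy forward selection of *all* predictors per target,
records each predictor's score at its selection step, and sets
`w_ij = max(s_i^j, s_j^i)` floored at 0. With all-equal inputs this
canonical score-at-selection contract is necessarily asymmetric across
pairs before the final max; the implementation is validated against
exhaustive MRMR enumeration on all 3–4-node instances instead of
idealised symmetry.

The consensus ranks all gene pairs within each of the 21 matrices
(descending score, lexicographic pair tie-break), averages the ranks
(Borda), and keeps the `top_edges` best pairs with weight
`1 - normalised mean rank`. The default edge budget targets mean degree
20 — dense enough that centralities and DIAMOnD have structure to work
with at 200 genes; it is configurable because no principled retention
rule exists for consensus rank aggregation. Borda ties fall back to the
lexicographic pair, which is deterministic but label-dependent;
permutation equivariance therefore holds exactly only for tie-free mean
ranks, and the tests check it in that regime.

Walktrap community detection (igraph implementation, walk length 4) is
provided for completeness of the network-analysis surface; no downstream
stage consumes the partition.

## Meta-analysis

Per study: two-sample linear-model t per gene, two-sided p, and Hedges'
g with the small-sample correction `J = 1 - 3/(4 df - 1)` and variance
`J^2 ((n1+n2)/(n1 n2) + d^2 / (2 df))`. Zero pooled variance yields
t = 0, p = 1, g = 0, flagged. The three branches:

- **Fisher:** `X = -2 sum ln p ~ chi2(2K)`; zero p-values are clamped to
  the smallest positive normal with a warning.
- **Effect size:** DerSimonian–Laird, `tau2 = max(0, (Q - df)/C)`,
  weights `1/(v + tau2)`.
- **Rank product:** `RP = (prod r)^(1/K)`; the p-value is the pooled
  within-study permutation tail (each permutation contributes one null
  RP per gene), which is calibrated per gene under exchangeability. By
  default up- and down-regulation are ranked separately by signed log2
  fold change and each gene keeps its better tail (`best_of_both`); a
  single |log2fc| ranking is available.

Branch ranks are made total orders by breaking ties lexicographically;
the final consensus is the Borda mean rank of the three. All rankings
are invariant to gene input order.

## Evidence, seeds and the differential module

Ranked sources (meta-analysis, differential centrality) grant evidence to
their top `top_n` genes; set sources (bridge, GWAS, disease genes, drug
targets) by membership; seeds need ≥ `min_evidence` (default 3) of the
six. The library default for `top_n` is 1000 (appropriate at
transcriptome scale); the pipeline configuration uses 20 at the 200-gene
synthetic scale, i.e. the top decile, since a cut-off larger than the
gene universe would mark every gene as evidence. Bridges are one-hop
common neighbours of disease-gene pairs (the minimal reading of
"connecting"; a two-hop option exists). Centrality ranks use unweighted
shortest paths — consensus weights are ranks, not distances — harmonic
closeness for disconnected graphs, average ranks for ties, and scores
rounded to 1e-9 before ranking so graph-symmetric nodes are not split by
floating-point accumulation order.

DIAMOnD runs on the binarised consensus edge set with seed weight 1, an
iteration budget of `2 |seeds|` by default, ties broken by higher seed
linkage then lexicographic id. **Significance correction:** the p-value
recorded at an addition is the minimum over all candidates scored that
iteration, so comparing it directly to a fixed alpha is anticonservative
— in a dense network essentially every addition passes 0.05, and the
DIAMOnD authors themselves caution against reading these values as
significance levels. The trace therefore stores both the raw p and
`p_adj = min(1, p * n_candidates)`, and the differential filter uses
`p_adj <= alpha` by default (`correction: candidates`); setting
`correction: none` reproduces the plain raw-p filter. The module is
`seeds ∪ (S_les \ S_non)` where S_* are the significant trace genes per
network; "not significant in non-lesional" covers both absence from the
trace and a failing p. The identity
`|module| = |seeds| + |lesional-specific|` holds by construction.

## Characterisation

Overrepresentation is a one-sided Fisher exact test on the 2×2
module-by-set table over the network gene universe (not the genome),
with Benjamini–Hochberg adjustment across sets. The KS enrichment
compares the normalised rank positions of set members against the
uniform law with the one-sided alternative "shifted toward the top"
(scipy's D+ statistic); calibration under random placement is verified
by simulation. Module edges are scored by the sum of endpoint evidence
counts, ordered by descending score, then descending consensus weight,
then lexicographic pair — a total order for any input — and partitioned
into seed–seed, seed–other and other–other classes.

## Disease similarity and drugs

Catalog synonyms are unioned into their canonical disease before the
`min_genes` (default 5) filter; losing the query disease is fatal.
Distances: `1 - s` for Jaccard, Dice, overlap and cosine similarity on
gene sets, and Euclidean / Hamming on binary membership vectors scaled
by the observed matrix maximum (all-zero matrix if the maximum is 0).

The Ipsen–Mikhailov distance treats each disease-distance matrix as a
weighted graph — by default with similarity weights `A = 1 - d`, zero
diagonal, which is the principal interpretive choice here (a
`weights: distance` flag uses the distances directly). Laplacian
eigenvalues give vibrational frequencies `omega = sqrt(lambda)` (the one
structural zero mode dropped); the spectral density is a sum of
Lorentzians of half-width gamma normalised on [0, ∞); the distance is
the L2 norm of the density difference, integrated by adaptive
quadrature. Gamma is calibrated per node count by Brent root-finding so
that distance(empty, complete) = 1 — the canonical normalisation — and
cached. The six measures are clustered by average linkage on their
pairwise IM distances, and the consensus follows the dendrogram
bottom-up, replacing each merge by the elementwise mean of its two
already-fused children; the root is the consensus matrix. Cluster-size
weighting is therefore implicit in the tree, and the consensus always
lies in the elementwise envelope of its inputs.

Diseases are ranked by ascending consensus distance to the query (query
excluded, ties lexicographic). Drug triples whose target is outside the
disease module are dropped; the rest are ordered by query-disease-first,
then disease rank, then (within a disease) more module targets first,
then lexicographic drug and target ids — the within-disease order is the
package's own deterministic refinement.

## Reproducibility and problem sizes

A single global seed is fanned out to per-stage child seeds by SHA-256
derivation (all below 2^31), so stages are individually re-runnable and
two runs with the same configuration and seed are byte-identical —
asserted file-by-file in the test suite. The shipped configuration runs
the full pipeline at the 200-gene study conditions in roughly 20 seconds
on one CPU; meta-analysis calibration checks use 2000 genes × 5 studies;
oracle-equivalence checks use exhaustive enumeration up to 12 nodes and
brute-force re-computation on graphs of 8–15 nodes. These sizes were
chosen so that every stated property is checked by direct computation.

## Known limitations

- The Gaussian single-factor generator cannot probe robustness to
  outliers, nonlinear dependence (where the MI estimators would diverge
  from the correlation estimators), or overlapping modules.
- Evidence binarisation (`top_n`) and the consensus edge budget
  (`top_edges`) have no data-driven defaults; both are exposed in the
  configuration and results should be read as conditional on them.
- The candidate-corrected DIAMOnD filter is conservative at
  transcriptome scale; `correction: none` restores the permissive raw
  filter when parity with the uncorrected procedure is wanted.
- Hierarchical consensus depends on the linkage (average by default) and
  on the IM weight interpretation; both are configurable.
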