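# Methods

This note records the models, conventions and numerical choices behind
`uuoseq`, what the synthetic data does and does not emulate, and the known
limitations.

## Coordinates and annotation

All in-memory intervals are 0-based half-open on a named chromosome with
an explicit strand; GTF I/O (1-based inclusive, Ensembl attribute dialect)
converts at the file boundary only. The TSS of a minus-strand gene is
`span.end - 1`, the last covered base. A gene's length for RPKM and the
filter is the exon-union length: overlapping exons are merged and counted
once. Biotypes other than `protein_coding` and `lncRNA` (pseudogenes etc.)
are carried through but ignored by the lncRNA stage.

## Normalization and filtering

Size factors use the median-of-ratios definition: the per-gene reference
is the geometric mean of counts across samples, computed over genes with
positive counts in every sample, and `s_j` is the per-sample median of
`count/reference`. Note this is the median of the plain ratios; tools
that take the median in log space differ only when averaging the two
middle elements of an even-length list. Normalized counts satisfy
`normalized * s_j = raw` exactly.

The filter cascade runs in a fixed order with strict `<` comparisons and
thresholds recomputed on the genes surviving the previous rule (the
stricter, sequential reading of a rule list; realized thresholds are
recorded in the `FilterReport`):

1. exon-union length < 500 bp (`min_gene_length`);
2. mean-across-samples normalized count per 100 bp below the 25th
   quantile (type-7 linear-interpolation quantile) of that statistic over
   the genes entering the rule — the per-gene mean, not all gene-sample
   values, is the distribution filtered on;
3. mean-across-samples normalized count below the median over the genes
   entering the rule.

Ties at a threshold are kept. Rule 3 removes half of what reaches it by
construction; the cascade is intentionally aggressive and keeps roughly
the well-measured third of a typical matrix.

Detected genes are counted at RPKM strictly above 0 by default — one
mapped read counts as detection. Any positive RPKM cutoff can be set via
`detection_rpkm_threshold`.

The paired-end inner-mate distance utility is the plain identity
`fragment_mean - 2 * read_length` with the fragment-size SD passed
through; negative values (overlapping mates) are legal output.

## Differential expression

Per gene and contrast, the two groups' normalized counts give a
method-of-moments NB dispersion

    alpha = max(1e-8, (var_within - mean_pooled) / mean_pooled^2)

with `var_within` the pooled within-group variance (df = n1+n2-2). The
effect size is `log2((mean_test + c) / (mean_ref + c))` with pseudocount
`c = 0.5`, which keeps every fold change finite. The test statistic is
the log mean ratio over its delta-method standard error under
`Var = mu + alpha mu^2`:

    z = ln((mB + c)/(mA + c)) / sqrt( vA/(nA (mA+c)^2) + vB/(nB (mB+c)^2) )

with `v = mu + alpha mu^2` evaluated at the group means. Because the
variance in the denominator is itself estimated from 2-5 replicates, `z`
is referred to a Student t distribution with `n1 + n2 - 2` degrees of
freedom rather than a normal; at these group sizes the normal reference
is visibly anticonservative (empirical null rejection ~0.12 at nominal
0.05) while the t reference calibrates the test (~0.05, see the
acceptance suite). Degenerate variance yields p = 1.

Benjamini–Hochberg adjustment is applied within each contrast
(statsmodels' step-up implementation). Two significance gates exist and
both are exposed: DE-list membership uses raw `p < 0.05` (how per-contrast
gene lists are reported), heatmap-style selection uses `FDR < 0.05`.
Status calls: significant and `log2FC >= +1` is *up*, `<= -1` is *down*,
inside the open interval is *significant-subthreshold*; the boundary
counts as passing. Dispersion is estimated per contrast from its two
groups only, while size factors come from all samples once.

Deliberately out of scope: fold-change shrinkage, covariate adjustment,
and numeric replication of any specific DESeq version — correctness is
established by calibration properties and oracles instead.

## lncRNA genomic context

One positional class per lncRNA, resolved in precedence order (overlap
evidence beats promoter proximity):

- **antisense** — >= 1 bp span overlap with a coding gene on the opposite
  strand (same-strand non-intronic overlap is not a separate class; such
  genes fall through to intergenic);
- **intronic** — span entirely inside a single intron (gap between
  consecutive merged exons) of a same-strand coding gene;
- **bidirectional** — no overlap, opposite strands, divergent orientation
  (each TSS pointing away from the other), TSS-to-TSS distance <= 1000 bp
  (`bidirectional_tss_window`; the common divergent-promoter convention,
  config-exposed since no canonical value exists);
- **intergenic** — none of the above.

Neighbor scans collect coding genes within ±100 kb of the lncRNA span
using edge-to-edge distances (0 on overlap); signed distances are negative
upstream *in the lncRNA's strand orientation*. Distances for both the
100 kb window and the 3 kb proximity rule are span-edge based, matching
the "upstream/downstream of the gene" phrasing of such scans; a TSS-based
variant would change borderline cases only.

Concordance per contrast: *similar* when both lncRNA and neighbor are
significant (raw p) with equal log2FC signs, *opposite* with unequal
signs, *none* otherwise; zero log2FC is never concordant. This is
per-contrast sign agreement; qualitative trajectory matching across the
whole time course is a possible alternative reading not implemented.

Candidates are lncRNAs up- or down-regulated in >= 1 contrast whose
nearest coding neighbor is strictly closer than 3 kb, ranked by maximum
|log2FC| (ties: smaller distance, then id). This is a mechanical superset
of what a curated candidate list would contain — the literature-judgement
step of choosing biologically interesting neighbors is not automatable.

## Enrichment

Gene sets arrive as GMT; over-representation is the hypergeometric upper
tail `P[X >= k]` for `X ~ Hypergeom(N, K, n)` with BH across the sets of
a collection. The universe is the tested (filter-surviving) genes, so the
statistic conditions on testability rather than on the whole annotation.
Itemset/concurrence-style analysis and live database retrieval are out of
scope; collections are user input.

## Ordination, clustering, qPCR

Classical (Torgerson) MDS double-centers the squared Euclidean distance
matrix of samples over the top-500-variance genes of
`log2(normalized + 0.5)` and takes the top eigenvectors; negative
eigenvalues are clipped; each axis's sign is fixed (first non-zero
coordinate positive) for determinism. Ward clustering is scipy's
agglomerative Ward on Euclidean distances; leaf order follows a fixed
recursive rule (subtree containing the smaller original index first) so
outputs are reproducible across runs. ddCt:
`ddCt = (Ct_t,cond - Ct_ref,cond) - (Ct_t,base - Ct_ref,base)`,
`fold = 2^-ddCt`, replicate Cts averaged arithmetically in cycle units
first.

## Synthetic data

The generator emulates the study conditions: three groups (4 SO, 3 2D,
3 8D), ~2000 genes of which 40 are lncRNAs planted 10 per positional
class. Counts are NB with `mu_gj = s_j q_g 2^(delta_g(group))` and
`Var = mu + alpha mu^2`:

- baselines `q_g` log-normal (log-mean `ln 150`, log-sd 1.2) — a
  realistic bulk dynamic range; the source study publishes no
  distributional fits, so these are stated, not fitted;
- dispersions `alpha_g` log-normal (log-mean `ln 0.08`, log-sd 0.5),
  typical of bulk tissue replicates;
- size factors uniform on [0.7, 1.4];
- 15% of unpaired genes are differential per ligated group, effect
  magnitudes uniform on [1, 2.5] log2 units, signs fair-coin (both
  volcano tails are exercised);
- every planted lncRNA/host pair receives coupled effects whose sign
  relation is concordant with probability 0.5, else opposing — giving the
  concordance stage non-trivial truth in both directions;
- per-contrast truth is the group-effect difference, so a gene is truly
  DE in `2D_vs_8D` exactly when its two deltas differ.

Coding genes are laid out with >= 2x the neighbor window (>= 210 kb)
edge-to-edge spacing so each planted lncRNA has exactly one coding gene
in its vicinity and its class is unambiguous; half the intergenic
lncRNAs sit closer than the 3 kb proximity cutoff to their host. One
RNG stream per seed, split into named substreams for annotation and
counts, makes outputs bit-identical for identical parameters regardless
of call order.

What the generator does **not** emulate: read-level artefacts (mapping,
GC, length bias within a gene), splice isoforms, batch effects,
correlated genes, outlier samples, and genomes with overlapping or
nested coding genes at realistic densities. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to every pathology of real tissue data. The three fixture
scenarios are `tiny` (40 genes, 2+2+2 samples, for fast smoke tests),
`default` (the study-shaped scenario above) and `null` (no effects, for
type-I error measurement).

## Problem sizes and determinism

The test and acceptance suites run the filter oracle on 20 random
fixtures of up to 2000 genes, the classifier oracle on 500 random
placements, calibration on the 2000-gene null fixture and 20 replicate
default simulations, the hypergeometric sweep on every instance with
N <= 12, and Ward/MDS oracles at n <= 6 / n = 10 — sizes chosen so each
property is measured with adequate precision while the whole suite stays
interactive. All stochastic stages are seeded; identical inputs give
byte-identical outputs (the run manifest records config hash and seed).

## Known limitations

- The moment dispersion estimator is noisy at n <= 4 per group; the t
  reference compensates on average but per-gene dispersions should not be
  interpreted individually.
- The median filter ties DE power to overall expression rank; lowly
  expressed genuinely-DE genes are removed before testing, as in the
  original filter design.
- Candidate selection is fully mechanical; biological prioritization of
  neighbors is left to the user.
- The type-7 quantile, tie-keeping and sequential threshold recomputation
  are documented conventions where the verbal rule descriptions admit
  alternatives; changing them shifts borderline genes only.
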