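# Methods

## Model

`chronet` models a longitudinal epigenomic experiment as an undirected
weighted graph G = (V, E): V is the set of *n* genomic regions (ATAC-seq
peaks or histone-mark domains), and an edge (a, b) with weight ρ_ab is kept
when the Spearman rank correlation of the two regions' log2-normalized
signal across the *m* samples exceeds a threshold. The working assumptions
are: (i) regions controlled by the same temporal program show *monotone*
co-variation of activity, which rank correlation captures while being
robust to outliers and to monotone transforms of the normalization; (ii)
the samples (time points, or averaged replicates thereof) are exchangeable
units for the correlation — no autocorrelation structure is modeled; and
(iii) community structure in G corresponds to co-regulated CRE programs.
The method reports statistical similarity, not causation or directionality.

## Preprocessing

Raw counts are transformed with log-CPM:
`log2((x + prior) / (libsize + 2·prior) × 1e6)`, prior = 0.5. This is a
deliberately self-contained transform: it differs from edgeR's `cpm(log=TRUE)`
(which rescales the prior by library size), and exact parity with edgeR is a
non-goal. Batch correction, when requested, subtracts per-feature batch-mean
deviations (the least-squares solution of a batch indicator model with
zero-sum contrasts), preserving the per-feature grand mean; it is idempotent.
Filtering removes regions on excluded chromosomes (exact string match,
default chrX/chrY), regions with sample variance (denominator m − 1) below a
cutoff (default 0.1; datasets with much larger dynamic range may warrant
1.0), and explicit id lists. Replicates of a time point are averaged,
giving one column per time point in time order. Variance uses the m − 1
denominator everywhere in the package. Temporal trends for display are
per-region z-scores (mean 0, sd 1 with m − 1).

The matrix type accepts any m ≥ 1 so that intermediate products (e.g. a
single averaged time point, or two-column toy inputs) remain representable;
the m ≥ 3 requirement (df = m − 2 ≥ 1) is enforced where correlations and
their p-values are actually computed.

## Correlation engine

Each row is ranked with average ties and standardized with the *population*
sd (divide by m), so that ρ_ab = Z_a·Z_b/m is exactly the Pearson
correlation of the rank vectors. The pair set is partitioned into
chunk-by-chunk blocks, each further split into slabs of at most `step_size`
pair evaluations; blocks only partition the work, so the edge set is
invariant to `chunk_size`, `step_size` and `workers` (threads via joblib;
the dot products release the GIL). ρ is rounded to 12 decimals before
thresholding and binning, which makes bin membership and the stored bytes
reproducible across blockings and BLAS kernels.

A p-value threshold is converted by computing the two-sided critical t at
level p with df = m − 2 and inverting t = ρ√(df/(1−ρ²)). No multiple-testing
correction is applied at this stage: the threshold is a single global edge
filter whose stringency the user sets, and the downstream topology-based τ
selection re-thresholds anyway.

Sign policy: the default keeps positive correlations only (ρ ≥ r_min ≥ 0),
matching the co-accessibility interpretation of communities; an `absolute`
policy admits |ρ| ≥ r_min, binning by |ρ| with the sign stored.

Edges are persisted to a directory of Parquet files (CSV fallback), one per
half-open correlation bin [lo, lo + 0.1) — top bin closed at 1.0 — starting
at floor(r_min, 0.1); bins below the threshold are never materialized. The
manifest records n, m, the threshold, the sign policy, node ids and per-bin
counts, so a network can be re-analyzed at any τ ≥ r_min by reading only
the intersecting bins.

## Threshold selection

For each candidate τ (default: the store's bin lower bounds) the metrics
are computed on the graph over *all* n input regions: density
E/(n(n−1)/2), global transitivity 3·triangles/triples (defined as 0 for
triangle-free or edgeless graphs), LCC and rLCC = LCC/n. Keeping isolated
nodes in the denominators makes values comparable across τ and preserves
every region for downstream annotation. The automatic rule returns the τ
with maximal rLCC; on ties, the largest τ — removing weak edges that do not
change the component structure. Note that when the node set spans several
chromosomes or signal groups that never merge, rLCC can plateau below 1 and
be flat in τ; the tie rule then selects the most stringent threshold, which
is the intended conservative behavior.

## Community detection

Leiden is run on the subgraph of non-isolated nodes with the
RB-configuration quality function (resolution γ) on edge weights ρ, over
the γ grid 0.5–1.5 in steps of 0.1, seeded (default 42) and iterated to
convergence. Because quality values at different γ are not comparable, each
partition is re-scored with standard weighted Newman–Girvan modularity at
γ = 1, and the γ maximizing this Q is selected; ties go to the smaller γ
(the coarser partition), avoiding over-fragmentation. Community ids are
dense from 1 in decreasing size order. Isolated nodes are unlabeled by
default, or form one trailing "disconnected" community on request; they
contribute nothing to Q either way. Pairwise Adjusted Rand Index between
the partitions of the grid is reported so fragmentation with rising γ can
be inspected.

## Characterization

*Target genes.* Each gene (one canonical TSS) gets a basal window 5 kb
upstream / 1 kb downstream (strand-aware), extended in both directions up
to 1 Mb from the TSS, stopping at the nearest neighboring gene's basal
domain and at chromosome bounds; basal windows are never trimmed, even when
they overlap each other (neighboring extended domains legitimately share the
intergenic interval up to each other's basal domain). A region is assigned
every gene whose domain it overlaps by ≥ 1 bp (a midpoint-containment rule
is available). Parameters are exposed; the defaults are the established
basal-plus-extension values.

*Enrichment.* One-sided hypergeometric over-representation of each gene set
(intersected with the background first) in a community's target genes,
against the background of all genes reachable from the full node set —
never a whole-genome background, which would inflate enrichment.
Benjamini–Hochberg correction across all terms of a collection; filter
q < 0.05 by default, or p < p_max when configured.

*Genomic classes.* Each region takes the class (e.g. PLS/pELS/dELS) of its
maximal-overlap annotation interval, ties broken by file order, no overlap
→ "unclassified"; per-community fractions sum to 1.

*TF scoring.* For each TF ChIP-seq experiment (a BED of binding intervals),
a 2×2 table — community vs rest-of-universe × overlaps vs not — gives a
two-sided Fisher exact p (floored at 1e-300) and an odds ratio with the
Haldane–Anscombe +0.5 correction when any cell is zero. The experiment
score is −log10(p)·log2(OR); scores are averaged per TF and the top 10
reported. This is a *local* interval-enrichment scorer over user-supplied
experiment files; scores from a database-backed web service computed over a
different experiment compendium are not numerically comparable, only the
rankings are.

*Trends.* Median and quartiles of per-region z-scores per community and
time point.

## Synthetic data

The generator emulates a peak-level count time course: K communities of
regions, each following one archetype (monotone up/down, early peak,
transient dip, bimodal — the shapes typical of stimulation and development
time courses), defined on the normalized time *rank* to match Spearman's
rank invariance. The log2 mean of region i at time t is
baseline + amplitude·archetype_c(t) (archetype rescaled to unit range over
the time grid), plus i.i.d. Gaussian noise (sd 0.2 by default), plus an
optional per-batch shift; counts are Poisson-sampled from 2^mean (negative
binomial with a dispersion parameter optionally). Baseline 8 (≈256 counts)
reflects typical peak-level coverage, and amplitude 2 (4-fold) a typical
dynamic range of modulated enhancers. Regions are contiguous blocks per
community alternating over two autosomes, plus flat-profile chrX decoys
that the chromosome filter must remove. The matched annotation fixture
plants, per community, one gene set whose genes' TSSs lie inside the
community's block and one TF whose intervals cover the community's regions
plus 5% of the others.

What the generator does *not* emulate: read-level sampling (Tn5 bias, GC
effects, peak-calling artifacts), correlated noise across regions,
cell-type mixtures, and irregular real-time spacing. Passing the recovery
tests therefore shows the pipeline is correct and well-calibrated for
rank-monotone temporal programs under count noise, not that any particular
real dataset will partition cleanly.

## Numerical choices and degenerate inputs

- ρ rounded to 12 decimals before binning; bin boundaries resolved with a
  1e-9 guard so a ρ exactly on a boundary joins the higher bin.
- Constant rows have undefined rank correlation and are rejected with their
  ids (filter first); zero library sizes and empty post-filter matrices are
  errors, never silent.
- Transitivity of an edgeless/triangle-free graph is 0; modularity of an
  edgeless graph is an error.
- Fisher p floored at 1e-300 before log; hypergeometric k = 0 gives p = 1.
- Tie-breaks: τ ties → larger τ; γ ties → smaller γ; TF mean-score ties →
  name ascending; class-overlap ties → annotation file order.

## Problem sizes

The test suite and the acceptance script run on desk-scale instances —
up to 1 020 regions × 16 samples end-to-end (≈ 5·10⁵ correlations),
50 × (200 × 8) matrices for the correlation-oracle sweep, and 100
label-shuffle simulations for the enrichment null — chosen so the full
verification completes in well under a minute on one core while still
exercising every stage at realistic parameter values. The engine itself is
O(n²m) time with O(chunk·step) working memory and has no desk-scale-specific
code path.

## Known limitations

- Correlation networks capture similarity, not regulatory causation or
  direction; indirect co-variation creates edges.
- Small m makes the t-based threshold coarse (at m = 8 and p = 0.1,
  r_min ≈ 0.62); with m < 3 no p-value thresholding is possible.
- The rLCC rule can be flat in τ on multi-block data (see above).
- One TSS per gene; multi-isoform regulatory domains are out of scope.
- Coordinates are taken as-is; cross-assembly lift-over must happen upstream
  (the `lift` hook only enforces this).
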