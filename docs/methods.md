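# Methods

This note records the statistical conventions, default parameters and design
choices behind `gravisig`, and what the synthetic-data generators do and do
not emulate.

## Signatures and thresholds

A directional signature is the set of genes with adj p strictly below
`adj_p_max` (default 0.05) and |log2FC| strictly above `min_abs_lfc`
(default 0.1; 0.2 for stimulated-condition analyses), each carrying
direction = sign(log2FC). Strict inequalities follow the convention in
which a gene sitting exactly on a cutoff is excluded; `build_signature` is
therefore monotone — raising the fold-change cutoff or lowering the p
cutoff never adds a gene. A gene passing the p filter with log2FC exactly 0
is directionless and dropped with a warning.

Cell QC removes cells with a mitochondrial count fraction strictly above
10% or with 250 or fewer detected genes (keep-if detected ≥ 251 — the
literal reading of a "≤ 250 genes removed" rule). The filter is idempotent
and preserves cell order. When no gene carries the mitochondrial prefix the
criterion is inert rather than fatal, with a warning, because dense test
fixtures often omit MT- genes.

The normalized layer is per-sample library-size scaling to 10,000 followed
by log1p. Variance-stabilising model fits are deliberately out of scope;
this transform is monotone, deterministic and comparable across tools, and
every scoring function declares it as its input. `ranksum_de` is a
desk-scale DE stand-in (two-sided Wilcoxon rank-sum per gene, BH-adjusted,
log2FC of pseudocounted means on the normalized layer); it is not a
substitute model for hurdle or negative-binomial fits on real data, and the
package consumes externally produced DE tables for those.

Conserved-gene ranking scores each sign-concordant gene by the sum of its
two log2FC values, ranks positive and negative sums separately by
magnitude, and breaks ties lexicographically by symbol (all rankings in the
package do, for cross-platform determinism).

## Overlap testing

`fisher_overlap_p(k, n_a, n_b, N)` is the exact hypergeometric tail
P(X ≥ k) — identical to a right-tailed Fisher's exact test on the 2×2
overlap table — computed by summation (scipy's `hypergeom.sf`), never by a
normal approximation. The test suite checks it exhaustively against
integer-arithmetic pmf sums for every instance with N ≤ 60.

The universe is an explicit choice: by default the intersection of the two
datasets' tested gene lists, overridable with a fixed genome size, because
the overlap p is meaningless without a declared background. Signature genes
absent from the comparison's tested list cannot overlap by construction;
they are excluded from the Fisher table's `n_a` but reported, and the
percentage denominator remains the full signature size (the convention in
which 106 of 375 prints as 28.3%). Percentages round half away from zero.

The comparison table's significance filter uses raw p by default
(bulk-style tables) and adj p behind a flag (single-cell-style tables),
mirroring how the two table kinds are conventionally thresholded.

Matching modes: `same` (default), `either` (used where a return-to-gravity
contrast makes both directions informative), `opposite`. Counting only
same-direction overlaps is conservative under a direction-agnostic null
(roughly half of chance overlaps match in sign), so the type-I calibration
property — null false-positive rate in [0.03, 0.07] — is asserted in
`either` mode, where the test is calibrated up to the discreteness of the
exact tail.

Ortholog translation expands one-to-many mappings (each target inherits the
source direction), drops unmapped genes with a count, and drops targets
receiving conflicting directions from two sources.

## Scoring

* **Weighted clock** (`iage_index`): score = Σ coefficient × normalized
  expression over the weighted genes present; absent genes contribute 0 and
  are logged; the score is linear in the coefficients. The clock
  coefficients themselves are an input file, not shipped facts.
* **Module score** (`module_score`): genes are binned into 24
  equal-frequency bins of average expression; each set gene draws 100
  control genes from its bin — without replacement when the bin suffices,
  with replacement otherwise, so small universes never fail — using a
  seeded generator (bit-reproducible). Score = mean(set) − mean(pooled
  controls); constant matrices and self-control configurations score 0, and
  adding a constant to the whole layer changes nothing.
* **ssGSEA** (`ssgsea_score`): genes ordered by decreasing value
  (lexicographic tie-break); with position i in 1..N, in-set genes weigh
  (N − i + 1)^α (α default 0.25); the score is the summed difference of the
  weighted in-set ECDF and the uniform out-of-set ECDF, unnormalized. At
  α = 0 the score is rank-based, hence invariant to strictly monotone
  transforms.
* **Group comparison** (`compare_groups`): two-tailed Mann–Whitney; exact
  permutation enumeration with mid-ranks for combined n ≤ 20 (configurable),
  tie-corrected normal approximation beyond, without continuity correction
  so identical groups give p = 1 exactly. Two-tailed p is
  min(1, 2·min(lower tail, upper tail)), symmetric under label exchange.

Taxon relative abundance is reads/total(host + non-host) per sample, with
zero totals mapping to frequency 0 under a warning.

## GCEA

Each compound class (drug / food / lincs) is tested against its own
universal gene set — the union of genes interacting with at least one
compound of the class — because the three corpora come from different
sources and their raw tables are not comparable. DEGs outside the universe
are excluded from `n` (the 2×2 table must live inside one finite universe)
and counted. Confidence scores never weight the test (the test is an
unweighted overlap by design); they only fill the top-compound report
matrix. An optional load-time score threshold exists (default 0: no
threshold, the least-assuming choice where none is prescribed). Adjustment
is Bonferroni over the compounds tested in the class, with BH available
behind a flag for exploration. Output ordering is (p, compound_id) —
deterministic under ties.

## Reversal

The core set is built from signature genes that are significant (raw
p < 0.05) and sign-concordant in an independent bulk contrast, partitioned
into up- and down-sets. Reversal metrics:

* sign-flip fraction; a treated log2FC of exactly 0 is not a reversal; the
  headline percent is nearest-integer (74/106 prints as 70%) with the raw
  fraction retained;
* Pearson correlation of reference vs treated log2FC (error on zero
  variance, since r is undefined);
* GSEA running sum: hits step by |stat|^w normalized over the set's hits
  (w default 1), misses by −1/(N − Nh); the ES is the signed value at
  maximal absolute deviation, so treatment-induced inversion appears as a
  sign change. When the positive and negative extrema tie exactly in
  magnitude the first-attained extremum is reported; at w = 0 negating the
  ranking negates the ES exactly except at such ties, where only the
  magnitude is preserved (a tie means the instance is its own mirror image,
  so no convention can flip the sign). The permutation p permutes gene
  labels with a seeded generator — only ranked statistics, not expression
  replicates, exist at this stage — and is two-sided with the +1
  correction, hence never 0.

Both GSEA rankings in `reversal_report` (reference and treated) are built
over the core genes shared with the treated table, keeping the report
self-contained; the up/down partitions are strict subsets of that ranking
whenever both directions are represented.

## Synthetic data

The generators emulate the *statistical structure* the pipeline assumes,
with recorded ground truth; they do not attempt realism beyond it.

* `simulate_expression`: negative-binomial counts, variance
  = μ + φμ² with dispersion φ = 0.5 (a typical single-cell overdispersion
  scale); baseline gene means log-normal(ln 5, 1.0) — counts of roughly
  0.5–50 per cell, the expressed-gene stratum where DE calling operates;
  that choice was made once, from a design-stage power analysis of the
  rank-sum pipeline, so that the planted-recovery regime (500 genes, 10%
  planted at |log2FC| = 1, 100 cells per condition → ≥ 90% recovery at
  adj p < 0.05) is a property of the conditions rather than of a lucky
  seed. Planted genes scale one condition's mean by 2^(±lfc).
* `simulate_deg_pair`: table A carries the planted signature
  (adj p < 0.05, |log2FC| > 0.1); a planted fraction of it is significant
  in table B with the same sign; all other B entries are null with p ~
  Uniform(0, 1) and log2FC ~ Normal(0, σ). Uniform null p-values are drawn
  directly rather than simulated through tests so calibration checks are
  exact in expectation. Note the realized same-direction overlap slightly
  exceeds the planted fraction: ~5% of the non-planted signature genes are
  significant in B by chance and half of those match in sign.
* `simulate_interactions`: planted compounds draw a fixed fraction of
  their genes from the DEG list; background compounds draw a background
  fraction, or sample uniformly from the whole pool when that fraction is
  None (the no-structure null). `degree_sigma > 0` draws per-compound
  degree from a log-normal around `genes_per_compound`, reflecting the
  heavy-tailed degree distributions of real compound–gene corpora; the
  null-calibration checks use uniform background with variable degree so
  the discrete exact test's attained level is averaged over supports
  instead of pinned to one lattice point. Scores are Uniform(150, 1000).
* `simulate_weighted_gene_set`: Normal(0, σ) coefficients, seeded.

What passing tests on these inputs shows: the pipeline's counting, testing,
adjustment and ranking logic is correct, calibrated under its nulls, and
recovers planted truth at stated effect sizes. What it does not show:
behaviour under real single-cell artefacts (cell-type mixtures, dropout
structure, batch effects, correlated genes), which the generators do not
model — conclusions about real data still require the externally fitted DE
tables the pipeline is designed to consume.

## Problem sizes and determinism

Test-suite and acceptance-script simulations use 200–2,000 genes or
compounds, 100 cells per condition and 1,000–2,000 null replicates — sizes
at which every planted effect is comfortably detectable and exact
enumeration oracles remain exhaustive (N ≤ 60 for the Fisher sweep, ≤ 10
genes for the GSEA sweep, combined n ≤ 8 for Mann–Whitney enumeration).
Every stochastic step takes an explicit seed, and each generator is a pure
function of (parameters, seed).

## Known limitations

* The percentage denominators and universe sizes of published comparisons
  are analysis choices; when reproducing a published overlap both the
  full-signature and tested-only denominators are reported.
* Bonferroni over a compound class treats compounds as independent tests,
  which they are not (shared targets); this matches the stated procedure
  and is conservative.
* The exact Mann–Whitney branch enumerates C(n, n1) assignments; the
  default exact/asymptotic boundary (combined n = 20) keeps that below
  ~185k evaluations.
* `ssgsea_score` and `gsea_es` are single-list statistics; no
  across-sample ES normalization is applied unless requested.
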