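# Methods

## Scope and model

`sccmap` ranks drug mechanisms of action (MOA) by how strongly their
perturbation signatures oppose the transcriptional program of a rare,
disease-critical cell population found in scRNA-seq data. The pipeline has
three statistical layers: (i) evidence combination across pairwise
differential-expression (DE) comparisons via π-scores and a one-sample
t-test, (ii) set-overlap inference via one-sided Fisher's exact tests, and
(iii) enrichment of negative query–library correlations via Firth-penalized
logistic regression. Everything else (QC, normalization, clustering,
correlation) is standard single-cell and CMaP machinery wired around those
layers.

## Preprocessing and clustering

Cells are kept when they have at least 500 genes with UMI > 0 **and** at
most 10% mitochondrial UMIs; both comparisons are strict on the failing
side, so a cell at exactly the threshold is retained. Mitochondrial genes
are recognized by the `MT-` name prefix, and the fraction is computed on
raw UMIs before normalization.

Normalization is LogNormalize, `ln(1 + 10⁴ · count / cell_total)`.
Variable genes are ranked by vst standardized variance on raw counts: a
local regression of log₁₀ variance on log₁₀ mean predicts each gene's
expected standard deviation, counts are standardized against it, clipped at
√n_cells, and the variance of the clipped values is the score. The local
regression is statsmodels' lowess with span 0.3 (a degree-1 local fit;
the original vst recipe uses a degree-2 loess — on count data the
difference moves a handful of genes near the rank-2000 boundary and none of
the strongly variable ones).

PCA operates on the per-gene centered/unit-scaled HVG submatrix, clipped at
±10. The decomposition is an exact symmetric eigendecomposition of the
gene–gene covariance (Lanczos with a fixed all-ones start vector), not a
randomized SVD: this makes the embedding deterministic and invariant to
cell order, which the test suite asserts. Components are sign-fixed so the
largest-magnitude gene loading is positive.

The SNN graph uses k = 20 nearest neighbors (each cell's neighbor set
includes itself), Jaccard edge weights, and prunes edges below 1/15 — the
conventional defaults, which the upstream description leaves implicit.
Louvain modularity optimization (igraph's multilevel algorithm) runs at
resolution 0.8 per sample and 0.4 for joint clustering; the RNG is
explicitly seeded (default 0). Cluster labels are contiguous integers from
0 ordered by decreasing size. Joint clustering concatenates two samples
over their shared genes with no batch correction — adequate for samples
sharing a technology and a planted common population, and deliberately
simpler than anchor-based integration, which is prior published machinery
rather than part of this protocol. The per-cluster sample composition table
it emits makes batch-driven splits visible.

## Cluster-annotating signatures

For cluster *c* among *n_t* clusters, DE against each other cluster yields
per gene a log₂ fold change φ (de-logged group means with pseudocount 1)
and a BH-adjusted p-value P (adjusted within each comparison; the adjusted
value is deliberately used inside π). Then

    π = φ · (−log₁₀ P),     P floored at 1e-300.

Per gene the *n_t* − 1 scores are combined by a one-sided one-sample
t-test of mean π against μ₀ = 2, the score of a gene exactly at the
conventional "differentially up-regulated" cutoff (LFC 1, adjusted p
0.01). Genes present in fewer than two comparisons are reported untested
rather than zero-filled — imputing zeros would bias the test toward
rejection. Zero within-gene variance is degenerate: p is set to 0 / 0.5 / 1
by the sign of (mean − μ₀) and the gene is flagged. The t-test p-values are
BH-adjusted across tested genes and the signature (CAS) is the ≤200 most
significant genes at FDR < 0.05, ordered by (FDR, p, mean π desc, gene id)
for a total deterministic order.

### The DE engine

The default engine is a simplified two-part hurdle test built for
zero-inflated UMI data: a 1-df chi-square score test on the detection rate
plus a Welch t-test on log-normalized expression among expressing cells
(needs ≥2 expressing cells per group), combined by Fisher's method with
2 df per available part. Genes expressed in fewer than 3 cells of the two
groups are dropped. A plain Welch engine (`engine="welch"`) and a TSV
import path for externally computed DE tables (e.g. a full
hurdle-regression package with covariates) are provided; the protocol's
contribution is the combination scheme, not the per-comparison test, and
the engine is pluggable for exactly that reason. Under permuted labels the
combined p-values are approximately uniform (KS distance < 0.04 at 100
cells per group in the suite's simulation).

## Population identification and matching

Each cluster's FDR-significant CAS genes are tested for marker-panel
enrichment by a one-sided Fisher's exact test over the genes tested in that
signature; p-values are BH-adjusted across clusters. The disease cluster is
the smallest-p cluster provided it reaches FDR < 0.05 and nonzero overlap —
otherwise the result is an explicit "not identified" status rather than a
forced pick. Odds ratios use the Haldane–Anscombe 0.5 correction only when
a table cell is zero; p-values always come from the exact test.

Matching against control clusters compares top-200 CAS lists over the
shared tested universe. Where the original workflow picked matched clusters
by inspecting a dendrogram/heat map, this implementation mechanizes the
choice: control clusters with log₁₀ OR ≥ 1 (the heat-map highlight
threshold) and FDR < 0.05 are selected, and the complete-linkage/Euclidean
hierarchical-clustering leaf order of the overlap-count matrix is emitted
for reporting. Selecting no cluster is an error that names the best
observed OR and FDR.

## Disease signature, pseudo-bulk, connectivity

The DCS contrasts the disease-cluster cells against the pooled cells of all
matched control clusters in a single two-group comparison (pooling, not
per-cluster meta-analysis, matches the single-contrast design). The
pseudo-bulk signature contrasts whole samples; for a ~1% population the
program fold changes shrink by roughly the mixing fraction, which is the
quantitative basis of the attenuation check in the acceptance suite.

The query takes the 125 most significant up- and 125 most significant
down-regulated DCS genes (FDR < 0.05; fewer taken with a warning if fewer
exist) and *then* intersects with the landmark panel — ranking first,
matching second. `select_within_landmarks=True` implements the reverse
order for users who want exactly 250 matched genes. Query values are log₂
fold changes by default (the usual CMaP convention; the upstream
description does not fix the quantity), with π and signed −log₁₀ FDR as
alternatives. Pearson correlation against each signature uses the exact
t transform, t = r√(n−2)/√(1−r²), with the lower tail as the one-sided
negative-correlation p; 1−r² is floored at 1e-12, signatures with fewer
than 10 matched genes or zero variance are flagged and skipped.

## MOA enrichment

For MOA *k*, membership m_k ∈ {0,1} of every signature is regressed on
x = −log₁₀ p_neg (raw one-sided p, floored at 1e-300):
logit Pr(m_k = 1) = β₀ + β₁x. MOA categories are small relative to the
library, so maximum likelihood is biased and diverges under separation; the
fit maximizes the Jeffreys-penalized likelihood ℓ(β) + ½ log det I(β)
(Firth's correction) by Newton iteration on the modified score with
step-halving, which keeps the objective monotone and the estimate finite
even under complete separation. Intercept-only fits reduce to the closed
form p̂ = (k + ½)/(n + 1), which the suite verifies exhaustively.

Inference is a penalized likelihood-ratio test (the reduced fit maximizes
the profile penalized likelihood with β₁ = 0, using the full-design
information in the penalty), halved and signed for the one-sided
alternative β₁ > 0; a Wald variant is available. pLRT was preferred over
Wald for its small-sample behavior. Signatures with a null MOA stay in the
background (m_k = 0 for all k) but form no category; only MOAs with ≥5
signatures are tested (the figure-level "≥100/≥150 signatures" filters of a
real LINCS-scale analysis are report-stage options, not fit-stage ones).
The reported odds ratio exp(β₁) is per unit of −log₁₀ p_neg. BH correction
runs across tested MOAs. Under permutation of x the one-sided test rejects
at very close to its nominal 5% level (0.05 ± 0.02 over 200 permutations in
the acceptance suite).

## Synthetic data

`simulate_counts` draws Gamma-Poisson (negative-binomial, var = μ + μ²/θ,
shared θ = 5) UMI counts for 8 healthy cell types (defaults 900…350 cells,
3000 genes, ~2500 UMI/cell, lognormal library-size spread clamped to
[0.6, 2]) plus a 55-cell disease population derived from type 0 by
eight-fold up-regulation of an 8-gene marker panel (near-silent elsewhere)
and a 100-gene disease program. Each cell type additionally has a 120-gene
identity block at five-fold. Eight types (rather than the minimum that
would cluster) matter for a structural reason: a cell-type identity gene's
π-score is ~0 in the one comparison against the disease population's own
base type, and with many clusters that single weak comparison cannot drag
the one-sample t-test below significance — mirroring the many-cluster
regime of real tissue. Per-type profiles are renormalized to a fixed
library-size scale, so planted fold changes are computed from the realized
profiles (they exceed four-fold throughout). 4% of cells are planted QC
failures, half at 12% depth (below the 500-detected-genes cut), half with
mitochondrial share inflated to 25%; healthy cells carry 3% mitochondrial
mass and pass both cuts with overwhelming probability at these depths
(the pass guarantee assumes ≥~1000 genes at the default depth). Truth
labels (cell type, disease membership, planted QC status) are emitted in a
sidecar table and never consumed by the pipeline.

`simulate_library` builds a landmark panel (978 genes by default: the
disease program plus random non-mitochondrial genes) and a library of 1040
signatures across 51 MOAs: 20 signatures of the planted MOA equal
−a/√(1−a²)·σ·z(program) + N(0, σ²) noise (so their expected correlation
with the program is ≈ −a; a = 0.8, σ = 1 by default), the rest pure noise,
10% with a null MOA label. With a = 1 and σ = 0 the anti-correlation is
exactly −1, which the suite asserts.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, gene–gene correlation within a cell type, mean-dependent dispersion,
dose–response structure or cell-line heterogeneity in the library. Passing
tests therefore demonstrate that the machinery recovers planted structure
under clean negative-binomial noise at realistic sizes — not robustness to
the full messiness of droplet data or of LINCS signatures.

## Problem sizes and numerical choices

The acceptance suite runs ten seeded end-to-end replicates (~3850 + ~3800
cells × 3000 genes each) plus a 200-permutation calibration; the whole
suite completes in well under half an hour on one CPU, and
`scripts/acceptance.py` reruns the same measurements in a few minutes.
Tolerances: p-value floors at 1e-300 before logs; (1−r²) floored at 1e-12;
Firth Newton stops when the modified score drops below 1e-7 (or the step
below `tol`); BH via statsmodels; ties in every ranked list are broken
deterministically ending at the gene id.

## Known limitations

- Joint clustering has no batch correction; strongly batched samples will
  split by sample, visible in the composition table.
- The simplified hurdle engine has no cell-level covariates (e.g. detection
  rate); users wanting a full hurdle regression can import its DE tables.
- The marker-based identification assumes the panel is specific; with no
  cluster reaching FDR < 0.05 the pipeline stops at "not identified" by
  design.
- Connectivity uses plain Pearson correlation on matched genes; weighted or
  running-sum connectivity scores are out of scope.
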