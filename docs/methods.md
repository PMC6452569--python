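# Methods

## Problem and scope

Myometrial expression studies of term pregnancy compare quiescent (NL) and
laboring (IL) tissue, sometimes splitting labor into early (ILEa, cervical
dilation < 3 cm) and established (ILEs, > 3 cm) stages. Individual studies
are small and sit on different platforms (RNA-seq counts vs microarray
intensities), so a labor signature worth trusting must survive integration:
the same genes, directions, and patterns across studies. This package
implements that integration as a library: normalization and merging,
multi-comparison differential expression, repeated sparse classification,
SVD eigen-patterns, over-representation, and signaling-network
reconstruction, with a synthetic-data generator that stands in for the
original cohorts.

## Synthetic data model

`simulate.SimConfig` defines the study conditions. Defaults: three studies
with group sizes (5 NL, 5 IL), (8 NL, 8 ILEa, 6 ILEs), (20 NL, 19 IL) on
platforms (count, count, intensity); 2000 genes per study of which 1500 are
shared by all studies and the rest are study-private; 100 labor-up and 30
labor-down planted genes among the shared ones with per-gene effects drawn
from N(1.2, 0.3²) on the log2 scale (clipped below at 0.1 so directions
never flip); ILEa effects scaled by 0.7 (early labor carries an attenuated
version of the established signature); per-study, per-gene batch shifts
N(0, 0.3²) on the log2 scale; one "ambiguous" sample per study that is
labeled as labor but generated from the NL expectation (in the three-group
study this sample sits in ILEa), emulating clinically mislabeled samples.

Count studies draw negative-binomial counts with mean 2^(log2-mean) and
variance μ + αμ² at dispersion α = 0.2; intensity studies add N(0, 0.4²)
noise directly on the log2 scale. Baseline log2 expression is uniform on
[3, 9] for shared genes and [1, 9] for private genes, so the zero-expression
filter has genuine work on the count platforms. All randomness flows from a
single `numpy` Generator seeded by `SimConfig.seed`; identical
configurations give bit-identical matrices and files.

What the generator does **not** emulate: probe-level microarray artifacts,
library-size variation, correlated gene modules beyond the planted
signature, immune-cell infiltration, or read-level data. Passing tests on
this generator demonstrate that the pipeline recovers the structure it
assumes — a shared monotone signature across platform noise — not that it
would resolve every pathology of real cohorts.

### A note on per-gene power at the default noise level

NB dispersion α = 0.2 puts a floor of √ln(1+α)/ln 2 ≈ 0.62 on the per-gene
log2-scale standard deviation regardless of expression level. For a 5-vs-5
comparison, even a strong planted gene (|log2FC| ≥ 1.2) then has a Welch
noncentrality near 3.5 against a BH-adjusted critical value near 4, i.e.
well under 50% power — and the high-confidence set requires significance in
all four comparisons simultaneously. Consequently the strict four-way
intersection is essentially empty under the default conditions, while every
aggregate analysis (classification, SVD separation, enrichment of the
single well-powered comparison, network recovery) sees the signature
clearly, because those pool evidence over ~130 planted genes. This is the
intended behavior of the stated conditions, and mirrors the real
methodological point: small cohorts cannot certify individual genes, but a
shared multivariate signature still transfers across studies.

## Preprocessing and merging

Per study: duplicate gene rows collapse to the duplicate with the highest
mean expression; genes with zero expression in more than `max_zero_samples`
(default 3) samples are removed (strict inequality: zeros in exactly 3
samples are kept); count matrices are transformed by log2(x+1) and relabeled
as intensity, already-log-scale studies pass through with a logged no-op.

"Row and column normalization" is one pass of gene-wise z-scoring followed
by one pass of sample-wise z-scoring, both with the sample (n−1) standard
deviation; constant rows or columns map to zeros rather than raising. The
column pass runs last, so every column of the output has mean 0 and sd 1
exactly (to 1e-8); re-applying the final pass is a no-op, but the full
two-pass operation is not idempotent and is deliberately applied once.

Merging restricts every study to the genes shared by all of them **before**
normalizing each study and concatenating columns, so the combined matrix
retains exact column standardization. Merging is order-insensitive up to
column order.

## Differential expression

Each comparison is a per-gene Welch (unequal-variance) two-sample t-test on
log2 values, with log2FC = condition mean − baseline mean, fold change
2^|log2FC| (a ratio of geometric means), and BH adjustment across all tested
genes of that comparison. Genes constant in both groups get p = 1.
Significance is strict: q < 0.05 AND fold change > 1.5. The standard
contrast list takes IL vs NL from two-group studies and ILEa vs NL plus
ILEs vs NL from a three-group study. The high-confidence set is the
intersection of the significant sets under the additional requirement of
identical direction in every comparison (a direction-agnostic flag exists
for comparison); per-gene medians of log2FC and q across comparisons are
reported.

One in-repo test replaces the per-platform external tools a practitioner
might use (count-model GLMs for RNA-seq, moderated linear models for
arrays): a single auditable test keeps the integration self-contained, and
the quantity of interest here is cross-study agreement, not per-tool
replication.

## Classification

L1-penalized ("lasso") or elastic-net logistic regression
(scikit-learn; liblinear for binomial lasso, saga otherwise; elastic-net
mixing fixed at 0.5 by default — the canonical midpoint, configurable).
Within-study evaluation: `n_runs` repetitions of stratified k-fold CV with
fresh folds per run (k = 3 for ~10-sample studies, 5 otherwise; folds are
stratified because 5-sample classes make unstratified folds degenerate).
Per fold, features are standardized with training-fold statistics only and
the penalty strength C is chosen by an inner stratified CV (default 5
folds, automatically reduced for tiny classes) minimizing binomial deviance
(log loss) over a fixed grid {0.01 … 10}; ties prefer the stronger penalty.
The saga solver runs at a loose tolerance (1e-2): it only has to rank
penalty values and produce stable supports. All estimators carry a fixed
`random_state`, so identical inputs give identical models.

Scoring: per run, every sample is tested exactly once; AUC is computed per
run on P(labor) with ILEa/ILEs pooled into one labor class, and the mean
over runs is reported (per-run AUCs are kept so quantiles can be formed
without inventing a pooling rule). Classification frequencies keep the
three classes separate in multinomial mode; the predicted class is the
highest-probability one with exact ties broken toward NL. Feature
aggregation counts, per gene (per class when multinomial), the number of
models selecting it and its mean coefficient.

Cross-study transfer trains `n_runs` models on one full study (three-group
training studies are reduced to NL and ILEs for comparability; training is
always binomial; stochasticity comes from the inner-CV splits), restricted
to the genes shared with the test study, and applies each model to every
test sample.

## SVD eigen-patterns

Full SVD of the combined matrix via `numpy.linalg.svd`. Naming follows the
transcriptomics convention: columns of U are eigen-samples (gene-indexed),
columns of V are eigen-genes (sample-indexed). Sign ambiguity is resolved
deterministically: component 1 is oriented so the mean eigen-gene loading
over labor-labeled samples is ≥ 0 (labor positive); without labels, and for
higher components, the largest-|loading| gene entry is made positive. The
energy of component i is σᵢ²/Σσⱼ², always reported against the full
spectrum. Pathway-restricted SVD re-runs the decomposition on the row
subset belonging to a gene set (≥ 2 genes required). The unsupervised
phenotype score of a profile normalized like the matrix rows is its dot
product with the first eigen-sample over shared genes (≥ 50% overlap
required); positive calls IL, ties call NL — conservative toward the
quiescent baseline.

## Over-representation

Exact hypergeometric upper tail P[X ≥ k] per gene set after restricting
members to the universe and applying size bounds (default 5–500), BH across
retained sets. The universe is the set of measured genes in the combined
matrix, not the genome: that is what was observable. No combined or
rank-based score is layered on top; the exact tail probability is the
deterministic core of over-representation.

## Signaling networks

The interactome is a directed graph with edge confidences in (0, 1]
(duplicate edges collapse to the maximum; self-loops are rejected) and a
flagged subset of transcription-factor → target edges that must exist in
the edge list. Edge cost is 1 − confidence by default (−log confidence
available); summing raw confidences would favor low-confidence edges, and
1 − c keeps edge costs on the same [0, 1] scale as node costs.

Node costs come from the dominant eigen-sample's gene loadings:

| scheme     | cost                         | cheap nodes                    |
|------------|------------------------------|--------------------------------|
| general    | 1 − minmax(abs(loading))     | strong loadings of either sign |
| non_labor  | minmax(loading)              | most-negative (NL-associated)  |
| labor      | 1 − minmax(loading)          | most-positive (IL-associated)  |

Nodes without a loading cost 1 (unmeasured genes are never preferred);
all-equal loadings map to 0.5 rather than dividing by zero. The non-labor
and labor cost vectors sum to 1 elementwise by construction.

Sinks are the top-loading genes per scheme (both signs for general,
`n_per_side` each), restricted to nodes with at least one incoming TF edge;
excluded genes are reported as uncoverable. A path's cost is the sum of its
node costs (source and sink included) plus its edge costs, and its final
edge must be a TF → sink edge. The search runs one Dijkstra per source with
edge traversal cost = edge cost + head node cost (source cost charged
once), excluding the sink from path interiors, then minimizes over TF
parents of the sink; heap entries are (cost, path) tuples, so among
equal-cost paths the lexicographically smallest node sequence wins —
deterministic and matched by the exhaustive-enumeration oracle in the
tests. For the general scheme, the ⌈retain_fraction × count⌉ cheapest paths
are kept (global ranking across sources; ceiling keeps at least half; ties
at the boundary resolve lexicographically); phenotype schemes keep all
paths. The output network is the union of retained paths only, with roles
receptor / signaling / transcription_factor / target_gene (source and sink
roles take precedence), exported as SIF, GraphML, node/edge attribute TSVs,
and a JSON path manifest.

## Pipeline driver and reproducibility

`pipeline.run_pipeline` executes simulate → preprocess → differential
expression → classification (within-study CV plus all ordered cross-study
pairs — six tasks for three studies) → SVD (global + program sets) →
over-representation → networks (three schemes), writing every intermediate
artifact and a run report with the parameters actually used and SHA-256
checksums of all outputs. A single global seed fans out to per-stage seeds
by fixed offsets; two runs with the same configuration produce identical
checksums. Expression and network files serialize floats with 17
significant digits (exact double round-trip); derived report tables use 10.

## Problem sizes in tests and the acceptance script

The test suite runs the default generator conditions with classification at
`n_runs` = 20 (within-study and transfer checks) and the pipeline test on a
reduced design (300 genes, three small studies, 2 runs); the acceptance
script uses 20 runs within-study and 10 per cross-study task. These sizes
keep the repeated nested-CV workload proportionate while leaving the
per-run estimates stable (AUC means move by < 0.01 between 10 and 100
runs on this generator).

## Known limitations

- The Welch test is applied to count data after log2(x+1); a count GLM
  would be more powerful at very low expression.
- The union network annotates a node with a single role even when it plays
  several (source and sink precedence over TF).
- Cross-study standardization uses training-study statistics; strong
  platform-specific mean-variance structure beyond what z-scoring removes
  would require dedicated batch correction, which is out of scope.
- The generator's planted-path guarantee relies on disjoint interior nodes
  for planted paths; real interactomes offer no such guarantee, and on them
  the method reports whatever minimum-cost admissible paths exist.
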