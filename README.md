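# laborsig

Integrative analysis of myometrial transcriptome studies around the onset of
human labor. The uterine smooth muscle (myometrium) switches from a quiescent
to a contractile state at term; multiple expression studies of non-labor (NL)
vs in-labor (IL) tissue exist, on different platforms and with different
group definitions (including early vs established labor, ILEa / ILEs). This
package implements, as a tested and reusable library, the full integration
pipeline needed to extract a cross-study labor signature and turn it into
phenotype-specific signaling networks:

1. **Cross-platform merging** — per-study gene filtering, `log2(x+1)` for
   count data, z-scoring of genes then samples, concatenation over shared
   genes into a combined matrix *M* (genes × samples).
2. **Differential expression** — per-comparison Welch tests on log2 values
   with Benjamini–Hochberg correction; genes with *q* < 0.05 and fold change
   > 1.5 in **every** comparison, with consistent direction, form the
   high-confidence labor gene set.
3. **Classification** — repeated stratified *k*-fold cross-validation and
   cross-study transfer of L1 ("lasso") / elastic-net logistic regression,
   with nested penalty selection, per-run AUC, per-sample classification
   frequencies, and model-gene aggregation.
4. **Eigen-patterns** — SVD *M* = *U*Σ*V*ᵀ; the first eigen-gene (row of
   *V*ᵀ) separates IL from NL samples, the first eigen-sample (column of
   *U*) ranks genes; the *energy* σ₁²/Σσᵢ² measures a component's share of
   variation, and projecting a new profile onto *U*₁ gives an unsupervised
   phenotype call.
5. **Over-representation** — exact hypergeometric tests of a query gene list
   against GMT gene-set collections, BH-adjusted, universe = measured genes.
6. **Signaling networks** — on a confidence-weighted directed interactome,
   node costs derived from SVD loadings (three schemes: general, non-labor,
   labor), edge cost 1 − confidence, and Dijkstra shortest paths from
   receptor sources to top-loading target genes **constrained so the final
   edge is a transcription-factor → target interaction**; the general
   network retains the cheapest 50% of paths and the union of retained paths
   is the output network.

A first-class synthetic-data module generates multi-study collections with a
planted labor signature (defaults: three studies of 10 / 22 / 39 samples on
count and intensity platforms, 100 up / 30 down planted genes, a three-group
study, mislabeled "ambiguous" samples) plus gene sets and a synthetic
interactome with planted high-confidence paths — so every stage runs and is
testable with no external data.

## Worked example

`examples/` contains one short script per capability. For instance
`python examples/04_svd_patterns.py` prints:

```
first-component energy (global): 5.80%
eigen-gene vs labor-label point-biserial correlation: 0.883
top-25 positive gene loadings: 25/25 are planted labor-up genes
  pathway-restricted energy, labor_program: 42.84%
  pathway-restricted energy, decoy_01: 9.09%
held-out sample calls:
S99-NL1    NL
...
S99-IL5    IL
```

The dominant pattern of the combined 1500 × 71 matrix correlates 0.88 with
the clinical labels, its positive gene loadings are exactly the planted
labor-up genes, restricting the matrix to the coherent labor program
concentrates the energy (42.8% vs 9.1% for a random decoy set), and all ten
held-out samples are called correctly by projection. Similarly,
`python examples/06_signaling_networks.py` prints:

```
general  : 66 nodes, 90 edges, 75 paths retained, 75 discarded
non_labor: 52 nodes, 79 edges, 75 paths retained, 0 discarded
labor    : 53 nodes, 86 edges, 75 paths retained, 0 discarded
planted paths recovered verbatim: 10/10
cheapest path: REC3 -> SIG10 -> TF09 -> G00932 (cost 3.149)
```

i.e. the three cost schemes give three networks, and every planted
high-confidence path is reconstructed exactly.

The end-to-end driver writes every artifact plus a reproducible run report:

```sh
laborsig all --seed 1 --out my_run          # or: python -m laborsig.cli ...
laborsig simulate --seed 1 --out fixtures   # just the synthetic files
laborsig netbuild --edges E.tsv --tf-edges T.tsv --loadings L.tsv \
    --sources REC1,REC2,REC3 --scheme labor --n-sinks 25 --out net_out
```

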