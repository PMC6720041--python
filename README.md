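# annobench

Benchmarking harness for automated cell-type annotation of scRNA-seq cell
clusters.

## The problem

After clustering, a single-cell RNA-seq analysis still has to answer "what
cell type is each cluster?".  Many tools can score how well a cluster's
expression matches known cell-type signatures, but they come from different
traditions — gene-set enrichment, bulk deconvolution, replicability analysis
— and comparing them fairly requires a common input contract and a common
evaluation.  `annobench` implements that framework: every method consumes a
cluster-average expression matrix **Ě<sub>xy</sub>** (mean raw counts of gene
*x* over all cells in cluster *y*) plus cell-type signatures, and emits a
cell-types × clusters matrix of prediction scores, which a shared harness
turns into ROC/PR curves, percent-correct tables and robustness profiles.

## Methods implemented

Signatures come in two forms — **gene sets** (named marker-gene lists, GMT)
and **continuous profiles** (genes × cell-types expression matrices such as
LM22, 547 genes × 22 leukocyte types); a profile can be thresholded to its
top 5% of genes per column to produce a binary matrix or gene sets.

| method | input | score |
|---|---|---|
| `ora` | gene sets | −log₁₀ one-sided Fisher exact p of marker overlap with the cluster's top-expressed genes, universe = signature ∩ matrix genes |
| `gsea` | gene sets | −log₁₀ gene-permutation p of the weighted KS running-sum enrichment score on the cluster-ranked gene list |
| `gsva` | gene sets | GSVA-style enrichment score (kernel CDF → symmetric rank statistic → weighted random walk), used directly |
| `cibersort_binary` / `cibersort_continuous` | 0/1 matrix / profile | cell-type fraction from linear ν-SVR deconvolution of the cluster profile (ν ∈ {0.25, 0.5, 0.75}, lowest-RMSE fit) |
| `metaneighbor_binary` / `metaneighbor_continuous` | 0/1 matrix / profile | directional neighbor-voting AUROC through a rank-normalised Spearman network (signatures train, clusters test, no train/test averaging) |

Evaluation concatenates all (cell type, cluster) scores into one vector,
marks an entry positive iff the gold standard assigns that type to that
cluster, and sweeps a threshold to obtain ROC AUC and PR AUC; per-cluster
percent-correct and the rank of the gold type per cluster (stratified by
signature size) are also reported.  The robustness module degrades
signatures — random gene removal for sets (10–99%), minimum-value masking of
each type's top genes for profiles (10–100%) — and re-runs scoring and
evaluation over many replicates to produce violin-ready AUC distributions.

A synthetic-data module generates planted-marker fixtures (negative-binomial
counts, gene-specific baselines, multiplicative marker effects, dropout)
together with matched signatures and gold standards, so the whole pipeline
runs with no external data.

## Worked example

```bash
cat > syn.yaml <<EOF
n_genes: 500
n_types: 4
markers_per_type: 12
cells_per_cluster: 30
seed: 3
EOF
annobench synth --config syn.yaml --out fix
annobench profiles --cells fix/cells.tsv --clusters fix/clusters.tsv --out exy.tsv
annobench score --method gsva --exy exy.tsv --gmt fix/signatures.gmt --out scores.tsv
annobench evaluate --scores scores.tsv --gold fix/gold.tsv --gmt fix/signatures.gmt --out metrics
```

prints

```
ROC AUC 1.0000  PR AUC 1.0000  correct 100.0%
```

and `scores.tsv` holds the cell-types × clusters enrichment scores, e.g.
`type_01` scores 0.994 for its own `cluster_01` and negative values
(−0.23, −0.42, −0.20) for the other clusters — on this strong-signal fixture
(12 markers per type, 8-fold elevation) GSVA separates every cluster's true
type perfectly, so the concatenated 16-pair score vector yields ROC AUC and
PR AUC of 1.0 and all 4 clusters are labelled correctly.  The `run`
subcommand chains all stages (including robustness) from one YAML config and
writes per-method score matrices, AUC summaries and a reproducibility
manifest; the same functionality is available as a library
(`import annobench`).

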