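# Methods

This note records the statistical procedures `annobench` implements, the
choices made where the underlying methods leave room, and what the synthetic
fixtures do and do not demonstrate.

## Input contract

All scoring operates on the cluster-average matrix Ě<sub>xy</sub>: the
arithmetic mean of **raw** counts of gene *x* over the cells of cluster *y*.
No log transform, library-size scaling or normalisation is applied — cluster
averaging is deliberately the only upstream step, so that every method sees
exactly the same input.  Gene identifiers match by exact, case-sensitive
string comparison; an explicit `uppercase_genes` helper exists for
cross-species symbol reconciliation and is never applied implicitly.

Cell-type signatures are interchangeable representations of marker
knowledge.  Binarisation keeps the top ⌈0.05·G⌉ genes per type column
(ceiling, so a positive fraction never yields an empty set); ties at the
cutoff break by descending value then ascending gene id, making every
thresholding operation deterministic.  The same rule builds the
"expressed genes" lists for over-representation analysis from
Ě<sub>xy</sub>; the expression cutoff for that step is genuinely arbitrary
in practice, and the default mirrors the 5% signature rule for symmetry
(configurable via `OraParams.fraction`).

## Scoring methods

**ORA.** For each (type *m*, cluster *y*): a one-sided Fisher exact test of
the 2×2 table (overlap / cluster-only / set-only / neither) over the
universe = (union of signature genes) ∩ (matrix genes).  Restricting the
universe to signature genes is a deliberate, conservative choice: genes the
signature never mentions carry no evidence either way.  The score is
−log₁₀ p.  Exact-test p-values are strictly positive, so the transform's
floor (10⁻³⁰⁰) is purely a numerical guard.

**GSEA preranked.** Genes are ranked per cluster by descending average
expression (the only cluster-intrinsic ranking available from
Ě<sub>xy</sub> alone; a z-score-versus-other-clusters metric is available
behind `GseaParams.ranking="zscore"`).  The running sum adds
|w|^p/Σ_hits|w|^p at member genes and subtracts 1/(N−N_hits) elsewhere;
p = 1 (weighted) by default, p = 0 gives classic scoring.  Significance is
one-sided for positive enrichment by gene-label permutation with the add-one
estimator p = (1 + #{ES* ≥ ES})/(nperm+1), so the −log₁₀ score is capped at
log₁₀(nperm+1) and always finite.  nperm defaults to 1000; the test-suite
and acceptance runs use 50–200 to keep simulation sizes desk-scale.
Permutations are vectorised (hit positions resampled per replicate) and
seeded; an all-zero hit-weight vector degrades gracefully to uniform hit
mass.

**GSVA-style scoring.** Stage 1 estimates, per gene, a cross-cluster kernel
CDF: Gaussian kernel with bandwidth sd/4 by default (a Poisson kernel with
rate = value + 0.5 is available for count-like inputs; which kernel suits
averaged counts best is an open judgement — the Gaussian default matches
the common invocation with no arguments).  Constant genes get z = 0.5.
Stage 2 ranks genes per cluster by decreasing z and forms the symmetric rank
statistic r = |G/2 − rank|.  Stage 3 walks the ordering with hit mass
∝ r^τ (τ = 1) and miss step 1/(G−|set|).  Stage 4 reports, by default, the
largest positive deviation plus the largest negative deviation ("difference"
mode; a max-magnitude mode exists).  Scores lie in [−1, 1] and are used
directly — no permutation p-value.  At least 3 clusters are required;
cross-column CDF estimation is meaningless below that.

**ν-SVR deconvolution.** Each cluster profile is treated as a mixture and
regressed on the signature columns with linear ν-SVR (C = 1) over
ν ∈ {0.25, 0.5, 0.75}; the lowest-RMSE fit wins; negative coefficients are
clipped and the rest normalised to a fraction vector.  The mixture is
z-scored and the signature matrix standardised **globally** (one mean and sd
for the whole matrix): per-column centring provably distorts mixing
proportions, while a global affine transform preserves them up to the
intercept.  One identifiability caveat is worth knowing: if the signature
columns partition the gene space (disjoint marker sets covering every row),
the columns sum to the intercept direction and the fraction vector is only
identifiable up to an additive shift — rankings survive, absolute fractions
do not.  Signatures with genes outside every marker set (true of LM22-like
profiles) do not have this problem.  Quantile normalisation and
absolute-mode scoring are out of scope.

**Directional neighbor voting.** Cluster and signature columns are
concatenated over shared genes; Spearman correlations of all column pairs
are rank-normalised over the whole flattened matrix (diagonal included) into
(0, 1].  Signatures are the training study and clusters the testing study,
with the usual train/test symmetrisation removed so votes flow one way.
With a single training column per type, the vote each column casts is
normalised by that column's own degree over the clusters — each signature
distributes one unit of vote mass.  (Normalising instead by the *receiving
cluster's* degree, the convention natural when training labels span many
columns, lets background rank-noise in the compressed network swamp
single-column votes; with one column per type the vote-mass convention is
the faithful adaptation, and the brute-force toy oracle in the test suite
pins it.)  The score of cluster *y* for type *t* is the one-sided AUROC of
*y*'s vote among all clusters' votes: with one positive this is
(rank−1)/(n−1) with average ranks on ties, so each type's row has mean 0.5
in the tie-free case.

A cell type whose signature shares no genes with the matrix cannot be
scored; such entries are explicit missing values (NaN), excluded pairwise
from evaluation with a logged count, never imputed as zero.

## Evaluation

All (type, cluster) scores are concatenated into one vector; truth = 1 iff
the gold standard maps that cluster to that type; clusters without gold
labels are dropped with a logged count.  ROC uses grouped thresholds and
trapezoidal AUC, which equals the Mann-Whitney statistic with half credit
for ties.  PR AUC uses step-wise average precision — exactly reproducible by
enumeration, at the cost of small differences versus tools that interpolate
PR curves nonlinearly.  Percent-correct counts a cluster as right only when
the gold type is the **unique** score maximum (ties are mispredictions — the
conservative reading when a single label must be assigned).  Gold-rank
tables report the average-tie rank of the gold type per cluster, binned by
the gold signature's gene count (default bins 1–2, 3–5, 6–10, 11–20, 21–50,
>50).  An optional cell-type restriction implements "expected types only"
benchmark variants; by default it filters evaluation, with a config switch
to also restrict scoring inputs.

## Robustness simulations

Gene sets are degraded by removing a removal fraction of genes; a set of
size n keeps max(1, round((1−removal)·n)) genes, rounding half away from
zero (only the 1-gene floor is forced; the rounding rule is this package's
choice).  The removal grid runs 0.10–0.90 in steps of 0.10 with a final
0.99 point — the grid endpoint below 1.0 is capped so every set retains a
gene.  Profiles are degraded by masking a random ⌈fraction·k⌉ of each
column's top-5% genes with the column minimum, leaving dimensions untouched.
Binary-matrix methods receive subsampled gene sets re-organised as 0/1
matrices (profiles are not re-binarised after masking — masking already
removes the marker signal the binarisation would find).  The default
replicate count is 1000; tests and the acceptance script run 100 (25 for
the permutation- and SVR-based scorers, with a 3-point grid and reduced
nperm), sizes chosen so the whole simulation remains a desk-scale
computation.  Every grid cell derives an independent seeded substream, so
results are bit-reproducible and independent of execution order.

## Synthetic fixtures

The generator plants one cluster per cell type: per-gene baseline means are
lognormal (σ = 0.25) around the background mean (real transcriptomes never
express all genes at one level, and without baseline variation top-gene
selection and profile masking degenerate); markers are multiplied by the
effect size (default 8) in their own cluster; counts are negative-binomial
(variance = μ + 0.5μ²) with independent dropout (default 0.1).  Default
dimensions are 2,000 genes, 8 types, 25 markers per type, 50 cells per
cluster — large enough that all five method families behave non-trivially,
small enough to score in seconds.  The profile signature is the noiseless
expected-mean matrix, mirroring how reference profiles are averages of
purified measurements.

What passing on these fixtures shows: the pipeline is wired correctly, each
scorer recovers planted structure at strong signal, and performance decays
monotonically as signatures are degraded.  What it does not show: behaviour
under batch effects, doublets, library-size variation, imbalanced cluster
sizes, clusters without a matching signature, or signatures curated with
real-world noise — conclusions about real datasets require real data.

## Known limitations

- GSEA here implements preranked scoring with gene-label permutations only;
  NES normalisation and FDR machinery are out of scope.
- GSVA's Gaussian kernel on averaged counts inherits the usual caveat that
  averaged counts are not Gaussian; the Poisson kernel option exists but
  neither choice is validated against real data here.
- The evaluation treats each (type, cluster) pair independently; confusion
  structure between similar types is not analysed.
- Percent-correct with tied maxima, and the exact expression cutoff for
  ORA's expressed-gene lists, are conventions; both are parameterised and
  documented rather than claimed canonical.
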