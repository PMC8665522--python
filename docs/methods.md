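# Methods

## Scope and data model

`cernapivot` reconstructs lncRNA–mRNA ceRNA (competing endogenous RNA)
networks from gene-level expression matrices of small paired case–control
bulk RNA-seq designs. The in-memory container is an `ExpressionMatrix`:
a genes × samples value matrix with a unit tag (`counts`, `fpkm`,
`log2fpkm`), per-gene transcript length (bp) and biotype (mRNA/lncRNA),
and a sample sheet (condition tumor/control, optional pair id). Alignment,
assembly and quantification are out of scope: the pipeline starts from a
count matrix, and miRNA targeting comes from a file-based interaction
table rather than a live database query.

## Normalization

FPKM is computed as `counts · 10⁹ / (library_size · length)` with the
library size taken as the column sum of the supplied count matrix — the
standard surrogate when per-sample mapped-fragment totals are unavailable.
This preserves the identity `Σ_g fpkm[g,s] · length[g] = 10⁹` per sample,
which the tests assert. All downstream statistics operate on
`log2(fpkm + 1)`; the pseudocount of 1 keeps zeros at zero and bounds fold
changes for unexpressed genes. An optional low-expression filter
(default fpkm ≥ 0.5 in ≥ 2 samples) is provided but off by default.

## Differential expression

Genes are screened with Welch's two-sample t-test on `log2(fpkm + 1)`,
with the fold change defined on FPKM group means as
`log2((mean_tumor + 1)/(mean_control + 1))`. A gene is called DE when
**p < 0.05 and |log2FC| > 1**, both strict; BH-adjusted p-values are
reported but do not enter the default call (screening studies of this
design typically gate on raw p). Welch's test is a deliberate stand-in for
count-model DE machinery: it is deterministic, dependency-free and — as
the null simulations verify — calibrated at n = 6 + 6 on this data shape.
Degenerate genes with zero variance in both groups get p = 1 when group
means agree and p = 0 (flagged) when they differ, so constant genes never
produce NaNs. The default analysis treats the groups as independent even
for paired designs, matching the unpaired tests these pipelines
historically used; the generator can add a per-pair offset
(`pair_sd` > 0), but then an unpaired test becomes conservative, so the
offset defaults to 0.

## Separability evaluation

The DE mRNA panel is assessed unsupervised on z-scored `log2(fpkm + 1)`
features: PCA via SVD of the centered sample matrix, K-means (k = 2,
10 k-means++ restarts, fixed seed), and a two-component Gaussian mixture
with a **single diagonal covariance shared by both components**, fit by EM
(tolerance 1e-6, ≤ 500 iterations, initialized from the K-means labels,
variance floored at 1e-9). The shared-diagonal structure is intentionally
rigid: with ~12 samples and hundreds of genes, per-component or full
covariances are unidentifiable. The EM log-likelihood trace is recorded
and is non-decreasing, which tests assert per run. Cluster labels are
aligned to conditions by majority before concordance is computed
(∈ [0.5, 1] for two balanced groups); "high posterior" defaults to 0.8
and is configurable.

## Enrichment

Over-representation uses the one-sided hypergeometric (Fisher upper-tail)
test, `p = P(X ≥ k)` for X ~ Hypergeometric(N, K, n), with BH adjustment
across the collection. The universe defaults to the genes actually tested
for DE — restricting to detectable genes guards against detection bias.
Each term carries the enrichment score `−log10 p` and the trend z-score
`(up − down)/√(up + down)` over its DE members, the standard summary of
whether a term's signal is up- or downregulated. Gene sets are read and
written as GMT. GO-DAG propagation and ranked (GSEA-style) tests are out
of scope.

## Network construction

For every (DE lncRNA, DE mRNA) pair, Pearson's r is computed on
`log2(fpkm + 1)` across **all** samples pooled (maximizing n in a 12-sample
study; the case–control contrast is part of the biological signal such
networks are built on). Two-sided p-values use the exact t-transform
`t = r√(n−2)/√(1−r²)` with n−2 df. Edges are kept at **p < 0.05 and
r ≥ 0.6** (inclusive boundary; `sign_mode="absolute"` admits negative
correlations, but the default is positive-only since ceRNA coupling
predicts positive correlation). Correlation on the log scale rather than
raw FPKM is a variance-stabilization choice. Surviving pairs must share at
least `min_shared = 1` targeting miRNAs in the interaction table
(annotation-only behavior is available by setting `min_shared = 0`);
shared miRNAs are recorded on the edge and expanded into miRNA nodes with
targeting edges to both partners, yielding an undirected simple
mRNA–lncRNA–miRNA graph. Correlation p-values are not
multiplicity-adjusted by default, matching the raw-p convention of the
filter; a BH option exists at the API level via the `de` utilities.

## Topology and pivotal nodes

Centralities are exact (non-sampled): degree; betweenness with the
undirected unordered-pair convention, endpoints excluded, unnormalized by
default; closeness in the Wasserman–Faust component-scaled form
`((reachable−1)/(n−1)) · (reachable−1)/Σdist`, which keeps values
comparable across components of a disconnected graph (isolated nodes score
0). The test suite checks all three against an independent brute-force
BFS path-counting oracle on hundreds of random graphs. TOP-k sets are
**tie-inclusive**: every node tying the k-th largest value is kept, so the
result is deterministic rather than exactly k-sized. Pivotal nodes are the
triple intersection of the TOP-k sets of the three metrics, reported with
all seven Venn region counts and partitioned by node type. k defaults to
100 (the convention for patient-scale networks); desk-scale synthetic runs
use k = 10, in proportion to their ~40-node networks. Ranks are computed
on the expanded mRNA–lncRNA–miRNA graph.

## qPCR quantification

The 2^−ΔΔCt method with amplification efficiency fixed at 2: replicate Ct
values are averaged arithmetically, ΔCt = Ct(target) − Ct(reference), and
the calibrator is the **mean ΔCt of the control group per target**, which
makes the calibrator group's mean ΔΔCt exactly 0 (geometric-mean fold 1)
and matches case–control bar-plot conventions. Group comparison is a
two-sided Student's t-test on per-sample ΔCt — identical (up to sign) to a
t-test on log2(fold), the scale on which folds are additive. No outlier
rejection, efficiency correction or multi-reference normalization.

## Synthetic-data generator

The generator emulates the study design the pipeline targets and returns
planted ground truth for scoring. Defaults (one value per parameter,
chosen once as a realistic bulk RNA-seq shape):

| parameter | default | meaning |
|---|---|---|
| `n_pairs` | 6 | tumor/normal pairs (12 samples) |
| `n_mrna`, `n_lncrna`, `n_mirna` | 400 / 80 / 150 | feature counts (desk scale) |
| `nb_mean_log_mu`, `nb_mean_log_sd` | 4.0, 1.5 | log-normal baseline NB means (natural log) |
| `nb_dispersion` | 0.2 | φ in var = μ + φμ² (0 → Poisson) |
| `de_fraction`, `de_log2fc` | 0.1, 3.0 | planted DE share and effect |
| `module_size`, `module_rho` | 8, 0.8 | hub-driven mRNA module and target correlation |
| `shared_mirna_count` | 3 | miRNAs shared by hub and each module member |
| `geneset_count`, `geneset_size` | 50, 20 | gene-set collection shape |
| `pair_sd` | 0.0 | per-pair baseline offset (log scale) |
| `qpcr_noise_sd` | 0.2 | replicate Ct noise (cycles) |

Counts are negative-binomial with log-normal baseline means; planted DE
genes have tumor means scaled by `2^±de_log2fc` (the hub/module block
shares one downregulated direction). Gene lengths are uniform on
[200, 10000] bp, independent of expression. Co-expression is induced by a
per-sample latent log-scale factor shared by the hub and module, with
loading τ set from `module_rho` via `τ² /(τ² + v) ≈ ρ` (v an NB log-noise
proxy); the control is monotone in ρ, not exact. Two design choices
matter:

* **The latent factor is centered within each group.** An uncentered
  factor's random tumor/control imbalance perturbs the planted group
  contrast by ~0.8 log2 units at n = 6, enough to mask the planted DE of
  the very genes it decorates. Centering makes planted correlation and
  planted DE orthogonal, independently controllable truths.
* **The planted block draws baseline means from the upper expression
  range** (log-mean μ+σ, sd σ/2). A hub whose counts sit at the NB noise
  floor cannot exhibit r ≥ 0.6 across a dozen samples no matter how it is
  wired; ground truth is only useful when it is detectable in principle,
  and real validated hubs are well-expressed (low-expression candidates
  are routinely dropped from qPCR validation).

The interaction table guarantees ≥ `shared_mirna_count` miRNAs targeting
both the hub and each module member, plus uniform background targeting
(4 targets per miRNA). One gene set draws ≥ 80% of its members from
planted DE mRNAs; the rest are background. The qPCR plate encodes
`ΔCt_tumor − ΔCt_control = −log2FC` with Gaussian replicate noise. All
outputs are pure functions of (config, seed); `de_fraction = 0` is a true
null with no group differences anywhere.

What the generator does **not** emulate: read-level noise and mapping
artifacts, isoform structure, GC/length-expression coupling, batch
effects, correlated background co-expression beyond the planted module,
miRNA expression (miRNAs exist only as predicted interactions), and
heavy-tailed outlier samples. Passing tests therefore demonstrate
calibration and recovery under the assumed NB/log-normal world, not
robustness to every artifact of real libraries.

## Numerical and problem-size choices

Exact collinearity (|r| = 1) maps to p = 0; constant genes yield r = NaN
and are excluded from filtering. Hierarchical clustering of DE genes uses
Euclidean distance with average linkage on per-gene z-scores (a
deterministic, robustness-oriented choice), reporting the 2-cluster cut.
The pipeline fans one global seed into per-stage seeds through
`numpy.random.SeedSequence`, so reports are byte-identical across reruns.
Simulation-based checks use 20 seeds at 2000 genes (null calibration) and
20 seeds at the 480-gene default (recovery); these sizes give stable
rates while keeping the whole suite fast on a laptop. Recovery of the
planted hub is evaluated at k = 10, matching TOP-k calling to the ~40-node
synthetic networks.

## Known limitations

Welch-on-log-FPKM is a screening test, not a count model: at very low
expression its calibration relies on the pseudocount, and it shrinks
power relative to NB-likelihood methods. Pooled-sample correlation mixes
within-group co-regulation with the case–control contrast; networks built
this way over-connect strongly DE genes, which is inherent to the design
being modeled. The hypergeometric test ignores gene–gene correlation in
gene sets. Centralities are exact but O(V·E); the implementation targets
the hundreds-of-nodes networks this analysis produces, not genome-scale
graphs.
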