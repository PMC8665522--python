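# cernapivot

Inference of lncRNA–mRNA competing-endogenous-RNA (ceRNA) networks from
small paired case–control bulk RNA-seq studies, with centrality-based
pivotal-node calling and qPCR validation math.

## The problem

Rare-tumor transcriptome studies often have only a handful of matched
tumor/normal pairs and no miRNA sequencing. A common analysis strategy is:

1. normalize counts to FPKM and screen genes at **p < 0.05 and
   |log2FC| > 1** (Welch's t-test on log2(FPKM+1) here);
2. check that the differentially expressed (DE) panel actually separates
   the groups (PCA, K-means, Gaussian mixture posteriors);
3. test gene sets for over-representation of DE mRNAs with the one-sided
   hypergeometric test, annotating each term with a trend z-score
   `z = (up − down)/√(up + down)`;
4. link DE lncRNAs to DE mRNAs by Pearson co-expression (**p < 0.05 and
   r ≥ 0.6** across all samples), keeping only pairs that *share predicted
   targeting miRNAs* — the ceRNA "sponge" signature, which predicts
   positive lncRNA–mRNA correlation;
5. expand shared miRNAs into an mRNA–lncRNA–miRNA graph and call
   **pivotal nodes**: the intersection of the tie-aware TOP-k sets of
   degree, betweenness and closeness centrality;
6. validate candidates by qPCR with the 2^−ΔΔCt method
   (`fold = 2^−(ΔCt − ΔCt_calibrator)`, triplicate wells averaged,
   Student's t-test on ΔCt).

`cernapivot` implements the full chain as a tested library plus CLI.
Because such studies rarely deposit raw data, the package ships a
first-class synthetic-data generator with planted ground truth — a
negative-binomial count matrix (6 tumor vs 6 matched normal samples by
default), a planted DE fraction, a hub lncRNA driving a correlated mRNA
module, a matched miRNA-target table, a planted enriched gene set, and a
simulated qPCR plate — so every stage can be scored for calibration and
recovery.

## Worked example

```python
import cernapivot as cp

config = cp.PipelineConfig.from_dict(
    {"outdir": "demo", "seed": 3, "topology": {"k": 10}})
report = cp.run_pipeline(config)
```

```
[cernapivot:simulate] 480 genes x 12 samples -> demo
[cernapivot:normalize] 480 genes after normalization
[cernapivot:de] 50 DE genes (43 mRNA, 7 lncRNA)
[cernapivot:evaluate] concordance=1.000
[cernapivot:enrich] 43 terms tested, 1 significant
[cernapivot:network] 15 supported edges, 42 nodes
[cernapivot:topology] 10 pivotal nodes at k=10
[cernapivot:qpcr] 3 targets quantified
```

Of 480 simulated genes, 50 pass the DE screen (43 mRNAs, 7 lncRNAs; 48
were planted). The DE panel separates tumor from control perfectly
(K-means concordance 1.0, every GMM posterior ≈ 1). Of 301 candidate
lncRNA–mRNA pairs, 150 pass the correlation filter and 15 survive the
shared-miRNA requirement, giving a 42-node network (3 lncRNA, 14 mRNA,
25 miRNA). At k = 10 the three centrality TOP-k sets intersect in 10
pivotal nodes — including the planted hub `LNC00040` (1 lncRNA, 8 mRNAs,
1 miRNA, mirroring the lncRNA-hub architecture such networks show). The
simulated qPCR plate confirms the hub's downregulation
(fold ratio 0.14, p ≈ 7.5e-10; the planted log2FC was −3). Everything is
written to `demo/`: FPKM and DE tables, enrichment TSV, a Cytoscape-ready
SIF/edge list, centralities, a pivotal-set JSON and the run report.

The same stages are available as subcommands:

```bash
cerna-pivot simulate --seed 5 --outdir sim
cerna-pivot normalize --in sim/counts.tsv --out sim/fpkm.tsv
cerna-pivot de --in sim/fpkm.tsv --out sim/de.tsv
cerna-pivot network --in sim/fpkm.tsv --de-table sim/de.tsv \
    --interactions sim/interactions.tsv --outdir sim/net
cerna-pivot topology --edges sim/net/network_edgelist.tsv \
    --nodes sim/net/network_nodes.tsv --outdir sim/topo --k 10
cerna-pivot qpcr --wells sim/qpcr_wells.tsv --out sim/rel.tsv \
    --reference-gene REF
cerna-pivot run --config pipeline.yaml --seed 3
```

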