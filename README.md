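# chipnet

Integrative transcription-factor (TF) regulatory-network analysis from
ChIP-seq peak sets and TF-knockout RNA-seq differential expression —
the computational workflow used to dissect how AP-1 family TFs (JunB,
BATF, Fosl2, ...) coordinate CD4⁺ T-helper-cell programs, packaged as a
tested, reusable Python library.

It is aimed at computational biologists who have, for each TF of
interest, (a) called ChIP-seq peaks (MACS2-style narrowPeak), (b) a
knockout-vs-wild-type differential-expression table (edgeR-style:
gene, log2FC, p, FDR), and (c) a gene annotation (BED6 or minimal
GTF) — and who want direct/indirect activation/repression networks,
cis-regulatory co-occupancy maps and signature enrichment, with every
rule testable against synthetic ground truth.

## What it computes

**Peak-gene association.** A peak is associated with a gene when its
summit falls within W = 5,000 bp up- or downstream of the gene body
(inclusive; coordinates are BED-style 0-based half-open).

**Network inference.** For each TF-knockout contrast, every gene with
FDR < 0.05 becomes an edge TF → gene, classified

* DIRECT if ≥ 1 peak summit of that TF lies within W of the gene body
  (a configurable manual-DIRECT list covers validated targets whose
  peaks fall outside the window), else INDIRECT;
* ACT if expression decreased in the knockout (log2FC < 0, KO-vs-WT
  orientation), REP if it increased.

Network-level summaries follow: sign-concordance quadrants of two
knockout contrasts over co-significant genes, the four cooperative
modes (ACT:ACT ... REP:REP) of a TF pair's common targets, net-effect
distributions of those groups in a subset contrast, and node
annotation for Cytoscape-ready TSV export.

**pCRMs.** Peaks pooled across the TF panel are transitively merged
(≥ 1 shared base) into putative cis-regulatory modules; k-means on the
binary occupancy matrix bins them into 8 clusters for heatmap display.
Differential-binding regions are classified co-bound (≥ 1 base overlap
with a reference TF's peaks) and summarized per volcano quadrant
(fold change ≥ 2, p < 0.01).

**Enrichment.** Signatures are the top-100 up/down genes of a subset
contrast by raw p-value; genes are ranked by s_g = −log10(p_g) ·
sign(log2FC_g); enrichment uses the weighted Kolmogorov–Smirnov
running-sum statistic (increment |s_i|^w / Σ_hits|s|^w at a hit,
decrement 1/(N − N_hits) at a miss; ES = the maximum-magnitude signed
deviation) with a 10,000-draw gene-set permutation null and plus-one
corrected p-values. Benjamini–Hochberg adjustment is provided as a
shared utility.

**Synthetic data.** A generator plants a TF → gene network with known
directness and modes, emits peaks, knockout and subset DE tables in
the exact formats the pipeline reads, and scores any inferred network
against the planted truth (precision/recall/F1, mode and directness
accuracy). A small fixture (200 genes, 3 TFs, seed 42) ships with the
package.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/03_build_network.py` on the bundled dataset prints:

```
Batf   DIRECT    ACT: 8 edges
...
Junb   INDIRECT  REP: 4 edges
edge precision 0.951  recall 0.967  mode acc 1.000  directness acc 1.000
co-regulation ACT:ACT: n=3, median log2FC +2.18
co-regulation ACT:REP: n=3, median log2FC -1.23
co-regulation REP:ACT: n=1, median log2FC -1.29
co-regulation REP:REP: n=1, median log2FC -3.05
```

Read: the edge counts break the inferred network down per TF,
directness and mode; precision/recall score it against the planted
truth (BH controls a false-discovery *rate*, so a handful of null
genes slip in and the weakest targets drop out — hence slightly below
1); mode and directness labels of recovered edges are perfect. The
co-regulation block shows that targets activated by both TFs sit high
in the subset contrast while co-repressed targets sit low — the
coherent-regulation readout the analysis is designed to expose.

The same steps are scriptable from a shell:

```bash
chipnet simulate --out data/ --seed 42
chipnet all --config config.yaml --set alpha=0.05 --set gsea_nperm=10000
```

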