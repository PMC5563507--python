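# Methods

This note documents the models and procedures chipnet implements, the
parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Coordinates and peak-gene association

All genomic coordinates are 0-based half-open (BED convention); a peak
summit is a single absolute base position inside its interval.
Chromosome names are opaque strings — no `chr`-prefix normalization is
attempted, and a mapper call whose peaks and genes share no chromosome
name fails loudly, since a silent namespace mismatch would otherwise
produce an empty but plausible-looking network.

A peak associates with a gene when the summit-to-body distance is at
most W (default 5,000 bp). Distance is 0 inside the body; for a summit
at or past the half-open end it is `summit − end + 1`, so the first
base past the body is 1 away and the window is symmetric in actual
bases on both sides. The threshold is inclusive at exactly W — the
common annotation-tool convention; the choice is isolated in one
comparison and pinned by boundary tests. Association is by summit for
every purpose, including DIRECT-target classification, so the package
has a single distance definition. Strand is carried on gene models but
ignored by window arithmetic (the window is symmetric). A peak may
associate with several genes and vice versa; no nearest-gene collapse
is applied because the rule contains no uniqueness clause.

The production mapper uses per-chromosome sorted-summit binary search;
its contract is exact equality with the all-pairs brute-force scan,
enforced on random instances in the tests.

## Network model

For each TF-knockout contrast, each gene with FDR < α (α = 0.05,
strict inequality) becomes one edge TF → gene:

* directness: DIRECT iff ≥ 1 associated peak of that TF, or the
  (TF, gene) pair is on the manual-DIRECT list. Manual status affects
  directness only — manual targets still require DE significance. The
  default manual list covers the experimentally validated Junb targets
  Ifng, Irf8 and Tbx21, whose peaks fall outside the 5-kb window.
* mode: ACT iff log2FC < 0 in KO-vs-WT orientation (the gene needs the
  TF to stay up), REP iff log2FC > 0. Tables supplied in the opposite
  orientation are flipped by a config flag, because the rule is
  orientation-dependent and input conventions vary. A significant gene
  with log2FC exactly 0 has no defined mode and is excluded with a
  warning rather than arbitrarily assigned.

One edge per (TF, gene) regardless of peak count; the count is kept in
`n_peaks`. Quadrant concordance between two knockout contrasts is
computed over genes significant in **both** tables (the denominator
the figure-legend convention supports), zero-log2FC genes excluded, so
the four quadrant fractions always sum to 1. Pair-mode groups contain
only genes with edges from both TFs. Net-effect summaries report
median and quartiles (linear-interpolation quantiles) of subset-
contrast log2FCs per group, with empty groups flagged rather than
dropped. All summaries are recomputable from the exported edge table
alone — there is no hidden state.

## pCRMs and occupancy clustering

Modules are the transitive ≥ 1-base merge of peaks pooled across the
TF panel; adjacency in half-open coordinates does not merge. Every
input peak lands in exactly one module, a conservation property the
tests enforce.

The original study's binning tool is not reused; clustering is k-means
(k = 8 default, 10 restarts, best inertia) on the binary occupancy
matrix — the simplest faithful reading of "binned into 8 clusters".
Cluster membership is therefore a visualization aid, validated only
against synthetic benchmarks, not expected to replicate any published
figure row-for-row. To make results independent of caller-supplied row
order, modules are clustered in canonical coordinate order and labels
mapped back; clusters are renamed in decreasing size order with
centroid-pattern tie-breaks. If fewer distinct occupancy patterns than
k exist, k is reduced with a warning. A signal mode (max peak score
per TF) is available for heatmap shading but never affects clustering
unless explicitly enabled.

Differential-binding statistics are consumed, not computed: DiffBind/
edgeR-style region tables are inputs, and the FDR < 0.05 differential-
event rule is a filter flag. The per-subtype volcano summary counts
regions with fold change ≥ 2 and p < 0.01 per signed quadrant
(log2FC ≥ +1 for gains, ≤ −1 for losses), each over its subtype's
total, with p capped at 1e-25 for plotting.

## Enrichment

Signatures take the top n = 100 up- or downregulated genes sorted by
**raw** p (ties: larger |log2FC|, then gene id); no FDR pre-filter is
applied, since the signature definition names only the p-sort. Both
choices are overridable. The rank metric is −log10(p) · sign(log2FC);
p = 0 is capped at magnitude 320 (just below double-precision
underflow of 10^−x) so ordering stays finite and deterministic, and
log2FC = 0 scores 0 regardless of p.

The enrichment statistic is the weighted Kolmogorov–Smirnov running
sum (weight 1 by default; weight 0 recovers the classic KS statistic,
cross-checked against an independent naive implementation). When the
largest positive and negative deviations tie exactly in magnitude the
positive one is reported; the tie is detected with an ulp-level
relative tolerance because accumulation order can perturb an exact
tie by one floating-point step. The null is gene-set (label) permutation —
the only null coherent for pre-ranked input, as sample permutation
would require expression matrices. With nperm draws the p-value is
plus-one corrected over all permutations,
`p = (1 + #{same-sign |ES′| ≥ |ES|}) / (1 + nperm)`, so the floor is
1/(nperm + 1): at the default nperm = 10,000 a perfectly concentrated
set reports p ≈ 9.999e-5, i.e. "p < 1e-4", and p is never 0. NES
divides ES by the mean |ES′| of same-signed nulls (the GSEA
convention). Numerical identity with the Java GSEA tool's tie-handling
and NES details is not claimed. Permutation ES values are computed by
a candidate-extremum shortcut (extrema can only occur immediately
before or after a hit), tested for exact agreement with the full
running sum.

BH adjustment delegates to statsmodels' step-up implementation behind
the package's own validated surface and is compared against a naive
sort/cummin reference in the tests.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes
of real data, not the data itself:

* gene bodies (length U(1,000, 8,000) bp) are placed left-to-right
  with inter-gene gaps of at least 2 W plus U(500, 4,000) bp, so every
  generated peak maps to at most one gene and recovery metrics stay
  interpretable; overlapping-gene ambiguity is exercised separately by
  handcrafted fixtures;
* planted targets (default 40 per TF in the 200-gene bundled dataset —
  a master-regulator-sized fraction of the universe) are DIRECT with
  probability 0.6 and ACT with probability 0.6; |log2FC| ~
  LogNormal(ln 2, 0.5) (median twofold change);
* true-target p-values follow Beta(a, 1) — one shape parameter
  interpolating from near-certain significance (a → 0) to the null
  (a = 1); non-targets draw p ~ U(0, 1) and log2FC ~ N(0, 0.1); the
  FDR column is the BH adjustment of the p column, row-exact;
* each DIRECT edge gets one peak with summit uniform over the gene's
  ±W window, dropped independently at the dropout rate; decoy peaks
  (20 per TF by default) land in inter-gene gaps farther than W from
  every body, so decoys can never create a DIRECT call;
* subset contrasts plant ACT targets as subset-up and REP targets as
  subset-down at the signature-overlap rate (0.5 by default),
  mirroring the coherent-regulation structure the net-effect and
  preference analyses read out.

All draws derive from one integer seed through independent named
streams; generation, writing, re-reading and re-generation are
byte-identical, and the bundled fixture is asserted byte-equal to a
fresh regeneration in the tests.

What the generator does **not** emulate: read-level signal, peak
shapes, count dispersion, correlated genes, multi-peak regulatory
architecture, or overlapping gene models. Passing recovery tests
therefore demonstrate the correctness of the classification rules and
plumbing under the stated statistical model, not performance on real
sequencing data.

A consequence worth stating explicitly: because significance is
controlled as a false-discovery *rate*, exact precision/recall of 1.0
on a generated dataset is not guaranteed even at a = 0.01 — with a
200-gene universe, BH at α = 0.05 admits occasional uniform-null false
positives (measured precision 0.951 on the bundled dataset) and the
Beta(0.01, 1) tail leaves a few percent of targets above the cut
(measured recall 0.967). Exact recovery holds, and is tested, for
noise-free instances whose target p-values sit far below and null
p-values far above any BH threshold.

## Pipeline and determinism

All stages run from one YAML config with `--set key=value` overrides;
every analysis threshold (α = 0.05, W = 5,000, k = 8, signature
n = 100, nperm = 10,000, the fold-change ≥ 2 / p < 0.01 differential
cut, volcano p-caps 1e-30 for expression and 1e-25 for binding) is a
named key with these defaults. Writers emit sorted rows and
`repr`-formatted floats, so identical inputs give byte-identical
files; the manifest records a SHA-256 per output and reruns reproduce
identical hashes. A stage failure aborts with the stage name and
leaves a manifest marked incomplete.

Problem sizes used by the validation suite and acceptance script —
50 mapping instances up to 500 × 100, 1,000-edge dropout studies,
1,000 co-significant genes for concordance, 4,000 modules for the
clustering benchmark, 2,000-gene null calibration — were chosen as the
smallest scales at which the binomial 99% confidence intervals being
asserted are informative.

## Known limitations

* DE and differential-binding statistics are consumed, never fitted;
  tables must arrive with valid p/FDR columns in one shared gene
  namespace (symbol or id — the package only checks for a non-empty
  intersection with the annotation).
* The 8-cluster occupancy binning is a display convention, not a
  model; cluster labels depend on k and seed (deterministically).
* GSEA here is pre-ranked only; phenotype-permutation GSEA is out of
  scope.
* Functional gene-class curation (cytokine/receptor/TF groupings) is
  accepted as a user-supplied table and passed through; no curation
  logic is implemented.
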