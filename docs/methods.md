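# Methods

`arsig` re-implements, as a reusable and fully tested pipeline, the
computational route from paired cistrome (ChIP-seq peak) and
transcriptome (RNA-seq count) data to condition-unique transcription
factor target-gene signatures, their co-target refinement against an
external knockdown dataset, per-sample signature scores, and
score-stratified survival analysis. The motivating setting is androgen
receptor (AR) reprogramming in castration-resistant prostate cancer —
comparing an AR-low/ligand-high condition against an AR-high/ligand-low
condition — but nothing in the code is specific to AR: any two-condition
peak + count design fits.

## Pipeline model

### Cistrome comparison

Peaks are BED-convention intervals (0-based, half-open) carrying the peak
caller's score, `-10·log10(q)`. Two peak sets are Venn-partitioned
*peak-centrically*: a peak of set A is "common" iff it overlaps (≥ 1 bp,
after extending ends by `max_gap`, default 0) at least one peak of set B,
and symmetrically for B. Because overlaps can be many-to-many, the two
common counts need not be equal; each input's counts always conserve its
size (`unique + common = total`). A merged-region-centric convention
exists in the field; the peak-centric one is used because the
"conserved peaks" phrasing it mirrors counts peaks, not merged regions.

Genomic-distribution calls classify each peak by its *midpoint* with
precedence promoter > exon > intron > distal-intergenic (promoter =
within `promoter_window`, default 3 kb, of a TSS). Top-peak selection
(default n = 5,000, mirroring the upstream motif-analysis convention)
sorts by descending score with (chrom, start, end) tie-breaks so the
selection is deterministic.

### Differential expression

The DE stage is a deliberately self-contained stand-in for a
quasi-likelihood NB pipeline; downstream stages consume only
(log2 fold-change, FDR), so any calibrated test is substitutable:

* size factors: median of count/geometric-mean ratios over genes
  positive in every sample (library-size fallback otherwise);
* dispersion: per-gene method of moments on normalized counts,
  `alpha = (pooled within-group variance − mu·mean(1/s)) / mu²`, shrunk
  50/50 toward the across-gene median and floored at 1e-8;
* test: Wald statistic on the log2 ratio of normalized group means
  (pseudocount 0.5), delta-method SE from the NB variance
  `mu/s + alpha·mu²`, referred to a t distribution with
  `2·(n1+n0−2)` degrees of freedom. The doubled degrees of freedom
  express the information the 50/50 shrinkage borrows across genes
  (limma-style: prior df equal to residual df); with a plain normal
  reference the test is measurably anti-conservative at n = 5/group and
  with `n1+n0−2` df measurably conservative. Under the package's own
  synthetic null (2,000 genes, n = 5/group, dispersion 0.05) the
  realized type-I error at α = 0.05 is within ±0.015 of nominal — this
  is asserted by the test suite, not assumed;
* multiplicity: Benjamini–Hochberg over all tested genes; genes with
  all-zero counts in the contrast are excluded from the family and
  reported separately;
* classification: up = FDR < 0.05 and fold-change > 1.5; down symmetric.
  Both inequalities are strict, so a gene at exactly 1.5-fold is excluded.

### Binding–expression integration

Gene-level regulatory potential sums distance-decayed peak
contributions: `rp(g) = Σ exp(−(0.5 + 4·|d|/window))` over peaks whose
midpoint lies within `window` (default 100 kb) of the TSS, where `d` is
the midpoint-to-TSS distance. At d = 0 a peak contributes exp(−0.5); at
the window edge exp(−4.5); one bp beyond, nothing. The decay constant
and window are the established defaults of the regulatory-potential
literature and are both configurable. A *direct target* is a gene that
passes the DE thresholds (either direction) and has ≥ 1 peak in the
window.

The activation-function test asks whether up- (down-) regulated genes
carry more binding than static genes (tested genes with FDR ≥ 0.5
failing both thresholds — a conservative background): one-tailed
two-sample Kolmogorov–Smirnov on the RP values, exact below 30 genes per
class, asymptotic tail bound otherwise. It depends on RP only through
ranks and refuses classes below 20 genes.

### Enrichment

* Pre-ranked GSEA: weighted running-sum enrichment score (hit steps
  ∝ |metric|^weight, miss steps −1/(N−n)); null from seeded gene-label
  permutations (random same-size sets), NES = ES / mean |same-sign null
  ES|, p from the matching-sign null tail, BH over sets. Sets with < 5
  members in the ranking are reported as NA.
* Over-representation: one-sided Fisher exact on the 2×2 in-query ×
  in-set table over a fixed universe, Haldane-corrected odds ratios, BH
  FDR. The same operator serves pathway collections and
  regulator→target networks (the regulator-enrichment stage).
* Motif comparison: motifs ranked by descending z-score per condition
  (ties by name); `delta_rank = rank_A − rank_B`, so a motif gaining
  enrichment in condition B gets a positive delta and leads the
  waterfall. Deltas sum to zero over a shared universe.

### Signature derivation

The central three-step derivation, per condition pair:

1. keep genes passing fold-change > 1.5 and FDR < 0.05 (either
   direction) that are direct binding targets of that condition's
   cistrome;
2. overlap the two filtered sets; keep the genes unique to each
   condition;
3. keep a unique gene only if its *folded* linear fold-change
   (max(fc, 1/fc)) exceeds the other condition's by a ratio > 1.5.

Step 3's "fold-change difference" is read as a ratio of folded
fold-changes — dimensionless and symmetric for up- and down-regulated
genes; the arithmetic-difference reading is available via
`mode="difference"`. Genes absent from one condition's table count as
neutral there (fc = 1, FDR = 1) so uniqueness is decidable for every
gene. Signatures record their intermediate step-1/step-2 sets as
provenance, and the derived pair is disjoint by construction. Signature
sizes are data outcomes, not contracts.

The co-target signature intersects one condition's up-/down-regulated
direct targets with an externally derived regulated gene set (e.g. genes
responsive to knockdown of a partner regulator), split by direction.

### Scoring and survival

Default per-sample scoring is *combined-z*: each gene is z-scored across
samples (zero-variance genes contribute 0) and the score is the mean z
over signature genes — matching a scorer whose input is expression
"centered and scaled across samples". A rank-based ssGSEA variant
(weighted in-set vs uniform out-set running ECDF difference, weight
0.25) covers the alternative reading. Group score comparisons use the
two-sided Wilcoxon rank-sum test, exact by enumeration when both groups
have n ≤ 10.

Cohorts are stratified at the empirical 75th percentile of the score:
high = top 25 %, computed as the ⌈0.25·n⌉-th largest score with boundary
ties going high (so the high group is never smaller than a quarter).
Kaplan–Meier estimation and the standard unweighted two-group log-rank
test are delegated to lifelines; the test refuses cohorts with no
events. No Cox model is fitted — the deliverable is the KM contrast and
its p-value.

## Synthetic benchmark

The generator plants known structure so that every downstream stage is
testable without any external download:

* **genome**: 2,000 genes uniformly placed (collision-free TSSs) on 5
  chromosomes of 20 Mb;
* **planted DE classes**: 3 % of genes each as A-unique, B-unique and
  common (60 genes per class at defaults), pairwise disjoint; 80 % of
  planted genes shift up and 20 % down, by |log2 fc| = 2, in the
  matching condition group(s) only;
* **peaks**: 300 common + 300 A-unique + 300 B-unique; 60 % of each
  class is placed with its midpoint within 10 kb of a planted gene of
  the matching class (every planted gene covered first, so each is a
  direct target), the rest ≥ 2×10 kb from every TSS. Common peaks have
  identical coordinates in both sets, and peaks of different classes are
  never allowed to overlap, so the planted Venn counts are exactly
  recoverable;
* **counts**: NB with log-uniform baselines on [20, 2000], dispersion
  0.05 (optionally jittered per gene), depth factors uniform on
  [0.7, 1.3]; four groups (vehicle, A, B, A+B) of 5 samples. Sample
  sizes per group are a convention — the study design this emulates does
  not pin them — and are flagged in the config;
* **external regulated set**: 50 % of planted B-unique genes plus 40
  random non-planted genes;
* **regulator network**: one planted regulator covering 80 % of the
  B-unique class plus 30 decoys with random target sets (40–120 genes);
* **motifs**: 200 shared motifs, base z ~ N(0, 2) with N(0, 0.2)
  condition noise; 10 planted motifs gain +5 z in condition B;
* **cohort**: 200 samples; signature genes load 0.7 on a shared latent
  factor, survival times exponential with log-hazard = hazard_beta ×
  (mean signature z) around a 24-month baseline median; an independent
  30 % of samples is censored uniformly before the event.

Determinism: every generator derives an independent stream from the one
seed, so outputs are byte-identical under a fixed config and independent
of call order.

What the generator does *not* emulate: read-level data, peak shapes or
sequence content, batch effects, gene–gene correlation outside the
cohort's single latent factor, mean–dispersion trends, and library
composition biases. Passing recovery tests therefore demonstrate that
the pipeline's logic is correct under its own model assumptions — not
that any particular biological dataset would yield the same signatures.

## Numerical choices and degenerate inputs

* Rank ties everywhere break lexicographically by name for determinism.
* Zero-variance genes score z = 0 rather than NaN.
* All-equal stratification scores put the whole cohort in the high
  stratum with a warning (the log-rank stage then refuses on the empty
  low group).
* Fisher odds ratios use the +0.5 Haldane correction only when a cell
  is zero.
* GSEA with an all-zero in-set metric at weight 1 falls back to uniform
  hit steps.
* Problem sizes in the test-suite simulations (e.g. 500 log-rank null
  replicates, 100 power replicates, 50 partition oracle trials of 200
  intervals) were chosen to keep Monte-Carlo error well inside each
  asserted band while the whole suite stays interactive.

## Known limitations

* The DE stand-in is calibrated but is not numerically interchangeable
  with any specific published DE package; dispersion shrinkage is global
  (no mean–dispersion trend).
* The regulatory-potential target call uses proximity + DE only; a
  rank-product refinement of target confidence is not implemented.
* The log-rank test is the standard unweighted variant.
* GSEA uses the gene-permutation null of pre-ranked mode; sample-label
  permutation is out of scope because the scorer never sees the raw
  per-sample matrix.
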