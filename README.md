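# arsig

Condition-unique transcription-factor target-gene signatures from paired
cistrome (ChIP-seq peak) and transcriptome (RNA-seq count) data.

When a transcription factor such as the androgen receptor (AR) is
reprogrammed — for example by receptor overexpression under
castrate-level ligand, as in castration-resistant prostate cancer — its
binding sites and target genes shift between conditions. `arsig`
implements the full computational route from two condition cistromes and
a count matrix to:

1. **peak-set comparison** — Venn partition into common and
   condition-unique peaks, genomic-feature distribution, top-N peak
   selection by score (−10·log₁₀ q);
2. **differential expression** — a calibrated negative-binomial Wald
   test with median-of-ratios normalization, moment dispersions and
   Benjamini–Hochberg FDR;
3. **binding–expression integration** — gene-level regulatory potential
   `rp(g) = Σᵢ exp(−(0.5 + 4·|dᵢ|/window))` over peaks within 100 kb of
   the TSS, direct-target calls (DE ∧ ≥1 peak in window), and a
   one-tailed KS test of whether regulated genes carry more binding;
4. **enrichment** — pre-ranked GSEA (weighted running sum, permutation
   NES), Fisher over-representation for pathway and regulator→target
   collections, and motif z-score rank-difference waterfalls;
5. **signature derivation** — the three-step condition-unique procedure
   (DE ∧ direct target → set difference → fold-change-ratio > 1.5
   filter), co-target intersection with an external regulated gene set,
   and per-sample combined-z / ssGSEA scores;
6. **survival** — top-25 % score stratification, Kaplan–Meier curves and
   the log-rank test (via lifelines).

A synthetic-data generator plants known peak classes, DE genes, motif
shifts, a true regulator and a score-dependent hazard, so the entire
pipeline is testable end-to-end with no external data. See
`docs/methods.md` for the model details and assumptions.

## Worked example

Run the full pipeline on the default synthetic study (2,000 genes, 60
planted DE genes per class, 300 common + 300/300 unique peaks, 5
samples/group):

```bash
arsig all --seed 1 --outdir runs/demo
```

which logs each stage and prints:

```
report written to runs/demo/report.json
signature A: precision=1.000 recall=1.000
signature B: precision=1.000 recall=0.983
```

`report.json` contains, among other entries:

```json
"venn_counts": {"common_a": 300, "common_b": 300, "unique_a": 300, "unique_b": 300},
"top_regulator": {"set": "REG_planted", "fdr": 3.7e-37},
"cotarget_sizes": {"up": 25, "down": 5},
"survival": {"statistic": 53.58, "p": 2.49e-13, "n_high": 50, "n_low": 150,
             "median_survival_high": 10.17, "median_survival_low": 47.45}
```

Reading: the Venn partition recovered the planted 300/300/300 peak
structure exactly; the derived condition-unique signatures matched the
planted gene classes (precision/recall ≈ 1); the planted regulator was
the top enrichment hit against 30 decoys; 25 up- and 5 down-regulated
direct targets intersected the external regulated set (planted overlap
50 % of the B-unique class); and the top quartile of cohort samples by
signature score had sharply worse survival (median 10.2 vs 47.5 months,
log-rank p ≈ 2×10⁻¹³ under a planted unit log-hazard per score unit).

Each stage is also available as its own subcommand over flat TSV/BED/GMT
artifacts (`arsig simulate | de | cistrome | integrate | signature |
cotarget | enrich | score | survive`), or from Python:

```python
from arsig import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=1), "runs/demo")
```

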