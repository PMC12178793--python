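# credyn

**Dynamics of cis-regulatory elements under progressive DNA damage.**

`credyn` is an analysis pipeline for studying how enhancers and promoters
change state across a three-timepoint DNA-damage time course (pre-damage,
moderate damage, severe damage — e.g., 0 h / 8 h / 16 h of doxorubicin
treatment), integrating eRNA/pancRNA expression (RNA-seq), chromatin
accessibility (ATAC-seq), activity (H3K27ac ChIP-seq), TF footprints and
p53 binding.  It is aimed at regulatory-genomics analysts who have processed
signal (fragment BEDs, peak calls, footprint tables, DE tables, loop lists)
and want a reproducible, tested implementation of the downstream analysis —
plus a synthetic-data generator that makes every stage testable without any
sequencing data.

## What it computes

- **Catalog curation** — candidate enhancers are removed if they overlap
  gene bodies extended ±1 kb (a coding-region proxy spanning TSS to TES) or
  blacklist regions; survivors are split by strand-aware upstream distance
  *d* from the nearest TSS to the enhancer midpoint: *proximal* for
  1 kb < *d* ≤ 2 kb, *distal* for *d* > 2 kb.  Promoters are
  strand-annotated by nearest TSS.
- **Signal quantification** — region expression as reads-per-million,
  RPM = (fragments overlapping the region by ≥ 1 bp) / library total × 10⁶,
  and CPM-normalized, binned (50 bp), smoothed (60 bp) coverage profiles
  around element centers.
- **State trajectories** — an element is accessible/active at a timepoint
  iff it overlaps a peak (≥ 1 bp), expressed iff RPM > 0; over the three
  timepoints it is *consistently positive* (all three), *consistently
  negative* (none) or *dynamic*.  Random genomic regions (10,000 × 2 kb,
  length-weighted placement) and random accessible regions (peaks avoiding
  all elements) provide controls.
- **Enhancer–gene pairs** — targets via basal-plus-extension regulatory
  domains (5 kb up / 1 kb down of the TSS, extended ≤ 1 Mb to the nearest
  neighbouring basal region) and via chromatin-loop anchors; a pair is
  *coordinated* (up or down) when enhancer RPM and gene expression are
  strictly monotone in the same direction across both timepoint steps.
  Consistently differential genes pass |log2FC| > 1 and FDR < 0.05 in both
  the 8h-vs-0h and 16h-vs-0h contrasts with the same sign.
- **TF footprint variability** — footprint protection scores and tag counts
  are aggregated per TF per timepoint, ranked by the sample standard
  deviation of activity across timepoints; top-30 lists per element class
  are intersected (TF complex names like `FOSL1::JUN` compared verbatim).
  Elements are partitioned into p53-bound/p53-free classes by p53 peak
  overlap (p53BER/p53FER/p53BPR/p53FPR).
- **Test battery** — the paired Friedman test in its tie-corrected
  chi-square form,

  Q = [12/(n·k·(k+1)) · Σⱼ Rⱼ² − 3n(k+1)] / C,  C = 1 − Σ(t³−t)/(n·k·(k²−1)),

  with exact small-*n* p-values by full (k!)ⁿ enumeration, and the unpaired
  two-sample Kolmogorov–Smirnov test with exact small-sample p-values by
  lattice-path enumeration; significance stars at p < 0.05/0.01/0.001/0.0001.

## Worked example

A complete synthetic run (no input files needed — the `simulate` stage
writes a ~2,000-element bundle with planted temporal structure):

```bash
credyn all --out demo --seed 1
```

The `compare` stage tests each element class for temporal change
(`demo/compare/friedman_by_class.tsv`); the RNA rows of that table:

```
assay    group   n  statistic       p_value stars  mean_0h  mean_8h  mean_16h
  RNA   distal 900 631.851150 6.241170e-138  ****  63.7456  36.4711   53.2711
  RNA promoter 800 731.011173 1.832064e-159  ****  39.1038  27.3625   19.9925
  RNA proximal 300 271.286974  1.232487e-59  ****  43.9133  32.2533   23.5233
```

Distal enhancer expression falls at moderate damage and rebounds at severe
damage (63.7 → 36.5 → 53.3 mean RPM) while promoter expression declines
monotonically (39.1 → 27.4 → 20.0), both overwhelmingly Friedman-significant
— the planted damage-response pattern.  The `report` stage scores every
stage's output against the generator's truth ledger
(`demo/report/recovery.tsv`):

```
             stage    metric   value
   trajectory_ATAC  accuracy 1.00000
trajectory_H3K27ac  accuracy 1.00000
    trajectory_RNA  accuracy 1.00000
 coordinated_pairs precision 0.43956
 coordinated_pairs    recall 1.00000
           top_tfs    recall 1.00000
     p53_partition precision 1.00000
     p53_partition    recall 1.00000
```

All planted trajectories, high-variance TFs and p53-bound elements are
recovered exactly, and every planted coordinated pair is found.  Pair
precision below 1 at default noise is expected: sampling noise makes some
unplanted enhancer–gene combinations genuinely monotone-coordinated, and
the detector reports what the data show (noise-free runs give precision
1.0; see `docs/methods.md`).

The same stages are available as library functions (`credyn.catalog`,
`credyn.signal`, `credyn.states`, `credyn.pairs`, `credyn.tfdyn`,
`credyn.stats`, `credyn.synthdata`) for use on real processed data; every
input is a plain BED/TSV format documented in the module docstrings.

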