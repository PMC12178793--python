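# Methods

This note documents the models, conventions and design choices behind
`credyn`: what each stage assumes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the numerical
details a user auditing results will want.

## Coordinates and overlap

All intervals are 0-based half-open (BED convention); *overlap* always
means at least one shared base, so an element `[100, 200)` and a peak
`[200, 300)` do not overlap.  Interval queries run on per-chromosome
interval trees; region counting uses sorted-array bisection
(`#(start < region_end) − #(end ≤ region_start)`), which is exact for
arbitrary interval sets.

## Catalog curation

Enhancers are removed when they overlap any gene interval extended by
`pad` (default 1,000 bp) on both sides, or any blacklist interval.  The
coding-region proxy is deliberately the full TSS-to-TES span, not an
exon-level mask: eRNA quantification is confounded by any overlapping
transcript signal, not only by exonic reads.

Distal/proximal classification measures the strand-aware upstream distance
from a gene's TSS to the **enhancer midpoint** (`floor((start+end)/2)`).
Genomic distance conventions differ between tools (edge vs midpoint); the
midpoint is symmetric, matches how profile plots are centred, and makes
classification invariant under reflection of the element.  Among genes
that have the enhancer on their upstream side the minimum distance is
taken; an enhancer downstream of every gene falls back to the unsigned
nearest-TSS distance, so every retained enhancer receives a class.
Distances ≤ 1 kb mark an element `too_close`; such elements cannot survive
filtering when each gene's TSS lies inside its own interval and the pad is
1 kb, but the guard is kept for unusual gene models.  Promoter strand is
the strand of the nearest TSS, ties broken by lexicographically smaller
gene id for determinism.

## Signal quantification

`region_rpm` counts fragments overlapping the region by ≥ 1 bp and scales
by the per-sample library total (`counts/total × 10⁶`).  Counting whole
fragments rather than per-base coverage keeps the quantity a true
"reads per million" and makes the scale-invariance property exact
(doubling every fragment and the library total changes nothing).

Profile matrices accumulate per-base coverage in `[center − flank,
center + flank)` (default flank 1,000 bp), average within 50-bp bins,
normalize to counts-per-million, and mean-smooth with a 60-bp window.  A
bin enters another bin's smoothing window when the two bins overlap the
`smooth`-bp span centred on the target bin (for 50-bp bins and 60-bp
smoothing: the bin and its two neighbours); windows truncate at the matrix
edges with no padding, so edge bins average over fewer bins rather than
over invented zeros.  Windows extending below coordinate 0 contribute zero
coverage.  Minus-strand rows are reversed so bins always run 5′→3′.
Treatment−control subtraction is elementwise and may go negative.

## State trajectories

Binary states are peak overlap (accessibility, activity) or RPM > 0
(expression) per timepoint; the three-timepoint trajectory is
`consistent_positive` (all set), `consistent_negative` (none set), else
`dynamic`.  The two consistent groups are the analysis targets; dynamic
elements are retained in outputs so the three categories always partition
the catalog.

Random regions (default 10,000 × 2 kb) choose a chromosome with
probability proportional to its length, then a start uniformly such that
the region fits — a uniform-per-base draw over the genome.  They may
overlap elements and each other; only *random accessible regions* (drawn
uniformly without replacement from peaks, lengths preserved verbatim)
exclude the element catalog.  Both draws are pure functions of their seed;
the pipeline draws once per run from the run seed.

## Enhancer–gene pairs

The nearest-gene model is basal-plus-extension: a basal window 5 kb
upstream / 1 kb downstream of each TSS (strand-oriented), extended on both
sides up to 1 Mb but stopping at the nearest neighbouring basal-region
boundary and the chromosome edge.  A neighbour whose basal region overhangs
the gene's own basal region blocks extension on that side entirely, so
domains overlap only where basal regions themselves overlap.  An enhancer
is assigned to every gene whose domain contains its midpoint.  Loop
evidence pairs an enhancer with a gene when one loop anchor overlaps the
enhancer and the other overlaps the gene's promoter, in either anchor
order; both evidence routes are reported (`domain`, `loop`, `both`) and the
caller may filter on provenance.

A candidate pair is *coordinated* when enhancer RPM and gene expression
triples are strictly monotone in the same direction at both steps, with a
configurable minimum step `eps` (default 0, i.e., strict monotonicity).
Direction uses the expression triples themselves; the DE tables provide an
independent cross-check (`consistent_de_genes`) but do not gate the pair
call.  The decision is invariant under uniform rescaling of all expression
values, so RPM/TPM unit choices cannot change it.

## TF footprints and p53

Per-TF binding activity at a timepoint is the mean of the chosen metric
over that TF's footprints.  The footprinting score semantics ("protection
score" = cleavage depletion in the footprint vs flanks, plus a tag count)
leave the combination open, so the metric is configurable:
`protection`, `tag_count`, or the default `combined` — the mean of the two
components after min-max normalization across the whole footprint table,
which puts both on a common [0, 1] scale without assuming either dominates.
TFs missing a timepoint are dropped with a logged reason rather than
imputed.  Ranking uses the sample standard deviation (ddof = 1) of the
three activities, descending, ties broken lexicographically; top-list
intersections compare names verbatim — `A::B` complexes are never split.
p53 partitioning is plain peak overlap; the four classes are asserted to
partition enhancers and promoters on every run.

## Test battery

**Friedman.**  Within-row mid-ranks; tie-corrected chi-square statistic
(see README for the formula).  When every row is fully tied the correction
factor is 0 and Q is defined as 0 with p = 1.  For n ≤ `exact_n_max`
(default 6) the p-value is exact: all (k!)ⁿ within-row orderings are
enumerated with multiplicity (tied rows contribute duplicate rank vectors,
keeping the null uniform), and p is the fraction of orderings with
Q ≥ Q_obs (tolerance 10⁻¹²).  Otherwise p is the chi-square upper tail
with k − 1 df.  The chi-square form (not the F approximation) is used
because the intended application is k = 3 with hundreds to thousands of
rows, where the chi-square null is accurate; the `method` field records
which path produced each p-value.

**Kolmogorov–Smirnov.**  D is the supremum ECDF distance evaluated after
advancing through tied pooled values, so ties never contribute spurious
intermediate deviations.  When m + n ≤ `exact_total_max` (default 20) and
the pooled sample is tie-free, the p-value is exact via integer
lattice-path counting: D is held as the integer `max |i·n − j·m|`, and the
number of monotone paths keeping the deviation strictly below it is
counted with exact integer arithmetic, giving
p = 1 − (#paths below)/C(m+n, n).  With cross-sample ties the exact null is
ill-defined without a tie-breaking convention, so the implementation logs a
note and falls back to the asymptotic series
p = 2·Σ (−1)^{j−1} exp(−2 j² e²) with the small-sample effective-size
correction e = (√(mn/(m+n)) + 0.12 + 0.11/√(mn/(m+n)))·D, truncated when
terms drop below 10⁻¹⁰ and clamped to [0, 1].

**Stars.**  Strict thresholds: p < 0.05/0.01/0.001/0.0001 → `*`–`****`,
else `ns`; p = 0.05 is `ns`.  No multiple-testing correction is applied
across comparison tables — stars are per-test annotations.

## Synthetic-data generator

The generator emulates the *processed* form of a three-timepoint
multi-omics experiment, not reads: it lays out a genome of 12-kb gene
slots across three chromosomes (alternating gene strand), places per slot
one gene, one promoter, up to three distal enhancers (3.4–5 kb upstream of
the TSS) and optionally one proximal enhancer (1.5 kb upstream), plus
decoy enhancers violating the curation rules and matching blacklist
entries.  Geometry guarantees ≥ 200 bp between any two elements, so peak
jitter and fragment placement can never bleed across elements.

Fragment counts per element, assay and timepoint are negative-binomial
(Gamma–Poisson; variance = μ + αμ², dispersion α = 0.05 by default) around
`baseline_rate` (50 fragments at 0 h) times a class/assay profile.  The
default profiles encode the damage-response directions: distal RNA
(1.0, 0.6, 1.2) and ATAC (1.0, 0.7, 1.1) fall then rebound, H3K27ac
(1.0, 0.6, 1.2) likewise, promoter RNA (1.0, 0.7, 0.5) and ATAC
(1.0, 0.8, 0.65) fall monotonically; a silent fraction (default 0.2) has
zero RNA everywhere.  The manifest's per-sample library total is a fixed
library size (default 10⁶) rather than the file's fragment count: the
emitted fragments are only the element-proximal subset of a library
dominated by genome-wide background, and normalizing by the subset's size
would spuriously cancel the global temporal profiles.  Zero dispersion
switches counts to rounded means, giving fully deterministic
("noise-free") bundles.

ATAC/H3K27ac states are planted per element (defaults: 70% consistently
positive, 15% consistently negative, 15% dynamic); peaks are emitted
directly from the planted states with boundary jitter (±10% of element
length) as the only state noise, so state-recovery tests are not
confounded by any peak-calling emulation.  State-negative timepoints still
receive 2% background coverage, keeping coverage and peaks qualitatively
consistent.  RNA expression truth is the realized counts themselves.

Planted coordinated pairs (default 40, half down / half up) override the
RNA profile of one distal enhancer per pair with a steep monotone profile
((1.0, 0.45, 0.15) at baseline 300 — strongly expressed, as real
coordinated enhancers are) and give the target gene a matching monotone
TPM profile with lognormal noise (σ = 0.05); distractor pairs (default 60)
get direction-conflicting or non-monotone partners.  Pairs are planted in
slots without proximal enhancers: a proximal enhancer's monotone-down
class profile inside the same regulatory domain as a planted down gene
would otherwise create pairs that are coordinated in truth but absent from
the ledger.  Loops connect each planted and distractor pair.  Footprint
tables plant `n_hi_var_tf` (default 8) TFs whose activity triples swing
several-fold while the rest stay within a few percent — far beyond the 5×
variance separation at which top-k recovery is checked — including `::`
complex names.  DE tables give planted monotone genes and a set of extra
genes passing both contrasts; all others are null.

What the generator does **not** emulate: read-level sequence content,
alignment and duplication artifacts, peak-caller boundary behaviour,
copy-number or GC biases, inter-element signal bleed, and Hi-C contact
noise (loops are exact).  Passing recovery tests therefore demonstrates
the correctness of the analysis logic under realistic count overdispersion
— not robustness to upstream processing errors in real data.

Coordinated-pair *precision* at default noise is substantially below 1
(≈ 0.4–0.6 on default bundles) and this is a property of the truth
definition, not a detector fault: under sampling noise some unplanted
enhancer–gene combinations are genuinely strictly monotone in the same
direction, and the detector correctly reports them.  Noise-free bundles
give precision = recall = 1 exactly; at default noise recall stays ≥ 0.9
by the planted pairs' steep profiles.

## Pipeline, determinism, problem sizes

Every stage writes its outputs plus a `manifest.json` snapshot (stage
parameters, seed, input paths relative to the run directory, row counts,
package version) and never mutates inputs, so identical configurations
yield byte-identical run trees; the test suite asserts this at file-hash
level.  All randomness — generator, random regions, subsampling — derives
from the run seed.

Default problem sizes are chosen so a full synthetic run (2,000 elements,
~900 k fragments across nine assay-timepoint files) completes in a few
seconds, and the test suite's heaviest checks (exhaustive permutation
oracles up to (3!)⁴ orderings per matrix, 10,000-replicate null
calibration of the Friedman test, 20-seed pattern reproduction) complete
in about a minute each.  Exact-path cutoffs (`exact_n_max = 6`,
`exact_total_max = 20`) keep enumeration costs bounded at ~46,000 and
~185,000 states respectively.

## Known limitations

- The distance classification assumes a single TSS per gene model;
  alternative promoters must be supplied as separate gene records.
- `region_rpm` counts fragments, not per-base area; for very long regions
  relative to fragment length the two conventions diverge.
- The exact KS path requires a tie-free pooled sample; heavily discretized
  data always takes the asymptotic route (logged).
- The domain model approximates a nearest-gene assignment; it does not use
  expression-based target inference, and loop calls are taken as given.
- The generator's planted states are independent across elements; real
  chromatin states are spatially correlated.
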