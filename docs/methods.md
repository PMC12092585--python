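# Methods

## Coordinates and gene models

All arithmetic uses 0-based half-open intervals (BED convention); GTF input
is shifted on read. A gene's TSS/TES are stored as *boundary* coordinates of
its longest transcript (ties broken by smallest start, for determinism), so
the TSS-to-TES span in genomic order is exactly the half-open gene body.
Windows are strand-aware: the promoter is −1000/+500 bp of the TSS and the
TF-target window −5000/+1000 bp, both measured in the direction of
transcription and clipped to chromosome bounds. Strand awareness of these
windows is an explicit modelling choice (standard practice for TSS-anchored
windows) and is pinned by mirror-symmetry property tests. Fragments are
unstranded — a paired-end fragment covers both strands — and duplicates are
defined by the full span (chrom, start, end), since PCR duplicates of a
paired-end fragment share both ends. The same deduplication rule is applied
to target and spike-in fragments.

## Peak calling

A re-implementation of local-Poisson window calling: 500-bp windows tiled
at a 100-bp step; fragment midpoints counted per window (midpoint counting
assigns each fragment to exactly one window width); the null rate is
max(λ_bg, λ_ctrl, 0.25) where λ_bg = N_sample·width/genome_length and
λ_ctrl is the control's window count scaled by N_sample/N_control. The
0.25 floor guards windows where both background and control are nearly
empty. Windows with an exact Poisson upper-tail probability < 1e-5 merge
when gapped ≤ 100 bp; a merged peak keeps its minimum window p and the
enrichment Σk/Σλ over member windows. The step and merge gap are package
choices. "Peaks present in both control sets" is implemented asymmetrically:
vs-IgG peaks are retained when they overlap (≥ 1 bp) any vs-input peak, and
the vs-IgG coordinates are kept, preserving a single canonical coordinate
set. Merged peak coordinates (not window summits) define peaks. No fragment
size model or broad-peak mode is attempted.

## The exact conditional count test

One test engine serves CUT&RUN and RNA-seq, differing only in where library
sizes come from. For a feature with within-group count sums (y_A, y_B) and
summed library sizes (L_A, L_B), the null conditional distribution of y_A
given n = y_A + y_B is Beta-Binomial(n, π0, ρ), π0 = L_A/(L_A+L_B); at
ρ = 0 this is the classic conditional binomial. The two-sided p-value is
the minimum-likelihood sum: every outcome whose pmf is ≤ the observed pmf
(relative tie tolerance 1e-8) contributes. When the inclusion set is the
whole support, p is exactly 1. log2 fold change uses a 0.5 pseudocount on
the group sums: log2((y_B+0.5)/L_B) − log2((y_A+0.5)/L_A); a feature with
n = 0 gets p = 1 and log2FC = 0. BH step-up FDR is applied across features.

Overdispersion ρ is estimated once, pooled over features, from within-group
replicate pairs by method of moments on conditional proportions:
E[(k_a − nπ)²] = nπ(1−π)(1 + (n−1)ρ_pair). Because the test conditions on
*group sums*, the pair-level estimate is rescaled: summing m i.i.d.
gamma-Poisson counts multiplies the Beta-Binomial precision a+b by m, so
the test uses ρ with a_tot = (m_A+m_B)/2 · (1−ρ_pair)/ρ_pair. Without this
rescaling the test is visibly conservative; with it, the empirical type-I
error on gamma-Poisson null data sits at the nominal 5% (asserted within
[0.03, 0.07] in the suite). ρ is floored at 0 (single-replicate groups warn
and use 0) and capped at 0.95.

The exact conditional test depends on library sizes only through their
ratios: scaling every library size by a constant changes neither p-values
nor fold changes (tested). Scaling a *single* sample's counts and size
changes the conditioning total, so per-sample invariance holds only
asymptotically and is not asserted.

## Normalization front-ends

* **Spike-in** — the library size of each mark sample is its deduplicated
  spike-in fragment count. Zero spike-in counts abort with a pointer to the
  enriched-regions mode.
* **Enriched regions** (low-spike-in fallback, used for the body mark) —
  per mark sample and control, each gene body is tested with an upper-tail
  binomial: p0 = (k_gc + 0.5)/(N_c + 0.5), p = P(Bin(N_s, p0) ≥ k_gs),
  where N are the samples' genome-wide totals; BH per (sample, control)
  across genes; a gene must pass FDR ≤ 0.05 against *both* controls, and the
  common set intersects all mark samples. Each sample's library size is its
  fragment total over the common set. The 0.5 smoothing and upper-tail
  orientation are package choices (the sidedness was otherwise unspecified);
  an empty common set is fatal with per-sample diagnostics.
* **Median-of-ratios** (RNA-seq) — genes with any zero count are excluded
  from the median; size factors feed the same exact test.

## RNA-seq rules

Genes with fewer than 10 fragments in *every* sample are dropped before
testing ("every sample low" — the alternative reading, any-sample-low,
would discard most genes). A DEG must pass FDR ≤ 0.05 and the fold-change
cut in *each* knockout-guide contrast with a shared direction; the DEG
definition uses FC ≥ 2, while the downregulated set feeding the
direct-target intersection uses FC ≥ 1.5.

## Classification and integration

C1 ⇔ dec_K4 ∧ dec_K36; C2 ⇔ dec_K4 only; C3 ⇔ dec_K36 only; C4 ⇔ no
decrease and any increase; C5 = remainder. A gene decreased in one mark and
increased in the other is assigned by the decrease (C2/C3): the decreased
clusters carry the downstream biology, so "decreased" takes precedence; the
rule is isolated in `classify_genes` and surfaced in the cluster table's
flag columns. Direct targets are rna_down ∩ (dec_K4 ∪ dec_K36) — the union
reading is consistent with the reported per-mark overlap fractions and is
exposed as plain set algebra should a different combination be wanted. Set
overlaps use the two-sided Fisher exact test (minimum-likelihood two-sided
convention, matching the exact count test); the overlap universe is the
intersection of the CUT&RUN and RNA-seq universes. Report percentages are
rounded to one decimal and printed without the decimal when it is zero
(3% vs 5.3%), matching the mixed precision convention of published counts.

## Signal tracks and metagene profiles

Tracks resize each fragment to 151 bp around its midpoint (−75/+75),
multiply per-bp coverage by 1e6/library_size (the library size used in the
differential test), and average within 10-bp bins; mass is conserved up to
bin-edge rounding (Σ value·width = 151·n·1e6/L, asserted within ±n).
Metagene matrices have a fixed 100-column layout — 20×100-bp upstream bins,
60 length-scaled body bins, 20×100-bp downstream bins — with minus-strand
genes flipped so column 0 is always 5'. Body bins average coverage per bin
(not sum) so profile height is length-invariant. Replicates are averaged
per bin *after* per-sample scaling. Heatmap rows order by cluster (C1–C5),
then descending control H3K4me3 signal in TSS ± 1000 bp, ties by gene id;
the published ordering sentence omits C4 and lists C5 twice (an apparent
typo), so all clusters here use the same TSS rule.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
sequence-level realism. Defaults: 300 non-overlapping genes (bodies uniform
2–20 kb, ≥ 1 kb gaps, random strand) on a 5-Mb chromosome; 2 CUT&RUN
replicates per condition at N = 200 000 fragments/sample; fragment lengths
Normal(180, 30) clipped to [50, 500]; enrichment factor 8 (a marked gene's
footprint carries 8× the background density — promoter footprint 1.5 kb
for H3K4me3, the whole body for H3K36me3); knockout loss factor 4; planted
class fractions 5% each for C1–C4. H3K4me3 midpoints are Normal(TSS,
σ = 200 bp); H3K36me3 midpoints follow a linear density ramp from TSS to
TES (inverse-CDF √U), matching the displayed promoter-peaked and
TES-ramped shapes. IgG and input are background-only.

Each sample draws exactly N fragments (fixed sequencing depth), allocating
them multinomially between background and genes in proportion to weights;
knockout divides affected weights by the loss factor. Because depth is
fixed, a global signal loss is invisible in raw counts — which is precisely
why spike-in calibration exists. Spike-in amount is constant per cell:
sequencing N target fragments from a condition with per-cell signal W
samples N/W cell-equivalents, so the sequenced spike-in count is
spikein_fraction·N·W_control/W_condition. Spike-in normalization then
recovers per-cell signal exactly, while total-count normalization cannot
see a global loss (both directions asserted in the suite). RNA-seq counts
are NB(s_j·μ_g·2^(lfc·I[knockout]), φ = 0.1) with μ_g log-uniform 8–1024,
size factors log-uniform [0.5, 2], a control and two knockout guides
sharing planted lfc = −2 on all C1–C3 genes plus 2% of C5 genes (so the
planted direct-target set is a strict subset of the RNA-down set). TF peaks
are 400-bp intervals near the TSS of bound genes (80% of C1–C3, 20%
otherwise).

What the generator does **not** model: GC/mappability structure in the
background (uniform instead — sufficient for the statistics under test and
keeps the oracles analytic), read-level errors, exon structure, alternative
promoters, batch effects, or between-replicate biological overdispersion in
CUT&RUN fragments (replicates differ only by sampling noise). Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the assumed model, not robustness to artifacts real data
may carry.

## Problem sizes and determinism

The default study scale — 300 genes, 5 Mb, 200 000 fragments/sample — was
chosen so the planted effects are detected with comfortable power while a
full pipeline run stays in the seconds range; the acceptance script and the
test suite both run it end to end. All randomness flows from a single
integer seed through per-stage child streams; identical configurations are
byte-identical, including file outputs. Control samples are seeded
independently of the mark so both marks share the same IgG/input fragments,
as in the emulated design.

## Known limitations

* The beta-binomial conditional test is a fully specified stand-in for
  quantile-adjusted conditional maximum likelihood; it matches the
  conditional binomial exactly at ρ = 0 and is calibrated on gamma-Poisson
  nulls, but does not shrink dispersions feature-wise.
* Peak calling has no fragment-size model and no broad mode; very wide
  domains are represented as runs of merged windows.
* The binomial enrichment screen conditions on genome-wide totals; if a
  mark relocates mass without concentrating it in gene bodies, the common
  significant set can be empty (this is surfaced, not papered over).
* With fixed per-sample depth, simultaneous planted gains (C4) and losses
  (C1–C3) partially offset in the spike-in ratio; the per-gene statistics
  remain correct, but global summaries of "total signal" should be read
  with the composition in mind.
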