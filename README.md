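# cutrun-delta

Differential histone-methylation analysis for spike-in-calibrated CUT&RUN,
with RNA-seq integration. The package implements the complete analysis path
from deduplicated paired-end fragments to a five-cluster gene classification
and direct-target calls:

1. **Peak calling** — sliding 500-bp windows (100-bp step) scored with an
   exact Poisson upper tail against a local rate
   λ_local = max(λ_background, λ_control, 0.25); a sample's peaks are its
   vs-IgG calls that also overlap a vs-input call, minus blacklist hits.
2. **Quantification** — fragment-midpoint counts over merged peaks
   (H3K4me3), promoters (−1000/+500 bp of the TSS, strand-aware) and gene
   bodies of the longest transcript (H3K36me3); 151-bp-resized, CPM-scaled,
   10-bp-binned signal tracks; 100-column metagene matrices.
3. **Differential testing** — an exact conditional count test: for group
   sums (y_A, y_B) and library sizes (L_A, L_B), y_A | y_A+y_B = n is
   Beta-Binomial(n, L_A/(L_A+L_B), ρ) under the null (Binomial at ρ = 0),
   with the two-sided p summing all outcomes no more likely than the
   observed one and BH-FDR across features. Library sizes are pluggable:
   spike-in fragment counts; totals over gene bodies binomially enriched
   over *both* IgG and input in *every* sample (the low-spike-in fallback);
   or median-of-ratios size factors for RNA-seq.
4. **Integration** — genes are partitioned into C1 (both marks down), C2
   (H3K4me3 only), C3 (H3K36me3 only), C4 (any mark up), C5 (unchanged);
   direct targets are RNA-downregulated genes (FDR ≤ 0.05, FC ≥ 1.5 in both
   knockout guides) losing at least one mark; set overlaps are scored with
   two-sided Fisher's exact tests; TF targets are genes whose −5 kb/+1 kb
   TSS window overlaps a ChIP peak.

A first-class synthetic-data generator (`cutrun_delta.simulate`) emulates
the full study design — TSS-peaked H3K4me3, TES-ramped H3K36me3, IgG/input
controls, constant-per-cell spike-in, and a 3×3 RNA-seq negative-binomial
matrix — with planted per-gene truth, so every stage is validated by
parameter recovery at desk scale.

## Worked example

The numbered scripts under `analysis/` run the default synthetic study
(300 genes on 5 Mb, 2 CUT&RUN replicates per condition at 200 000 fragments
per sample, 8-fold mark enrichment, 4-fold planted knockout losses):

```bash
python analysis/01_simulate_dataset.py
python analysis/02_call_peaks.py
python analysis/03_differential_marks.py
python analysis/04_rnaseq_de.py
python analysis/05_classify_integrate.py
python analysis/06_tracks_metaplots.py
```

Script 05 prints, for seed 1:

```
cluster sizes: {'C1': 14, 'C2': 15, 'C3': 16, 'C4': 17, 'C5': 238}
direct targets: 34; TF-bound fraction: 85.3%
rna_down_vs_dec_k4: intersection 20, Fisher p = 5e-14
rna_down_vs_dec_k36: intersection 23, Fisher p = 3.35e-18
planted-cluster agreement: 98.3%
```

The planted truth was 15/15/15/15/240 genes in C1–C5: the pipeline recovers
the planted clusters almost perfectly, and the Fisher overlaps between
RNA-downregulated and mark-losing genes are vanishingly small, as expected
when transcriptional loss is driven by mark loss. The same machinery is
available as a CLI (`cutrun-delta simulate|callpeaks|quantify|tracks|diff|
classify|integrate|run-all`).

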