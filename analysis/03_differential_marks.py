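"""Differential H3K4me3 (merged peaks, spike-in sizes) and H3K36me3
(gene bodies, binomial-enrichment sizes) between knockout and control.

Prints the library sizes each normalization resolved and writes the two
differential tables plus the per-mark decreased/increased gene lists.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from _paths import RESULTS, SCRATCH

from cutrun_delta import differential as diff
from cutrun_delta.genome import read_annotation
from cutrun_delta.io_formats import deduplicate, read_fragments
from cutrun_delta.pipeline import differential_mark_k36
from cutrun_delta.quantify import count_table


def load(sid: str, what: str = "target"):
    return deduplicate(read_fragments(SCRATCH / f"{sid}.{what}.bedpe", sid))


def gene_sets(result, features, annotation, mode):
    return diff.call_differential_genes(result, features, annotation, mode=mode)


def main() -> None:
    annotation = read_annotation(SCRATCH / "genes.bed", SCRATCH / "chrom_sizes.tsv")
    outdir = RESULTS
    outdir.mkdir(exist_ok=True)

    # H3K4me3: counts over the merged peaks from script 02, spike-in sizes
    merged = pd.read_csv(RESULTS / "peaks" / "merged_peaks.tsv", sep="\t")
    k4_samples = [f"H3K4me3_{c}_r{i}" for c in ("control", "knockout") for i in (1, 2)]
    k4_frags = {s: load(s) for s in k4_samples}
    table = count_table(list(k4_frags.values()), merged)
    spike = {s: load(s, "spikein").n_fragments for s in k4_samples}
    norm = diff.spikein_library_sizes(spike)
    print("spike-in library sizes:", dict(norm.library_sizes))
    k4 = diff.exact_count_test(table, k4_samples[:2], k4_samples[2:], norm)
    diff.write_diff(k4, outdir / "diff_h3k4me3.tsv")
    dec4, inc4 = gene_sets(k4, merged, annotation, "promoter")

    # H3K36me3: gene-body counts, binomial-enrichment sizes
    k36_samples = [f"H3K36me3_{c}_r{i}" for c in ("control", "knockout") for i in (1, 2)]
    targets = {s: load(s) for s in k36_samples}
    for ctrl in ("igg_control", "igg_knockout", "input_control", "input_knockout"):
        targets[ctrl] = load(ctrl)
    conditions = {s: ("knockout" if "_knockout_" in s else "control") for s in k36_samples}
    k36, norm36, common = differential_mark_k36(targets, annotation, k36_samples, conditions)
    print(f"binomial enrichment: {len(common)} common significant gene bodies")
    print("enriched-region library sizes:", dict(norm36.library_sizes))
    diff.write_diff(k36, outdir / "diff_h3k36me3.tsv")
    dec36, inc36 = gene_sets(k36, None, annotation, "body")

    for name, s in [("dec_k4", dec4), ("inc_k4", inc4),
                    ("dec_k36", dec36), ("inc_k36", inc36)]:
        pd.Series(sorted(s)).to_csv(outdir / f"genes_{name}.txt", index=False, header=False)
        print(f"{name}: {len(s)} genes")


if __name__ == "__main__":
    main()
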