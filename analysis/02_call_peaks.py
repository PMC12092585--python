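"""Call H3K4me3 peaks per sample against IgG and input, then merge.

Each sample's peaks are the vs-IgG calls retained when they also overlap a
vs-input call; the union across the four samples defines the merged peak
set used for differential counting.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _paths import RESULTS, SCRATCH

from cutrun_delta.genome import read_chrom_sizes
from cutrun_delta.io_formats import deduplicate, read_fragments
from cutrun_delta.peaks import (
    call_peaks,
    intersect_peak_sets,
    merge_peaks_across_samples,
    write_peaks_bed,
)

MARK_SAMPLES = [
    "H3K4me3_control_r1", "H3K4me3_control_r2",
    "H3K4me3_knockout_r1", "H3K4me3_knockout_r2",
]


def main() -> None:
    sizes = read_chrom_sizes(SCRATCH / "chrom_sizes.tsv")
    outdir = RESULTS / "peaks"
    outdir.mkdir(parents=True, exist_ok=True)
    per_sample = []
    for sid in MARK_SAMPLES:
        cond = "knockout" if "_knockout_" in sid else "control"
        sample = deduplicate(read_fragments(SCRATCH / f"{sid}.target.bedpe", sid))
        igg = deduplicate(read_fragments(SCRATCH / f"igg_{cond}.target.bedpe"))
        inp = deduplicate(read_fragments(SCRATCH / f"input_{cond}.target.bedpe"))
        vs_igg = call_peaks(sample, igg, sizes)
        vs_input = call_peaks(sample, inp, sizes)
        both = intersect_peak_sets(vs_igg, vs_input)
        write_peaks_bed(both, outdir / f"{sid}.peaks.bed")
        print(f"{sid}: {len(vs_igg)} vs IgG, {len(vs_input)} vs input, {len(both)} in both")
        per_sample.append(both)
    merged = merge_peaks_across_samples(per_sample)
    merged.to_csv(outdir / "merged_peaks.tsv", sep="\t", index=False)
    print(f"merged peak set: {len(merged)} intervals -> {outdir / 'merged_peaks.tsv'}")


if __name__ == "__main__":
    main()
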