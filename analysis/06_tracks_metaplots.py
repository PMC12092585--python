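"""Scaled signal tracks and metagene profiles per cluster.

Builds spike-in-scaled (H3K4me3) and enriched-region-scaled (H3K36me3)
tracks, averages replicates, and writes the 100-column metagene matrix and
per-cluster mean profiles, plus a metaplot PNG. The (large, regenerable)
bedGraph tracks go under scratch/; the matrices and figure under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
from _paths import RESULTS, SCRATCH

from cutrun_delta.genome import read_annotation
from cutrun_delta.io_formats import deduplicate, read_fragments, write_bedgraph
from cutrun_delta.quantify import make_track, meta_matrix


def main() -> None:
    annotation = read_annotation(SCRATCH / "genes.bed", SCRATCH / "chrom_sizes.tsv")
    clusters = pd.read_csv(RESULTS / "clusters.tsv", sep="\t", index_col=0)["cluster"]
    track_dir = SCRATCH.parent / "tracks"
    track_dir.mkdir(parents=True, exist_ok=True)
    outdir = RESULTS / "metagene"
    outdir.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for row, mark in enumerate(("H3K4me3", "H3K36me3")):
        for col, cond in enumerate(("control", "knockout")):
            tracks = []
            for rep in (1, 2):
                sid = f"{mark}_{cond}_r{rep}"
                frags = deduplicate(read_fragments(SCRATCH / f"{sid}.target.bedpe", sid))
                lib = (
                    deduplicate(read_fragments(SCRATCH / f"{sid}.spikein.bedpe")).n_fragments
                    if mark == "H3K4me3"
                    else frags.n_fragments
                )
                track = make_track(frags, lib, annotation.chrom_sizes)
                write_bedgraph(track, track_dir / f"{sid}.bedgraph", name=sid)
                tracks.append(track)
            matrix, profiles = meta_matrix(tracks, annotation, groups=clusters)
            matrix.to_csv(outdir / f"meta_{mark}_{cond}.tsv", sep="\t",
                          float_format="%.4g")
            profiles.to_csv(outdir / f"profiles_{mark}_{cond}.tsv", sep="\t",
                            float_format="%.4g")
            ax = axes[row][col]
            for cluster, prof in profiles.iterrows():
                ax.plot(range(len(prof)), prof.values, label=cluster)
            ax.set_title(f"{mark} {cond}")
            ax.axvline(20, ls=":", c="grey")
            ax.axvline(80, ls=":", c="grey")
    axes[0][0].legend(fontsize=8)
    for ax in axes[1]:
        ax.set_xticks([20, 80], ["TSS", "TES"])
    fig.tight_layout()
    fig.savefig(RESULTS / "metaplots.png", dpi=120)
    print(f"bedGraph tracks -> {track_dir}")
    print(f"metagene matrices -> {outdir}")
    print(f"metaplot figure -> {RESULTS / 'metaplots.png'}")


if __name__ == "__main__":
    main()
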