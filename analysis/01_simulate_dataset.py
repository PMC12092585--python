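"""Simulate the synthetic study dataset.

Writes per-sample target/spike-in BEDPE fragments, the gene annotation,
RNA-seq counts, TF peaks, and the planted truth table. Fragment files land
in scratch/ (they are large and fully regenerable from the seed); the truth
table and a small design summary land in results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from _paths import RESULTS, SCRATCH, study_config

from cutrun_delta.simulate import write_dataset


def main() -> None:
    config = study_config()
    manifest = write_dataset(config, SCRATCH)
    RESULTS.mkdir(exist_ok=True)
    truth = pd.read_csv(SCRATCH / "truth.tsv", sep="\t", index_col=0)
    truth.to_csv(RESULTS / "truth.tsv", sep="\t")
    planted = truth["cluster"].value_counts().sort_index()
    print(f"simulated {len(truth)} genes; planted cluster sizes:")
    print(planted.to_string())
    print(f"{len(manifest['samples'])} fragment samples under {SCRATCH}")


if __name__ == "__main__":
    main()
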