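"""RNA-seq differential expression with the both-guides DEG rule.

Runs the exact conditional test per knockout guide over median-of-ratios
size factors; a DEG must pass FDR <= 0.05 and FC >= 2 in both guides with a
shared direction. The looser FC >= 1.5 down-set feeding the direct-target
intersection is written alongside.
"""

import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from _paths import RESULTS, SCRATCH

from cutrun_delta import differential as diff
from cutrun_delta.io_formats import read_counts


def main() -> None:
    table = read_counts(SCRATCH / "rnaseq_counts.tsv")
    with open(SCRATCH / "manifest.yaml") as fh:
        condition_map = yaml.safe_load(fh)["rnaseq_conditions"]
    degs = diff.rnaseq_de(table, condition_map, "ctrl", ["sg2", "sg3"], fc_cut=2.0)
    loose = diff.rnaseq_de(table, condition_map, "ctrl", ["sg2", "sg3"], fc_cut=1.5)
    print(f"{len(table.feature_ids)} genes, {len(degs['filtered'].feature_ids)} pass the "
          f"low-count filter; size factors: {degs['size_factors'].round(3).to_dict()}")
    print(f"DEGs (FC>=2 both guides): {len(degs['deg_down'])} down, {len(degs['deg_up'])} up")
    print(f"down at FC>=1.5 both guides: {len(loose['deg_down'])}")
    for guide, res in degs["contrasts"].items():
        diff.write_diff(res, RESULTS / f"rnaseq_{guide}_vs_ctrl.tsv")
    for name, s in [("rna_deg_down", degs["deg_down"]), ("rna_deg_up", degs["deg_up"]),
                    ("rna_down_fc1.5", loose["deg_down"])]:
        pd.Series(sorted(s)).to_csv(RESULTS / f"genes_{name}.txt", index=False, header=False)


if __name__ == "__main__":
    main()
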