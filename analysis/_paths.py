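"""Shared locations and the study configuration for the analysis scripts.

Large per-sample fragment files go under scratch/ (regenerable at any time
from the seed); tables and reports go under results/.
"""

from pathlib import Path

from cutrun_delta.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

SEED = 1


def study_config() -> SimulationConfig:
    """The default synthetic study: 300 genes on 5 Mb, 2 CUT&RUN replicates
    per condition at 200k fragments, 4-fold planted losses, 3x3 RNA-seq."""
    return SimulationConfig(seed=SEED)
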