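import pytest

from cutrun_delta.genome import GeneModel, GenomeAnnotation
from cutrun_delta.pipeline import run_all
from cutrun_delta.simulate import SimulationConfig


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """Three genes on a 100-kb chromosome, both strands, two transcripts."""
    genes = [
        GeneModel.from_transcripts("gA", "chr1", "+", [(10_000, 18_000)]),
        GeneModel.from_transcripts("gB", "chr1", "-", [(30_000, 42_000), (32_000, 40_000)]),
        GeneModel.from_transcripts("gC", "chr1", "+", [(60_000, 75_000)]),
    ]
    return GenomeAnnotation(genes, {"chr1": 100_000})


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study scale (300 genes,
    2e5 fragments/sample, 2 CUT&RUN replicates, 4-fold planted losses),
    shared across recovery tests."""
    return run_all(SimulationConfig(seed=1))
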