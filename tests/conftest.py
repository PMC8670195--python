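import pytest

from famforge.config import PipelineConfig
from famforge.pipeline import PipelineInputs, run_pipeline
from famforge.synthetic_data import SimulatedFamily, simulate_family

DEFAULT_SEED = 17


@pytest.fixture(scope="session")
def default_sim() -> SimulatedFamily:
    """The default synthetic scenario (8 OGs x 5 genes, 3 chromosomes)."""
    return simulate_family(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_cfg() -> PipelineConfig:
    # test-scale motif widths; everything else at production defaults
    return PipelineConfig(motif_wmax=20, rng_seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def pipeline_result(default_sim, default_cfg):
    inputs = PipelineInputs(
        annotation=default_sim.annotation,
        genome=default_sim.genome,
        refdb=default_sim.refdb,
        pwms=default_sim.pwms,
        wgd_blocks=default_sim.wgd_blocks,
        de_table=default_sim.de_table,
    )
    return run_pipeline(inputs, default_cfg)
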