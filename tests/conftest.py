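import pytest

from circedit.pipeline import RunConfig, run_pipeline
from circedit.synthetic import SimulationConfig, build_genome


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def built(default_cfg):
    """(genome, genes, repeats, variants, manifest) for the default design."""
    return build_genome(default_cfg)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory, default_cfg):
    """One full default pipeline run shared by downstream-module tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(RunConfig(outdir=str(outdir), simulation=default_cfg))
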