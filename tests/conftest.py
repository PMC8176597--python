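import pytest

from tetrace.pipeline import run_all
from tetrace.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full end-to-end run on the default study design, shared by every
    test that inspects pipeline outputs."""
    outdir = tmp_path_factory.mktemp("study")
    return run_all(SimulationConfig(seed=0), outdir)


@pytest.fixture(scope="session")
def deterministic_study(tmp_path_factory):
    """A noise-free simulation (counts = rounded expectations)."""
    from tetrace.synthetic import simulate

    cfg = SimulationConfig(seed=0, dispersion=None)
    return simulate(cfg, tmp_path_factory.mktemp("det_study"))
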