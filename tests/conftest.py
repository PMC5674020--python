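import warnings

import pytest

import passagemut as pm
from passagemut import workflow

warnings.filterwarnings("ignore", category=RuntimeWarning, message="Mean of empty slice")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default line-1 configuration (seed 0)."""
    workdir = tmp_path_factory.mktemp("line1")
    return workflow.run_line(pm.CultureConfig(rng_seed=0), workdir)


@pytest.fixture(scope="session")
def line2_truth():
    """Ground truth of the line-2 preset (earlier burst, CNA burst at P3)."""
    truth, records = pm.simulate_culture(pm.msc_line_preset(2))
    return truth


@pytest.fixture(scope="session")
def small_genome():
    return pm.GenomeModel(n_chromosomes=2, chromosome_length=1_000_000)
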