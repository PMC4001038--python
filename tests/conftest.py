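import pytest

from tnfit import synthetic_data as sd
from tnfit.cli import run_end_to_end
from tnfit.genome_annotation import Gene, GenomeAnnotation


@pytest.fixture(scope="session")
def nitrate_config():
    return sd.nitrate_scenario(seed=1)


@pytest.fixture(scope="session")
def nitrate_run(nitrate_config):
    """One full simulated study (all six conditions, both pipelines),
    shared across tests: the expensive fixture everything recovery-related
    reads from."""
    return run_end_to_end(nitrate_config)


@pytest.fixture
def toy_annotation():
    """Five genes, two operons, one on the minus strand."""
    genes = [
        Gene("gA", "chr1", 101, 700, "+", operon_id="op1"),
        Gene("gB", "chr1", 801, 1400, "+", operon_id="op1"),
        Gene("gC", "chr1", 1501, 2100, "-"),
        Gene("gD", "chr1", 2201, 2800, "-", operon_id="op2"),
        Gene("gE", "chr1", 2901, 3500, "-", operon_id="op2"),
    ]
    return GenomeAnnotation({"chr1": 4000}, genes)


@pytest.fixture
def small_config():
    """Small single-condition scenario for fast pipeline tests."""
    return sd.ScenarioConfig(
        seed=11,
        n_genes=60,
        n1=260,
        n2=260,
        overlap=80,
        strain_effect_sd=0.3,
        conditions={"stress": {"g0005": 2.5, "g0006": 3.0, "g0040": -1.0}, "ctrl": {}},
        doublings={"stress": 3.0, "ctrl": 3.0},
        sigma=0.2,
        background=0.0,
        tnle_sites=5000,
        tnle_reads=25000,
        tnle_condition="stress",
    )
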