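import io

import pytest

from wgdevolve import genome
from wgdevolve.io_formats import read_arm_definitions, uniform_codon_usage
from wgdevolve.synthetic import PatientConfig, simulate_patient


@pytest.fixture(scope="session")
def hg19_cytoband_text() -> str:
    """Minimal cytoBand file covering all hg19 chromosomes."""
    return "\n".join(genome.cytoband_lines()) + "\n"


@pytest.fixture(scope="session")
def hg19_arms(hg19_cytoband_text):
    return read_arm_definitions(io.StringIO(hg19_cytoband_text))


@pytest.fixture(scope="session")
def uniform_usage():
    return uniform_codon_usage()


@pytest.fixture(scope="session")
def noise_free_bundle():
    """One deterministic noise-free synthetic patient shared across tests."""
    return simulate_patient(PatientConfig().noise_free(), seed=20260919)
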