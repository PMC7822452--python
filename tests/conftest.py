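import pytest

from mitovir.seqcore import GeneticCode
from mitovir.synthetic_data import MITOVIRUS_PRESET, gen_viral_genome


@pytest.fixture(scope="session")
def code1():
    return GeneticCode.from_table_id(1)


@pytest.fixture(scope="session")
def code5():
    return GeneticCode.from_table_id(5)


@pytest.fixture(scope="session")
def mitovirus_genome():
    """The reference synthetic mitovirus genome used across the suite:
    2697 nt, one 804-codon ORF under the invertebrate mitochondrial code,
    ~69.74% AT, UGA-rich Trp usage."""
    return gen_viral_genome(seed=1, **MITOVIRUS_PRESET)
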