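import pytest

from damageclock.data import (
    copa_exon8_9_synthetic,
    family_pedigree,
    plb1_exon33_synthetic,
    sps_distribution,
)


@pytest.fixture(scope="session")
def sps_dist():
    return sps_distribution()


@pytest.fixture(scope="session")
def family():
    return family_pedigree()


@pytest.fixture(scope="session")
def plb1():
    return plb1_exon33_synthetic()


@pytest.fixture(scope="session")
def copa():
    return copa_exon8_9_synthetic()
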