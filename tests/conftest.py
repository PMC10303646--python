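import pytest

from primeraudit.fixtures import published_variant_table


@pytest.fixture(scope="session")
def its86f_table():
    return published_variant_table("ITS86F")


@pytest.fixture(scope="session")
def its4_table():
    return published_variant_table("ITS4")
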