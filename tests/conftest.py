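import pytest

from cleavescan import CALPAIN2, CASPASE3, table4_record


@pytest.fixture
def caspase3():
    return CASPASE3


@pytest.fixture
def calpain2():
    return CALPAIN2


@pytest.fixture(scope="session")
def table4():
    return table4_record()
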