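import pytest

from cpdi.standards import default_cpdi_standard


@pytest.fixture(scope="session")
def standard():
    return default_cpdi_standard()
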