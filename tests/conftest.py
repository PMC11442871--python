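import pytest

from screencea import load_default_parameters


@pytest.fixture()
def base_inputs():
    """Fresh copy of the shipped base-case inputs (mutable per test)."""
    return load_default_parameters()
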