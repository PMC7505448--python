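import pytest

from evlipid.lipid_library import build_default_library
from evlipid.synthetic_data import generate_lipidome


@pytest.fixture(scope="session")
def library():
    """Full default enumerated library (built once per session)."""
    return build_default_library()


@pytest.fixture(scope="session")
def paper_truth():
    """One paper-like ground-truth draw, fixed seed."""
    return generate_lipidome("paper-like", seed=11)
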