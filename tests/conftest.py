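import pytest
from hypothesis import settings

from trapmap import FixtureSpec, make_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: The seven sequon-bearing tryptic peptides of the reference peptide map,
#: with their printed chain coordinates and observed MH+ values.
TABLE1 = {
    "VTSPNITVTLK": (29, 39, 1173.58),
    "GFIISNATYK": (60, 69, 1114.83),
    "LVLNCTAR": (117, 124, 947.58),
    "NSTFVR": (193, 198, 724.50),
    "NGIPLESNHTIK": (242, 253, 1324.83),
    "DTGNYTVILTNPISK": (267, 281, 1637.99),
    "EEQYNSTYR": (372, 380, 1190.58),
}


@pytest.fixture(scope="session")
def paper_fixture():
    """The preset homodimer assembly (seed 1) used across the suite."""
    return make_fixture(FixtureSpec(seed=1))
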