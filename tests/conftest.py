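import warnings

import pytest
from hypothesis import settings

from pinpoint.fixtures import FixtureSpec, make_fixture
from pinpoint.guide_design import SpacerEdit
from pinpoint.target_scan import Protospacer, find_protospacers

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

GALK_WITH_PAM = "AGGCTGTAACTGCGGGATCA" + "TGG"


@pytest.fixture(scope="session")
def galk_target() -> Protospacer:
    """The printed galK protospacer as a standalone target (fixture PAM)."""
    (t,) = find_protospacers(GALK_WITH_PAM, "galK")
    return t


@pytest.fixture(scope="session")
def t504a() -> SpacerEdit:
    """The classic nonsense edit T504A: spacer index N7, T→A."""
    return SpacerEdit(k=7, ref_run="T", alt_run="A")


@pytest.fixture(scope="session")
def small_fixture():
    """A 4-gene synthetic fixture including the galK-like worked example."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixture(FixtureSpec(n_genes=4, gene_length=700, seed=11))
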