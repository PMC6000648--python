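import numpy as np
import pytest

from trnaevo.decoding import GeneticCode, ModificationRuleSet


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return GeneticCode.standard()


@pytest.fixture(scope="session")
def rules() -> ModificationRuleSet:
    return ModificationRuleSet.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


# --- tiny text fixtures, generated in-memory ------------------------------

TRNASCAN_3LINES = """\
Sequence\t\ttRNA\tBounds\t\ttRNA\tAnti\tIntron Bounds\tCove
Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore
--------\t------\t----\t------\t----\t-----\t-----\t----\t------
chr1\t1\t100\t171\tMet\tCAT\t0\t0\t78.8
chr1\t2\t300\t371\tLeu\tGAG\t0\t0\t70.1
chr1\t3\t600\t529\tIle\tGAT\t0\t0\t66.2
"""


@pytest.fixture()
def trnascan_file(tmp_path):
    p = tmp_path / "G900.tsv"
    p.write_text(TRNASCAN_3LINES)
    return p
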