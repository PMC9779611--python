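import pytest

from sialofold import fixtures, structmodel
from sialofold.seqdb import SequenceRecord


@pytest.fixture
def cys7_model():
    """Single chain, 7 cysteines, pairs (1,6)/(2,4)/(3,5) bonded at 2.05 Å."""
    text = fixtures.make_cys_structure(
        [(1, 6, 2.05), (2, 4, 2.05), (3, 5, 2.05)], n_cys=7, seed=0
    )
    return structmodel.parse_pdb_text(text, model_id="cys7")


@pytest.fixture
def homodimer_model():
    """Two identical chains bridged by their C7 cysteines."""
    text = fixtures.make_dimer_structure([(7, 7, 2.05)], n_cys=7, seed=0)
    return structmodel.parse_pdb_text(text, model_id="homodimer")


@pytest.fixture
def reciprocal_dimer_model():
    """Two chains with reciprocal A:1-B:8 and A:8-B:1 bridges."""
    text = fixtures.make_dimer_structure([(1, 8, 2.05), (8, 1, 2.05)], n_cys=8, seed=0)
    return structmodel.parse_pdb_text(text, model_id="reciprocal")


@pytest.fixture
def simple_records():
    return [
        SequenceRecord("r1", "MKVLAAGRGDAAKL"),
        SequenceRecord("r2", "MKVLAAGAAAAAKL"),
        SequenceRecord("r3", "AAAAAAAAAA"),
    ]
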