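import string
from pathlib import Path

import pytest
from hypothesis import strategies as st

from synbiokit import fixtures as fx
from synbiokit.records import Feature, GeneticRecord, Span

DATA = Path(__file__).parent / "data"


@pytest.fixture
def and_gate_record():
    return fx.make_and_gate_record(0)


@pytest.fixture
def and_gate_genbank():
    return fx.make_and_gate_genbank(0)


@pytest.fixture
def kazusa_text():
    return fx.make_kazusa_fixture()


@pytest.fixture
def demo_picklist():
    return fx.make_demo_picklist()


# ---------------------------------------------------------------------------
# hypothesis strategies for random-but-representable records

_FEATURE_KEYS = ["promoter", "RBS", "CDS", "terminator", "rep_origin", "misc_feature", "custom_key"]
_IDENT = st.text(alphabet=string.ascii_letters, min_size=1, max_size=10)
_QVALUE = st.text(alphabet=string.ascii_letters + string.digits + " _-", min_size=1, max_size=12)


@st.composite
def genetic_records(draw, max_len=120, max_features=6):
    n = draw(st.integers(min_value=10, max_value=max_len))
    seq = draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    n_feat = draw(st.integers(min_value=0, max_value=max_features))
    features = []
    for _ in range(n_feat):
        start = draw(st.integers(min_value=0, max_value=n - 1))
        end = draw(st.integers(min_value=start + 1, max_value=n))
        ftype = draw(st.sampled_from(_FEATURE_KEYS))
        strand = draw(st.sampled_from([1, -1]))
        quals = draw(
            st.dictionaries(_IDENT, st.lists(_QVALUE, min_size=1, max_size=2), max_size=2)
        )
        features.append(Feature(ftype, Span(start, end), strand, quals))
    rec_id = draw(st.text(alphabet=string.ascii_letters + string.digits, min_size=1, max_size=10))
    topology = draw(st.sampled_from(["linear", "circular"]))
    return GeneticRecord(id=rec_id, sequence=seq, topology=topology, features=features)
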