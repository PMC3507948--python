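import pytest

from gainscan.io_formats import Alignment, ProteinSequence


@pytest.fixture
def toy_alignment() -> Alignment:
    """Four members, one gap column, 6 columns."""
    return Alignment(
        [
            ProteinSequence("s1", "MKV-DE"),
            ProteinSequence("s2", "MKVADE"),
            ProteinSequence("s3", "MRVADE"),
            ProteinSequence("s4", "MRVADD"),
        ]
    )


@pytest.fixture
def two_clade_alignment() -> Alignment:
    """5+5 members; column 4 splits perfectly by clade, others invariant."""
    members = [ProteinSequence(f"A{i}", "AGDE") for i in range(1, 6)]
    members += [ProteinSequence(f"B{i}", "AGDK") for i in range(1, 6)]
    return Alignment(members)
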