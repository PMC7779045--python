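import pytest

from mitonet.msa import ProteinAlignment


def make_alignment(seqs, species=None, reference_index=0, name="MT-TEST"):
    """Build a small alignment; row 0 is human unless stated otherwise."""
    n = len(seqs)
    if species is None:
        species = ["Homo sapiens"] + [f"Species sp{i}" for i in range(1, n)]
    return ProteinAlignment(
        identifiers=tuple(f"rec{i}" for i in range(n)),
        species=tuple(species),
        sequences=tuple(seqs),
        reference_index=reference_index,
        name=name,
    )


@pytest.fixture
def toy_alignment():
    return make_alignment(
        [
            "MKLVA",
            "MKLVA",
            "MQLVA",
            "MKIVA",
        ]
    )
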