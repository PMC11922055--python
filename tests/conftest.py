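import pytest

import stallkit as sk


@pytest.fixture(scope="session")
def ref():
    """Default isodecoder reference: 26 Ser/Leu substrates, no decoys."""
    return sk.make_trna_reference(seed=1)


@pytest.fixture(scope="session")
def ref_with_decoys():
    return sk.make_trna_reference(seed=1, n_decoys=10)


@pytest.fixture(scope="session")
def txome():
    return sk.make_transcriptome(n_genes=30, seed=5)
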