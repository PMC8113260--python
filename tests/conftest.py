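import numpy as np
import pytest

from phosfold import BlockSpec, ProteinRecord, generate_protein
from phosfold.synthetic import RGG_LIKE_COMPOSITION, STRUCTURED_COMPOSITION


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def poly_g_ps():
    """21-mer poly-G with a central phospho-serine."""
    return ProteinRecord("PGS", "G" * 10 + "S" + "G" * 10, phospho_sites={11})


@pytest.fixture
def two_block_record():
    """Folded-like block followed by an RGG-like disordered block."""
    spec = BlockSpec(
        blocks=[(100, STRUCTURED_COMPOSITION), (150, RGG_LIKE_COMPOSITION)],
        phospho_density=0.2,
        seed=11,
    )
    return generate_protein(spec, record_id="TWOBLOCK")


def random_record(rng, min_len=25, max_len=120, site_rate=0.15):
    """Random canonical-sequence record with sites on random S/T/Y."""
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(alphabet, size=n))
    sites = {
        i + 1
        for i, aa in enumerate(seq)
        if aa in "STY" and rng.random() < site_rate
    }
    return ProteinRecord(f"R{n}", seq, phospho_sites=sites)
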