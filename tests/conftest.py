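import numpy as np
import pytest

from cdsevol.genetics import SENSE_CODONS
from cdsevol.seqio import CdsSet, CodingSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_cds(seq: str, gene_id: str = "g1", valid: bool = True) -> CodingSequence:
    return CodingSequence(id=gene_id, seq=seq, valid=valid)


def random_valid_cds(rng: np.random.Generator, n_codons: int, gene_id: str) -> CodingSequence:
    codons = rng.choice(SENSE_CODONS, size=n_codons)
    return CodingSequence(id=gene_id, seq="".join(codons))


@pytest.fixture
def random_gene_set(rng) -> CdsSet:
    genes = [random_valid_cds(rng, int(rng.integers(50, 200)), f"g{i}") for i in range(20)]
    return CdsSet(species="test", sequences=genes)
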