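import numpy as np
import pytest

from ssbdsb.seqio import ALPHABET, LabeledDataset, ProteinRecord
from ssbdsb.synthetic import GeneratorConfig, generate_dataset


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def random_record(rng: np.random.Generator, length: int, rid: str = "p") -> ProteinRecord:
    return ProteinRecord(id=rid, sequence=random_sequence(rng, length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset() -> LabeledDataset:
    """60 + 25 proteins with a strong composition signal, lengths 60-200."""
    return generate_dataset(
        GeneratorConfig(
            n_dsb=60, n_ssb=25, len_min=60, len_max=200, delta=0.2, seed=7
        )
    )


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">p1 some description\nACDC\n>p2\nAC\nDC\n")
    return path
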