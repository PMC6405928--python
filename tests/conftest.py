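import random
from pathlib import Path

import pytest

from premir.seqio import SequenceRecord

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


def random_dna(rng: random.Random, n: int, gc: float = 0.5) -> str:
    return "".join(
        (rng.choice("GC") if rng.random() < gc else rng.choice("AT"))
        for _ in range(n)
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)


@pytest.fixture
def small_genome(rng) -> list[SequenceRecord]:
    return [
        SequenceRecord("chr1", random_dna(rng, 3000)),
        SequenceRecord("chr2", random_dna(rng, 2000)),
    ]
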