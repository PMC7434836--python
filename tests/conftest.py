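import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from acpkit import GeneratorConfig, Peptide, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def random_peptides(rng):
    """50 random peptides of lengths 5-30 over the 20-letter alphabet."""
    from acpkit import ALPHABET

    peptides = []
    for i in range(50):
        length = int(rng.integers(5, 31))
        seq = "".join(ALPHABET[j] for j in rng.integers(0, 20, size=length))
        peptides.append(Peptide(id=f"r{i:02d}", sequence=seq))
    return peptides


@pytest.fixture
def small_dataset():
    """A small biased dataset, long enough for every default encoder."""
    return generate(GeneratorConfig(
        n_pos=20, n_neg=30, length_range=(10, 30), bias=2.0, seed=7,
    ))


def write_fasta_text(path: Path, records: list[tuple[str, str]]) -> Path:
    path.write_text("".join(f">{h}\n{s}\n" for h, s in records))
    return path
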