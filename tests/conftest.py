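import numpy as np
import pytest

from mitoatlas.genome_model import MitoGenome, Molecule

BASES = np.array(list("ACGT"))


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[codes])


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def make_genome(*mols: tuple[str, str, str]) -> MitoGenome:
    return MitoGenome([Molecule(n, s, t) for n, s, t in mols])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
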