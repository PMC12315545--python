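import numpy as np
import pytest

from peplearn.chem import builtin_library, sequence_to_molecule
from peplearn.fragment import learn_vocabulary
from peplearn.simulate import CorpusSpec, generate_corpus


@pytest.fixture(scope="session")
def lib():
    return builtin_library()


@pytest.fixture(scope="session")
def diglycine(lib):
    return sequence_to_molecule(["G", "G"], lib)


@pytest.fixture(scope="session")
def mixed_corpus(lib):
    """60 random peptides over the full monomer pool, lengths 2-12."""
    spec = CorpusSpec(
        n_molecules=60, min_length=2, max_length=12,
        monomer_pool=tuple(lib.codes()), seed=101,
    )
    return [m for _, _, m in generate_corpus(spec, lib)]


@pytest.fixture(scope="session")
def mixed_vocab(mixed_corpus):
    return learn_vocabulary(mixed_corpus, min_freq=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
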