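"""Fragmentation operators, vocabulary mining, OOV fallback, reassembly."""

import collections

import pytest
from rdkit import Chem

from peplearn.chem import canonical_key, molecule_from_smiles, sequence_to_molecule
from peplearn.errors import IntegrityError
from peplearn.fragment import (
    METHODS,
    Fragmentation,
    adafrag_fragment,
    amiibo_fragment,
    baseline_fragment,
    brics_split,
    count_fragment_keys,
    learn_vocabulary,
    reassemble,
)
from peplearn.simulate import CorpusSpec, generate_corpus


class TestAmiibo:
    def test_diglycine_split(self, diglycine):
        frag = amiibo_fragment(diglycine)
        assert sorted(len(f) for f in frag.fragments) == [4, 5]
        assert len(frag.cut_bonds) == 1
        # the amide C(=O)-N bond stays inside a fragment
        cut = {frozenset(p) for p, _ in frag.cut_bonds}
        assert not (cut & diglycine.amide_bonds())

    def test_single_glycine_uncut(self, lib):
        frag = amiibo_fragment(sequence_to_molecule(["G"], lib))
        assert frag.n_fragments == 1 and frag.cut_bonds == []

    @pytest.mark.parametrize("n", list(range(2, 11)))
    def test_fragment_count_equals_residue_count(self, lib, n, rng):
        """Proline-free linear canonical peptides split into one fragment per residue."""
        pool = [c for c in lib.codes(canonical=True) if c != "P"]
        seq = [pool[int(i)] for i in rng.integers(len(pool), size=n)]
        frag = amiibo_fragment(sequence_to_molecule(seq, lib))
        assert frag.n_fragments == n
        assert len(frag.cut_bonds) == n - 1

    def test_proline_merges_with_predecessor(self, lib):
        frag = amiibo_fragment(sequence_to_molecule(["A", "P", "G"], lib))
        assert frag.n_fragments == 2

    def test_never_cuts_amides_or_rings(self, mixed_corpus):
        for mol in mixed_corpus:
            frag = amiibo_fragment(mol)
            cut = {frozenset(p) for p, _ in frag.cut_bonds}
            assert not (cut & mol.amide_bonds())
            for i, j in (tuple(sorted(b)) for b in cut):
                assert not mol.mol.GetBondBetweenAtoms(i, j).IsInRing()


class TestBricsSplit:
    def test_benzyl_fragment_splits_with_ring_whole(self, lib):
        phe = sequence_to_molecule(["F"], lib)
        frag = amiibo_fragment(phe)
        assert frag.n_fragments == 1
        parts = brics_split(phe, frag.fragments[0])
        assert len(parts) >= 2
        ring = {a.GetIdx() for a in phe.mol.GetAtoms() if a.GetIsAromatic()}
        assert any(ring <= p for p in parts)

    def test_single_atom_identity(self, diglycine):
        assert brics_split(diglycine, [0]) == [frozenset({0})]

    def test_no_brics_bond_identity(self):
        eth = molecule_from_smiles("CC")
        assert brics_split(eth, [0, 1]) == [frozenset({0, 1})]

    def test_disconnected_subset_rejected(self, diglycine):
        with pytest.raises(ValueError):
            brics_split(diglycine, [0, 8])


class TestVocabulary:
    def test_frequencies_match_naive_counter(self, mixed_corpus):
        """Stored frequencies equal a brute-force per-molecule recount."""
        naive = collections.Counter()
        for mol in mixed_corpus:
            for atoms in amiibo_fragment(mol).fragments:
                naive[canonical_key(mol, atoms)] += 1
        vocab = learn_vocabulary(
            mixed_corpus, min_freq=1, max_fragment_atoms=10**6
        )
        for key, count in naive.items():
            assert vocab.entries[key][1] == count

    def test_repeated_corpus_counts(self, lib):
        corpus = [sequence_to_molecule(["G", "G"], lib) for _ in range(50)]
        vocab = learn_vocabulary(corpus, min_freq=2)
        freqs = {k: f for k, (_i, f) in vocab.entries.items() if f == 50}
        assert len(freqs) == 2  # both diglycine amiibo fragment keys

    def test_min_freq_excludes_everything(self, mixed_corpus):
        vocab = learn_vocabulary(mixed_corpus, min_freq=10**6)
        assert set(vocab.entries) == set(vocab.reserved_keys)

    def test_planted_motif_enters_vocabulary(self, lib):
        spec = CorpusSpec(
            n_molecules=40, min_length=3, max_length=8,
            monomer_pool=("G", "A", "S", "V"),
            planted_motif=("Nle", "Nle"), motif_fraction=0.5, seed=7,
        )
        corpus = [m for _, _, m in generate_corpus(spec, lib)]
        vocab = learn_vocabulary(corpus, min_freq=2)
        probe = sequence_to_molecule(["G", "Nle", "A"], lib)
        nle_key = canonical_key(probe, amiibo_fragment(probe).fragments[1])
        assert nle_key in vocab

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            learn_vocabulary([])

    def test_save_load_bit_exact(self, mixed_vocab, tmp_path):
        p = tmp_path / "vocab.json"
        mixed_vocab.save(p)
        loaded = type(mixed_vocab).load(p)
        assert loaded.entries == mixed_vocab.entries
        assert loaded.params == mixed_vocab.params


class TestAdafrag:
    def test_in_vocab_molecules_match_amiibo(self, mixed_corpus, mixed_vocab):
        vocab_all = learn_vocabulary(mixed_corpus, min_freq=1, max_fragment_atoms=10**6)
        mol = mixed_corpus[0]
        assert adafrag_fragment(mol, vocab_all).fragments == amiibo_fragment(mol).fragments

    def test_oov_fragment_is_brics_split(self, lib, mixed_corpus):
        """A residue never seen in vocabulary mining gets decomposed."""
        vocab = learn_vocabulary(
            [m for m in mixed_corpus], min_freq=10**6  # reserved-only vocabulary
        )
        mol = sequence_to_molecule(["F", "F"], lib)
        frag = adafrag_fragment(mol, vocab)
        assert frag.n_fragments > amiibo_fragment(mol).n_fragments
        for atoms, key in zip(frag.fragments, frag.fragment_keys):
            assert key in vocab or len(atoms) == 1

    def test_deterministic(self, mixed_corpus, mixed_vocab):
        for mol in mixed_corpus[:5]:
            a = adafrag_fragment(mol, mixed_vocab)
            b = adafrag_fragment(mol, mixed_vocab)
            assert a.fragments == b.fragments and a.cut_bonds == b.cut_bonds


class TestBaselines:
    def test_atoms_only_diglycine(self, diglycine):
        frag = baseline_fragment(diglycine, "atoms_only")
        assert frag.n_fragments == 9 and len(frag.cut_bonds) == 8

    def test_principal_subgraph_requires_vocab(self, diglycine):
        with pytest.raises(ValueError):
            baseline_fragment(diglycine, "principal_subgraph")

    def test_principal_subgraph_can_cut_amides(self, lib):
        """Without amide protection, the data-driven baseline cuts C(=O)-N bonds."""
        corpus = [sequence_to_molecule(["G", "G"], lib) for _ in range(20)]
        vocab = learn_vocabulary(corpus, min_freq=2, amiibo_first=False)
        frag = baseline_fragment(corpus[0], "principal_subgraph", vocab)
        cut = {frozenset(p) for p, _ in frag.cut_bonds}
        assert cut & corpus[0].amide_bonds()


class TestReassembly:
    @pytest.mark.parametrize("method", METHODS)
    def test_round_trip_all_methods(self, mixed_corpus, mixed_vocab, method):
        psub_vocab = learn_vocabulary(
            mixed_corpus[:20], min_freq=2, amiibo_first=False
        )
        for mol in mixed_corpus[:15]:
            if method == "amiibo":
                frag = amiibo_fragment(mol)
            elif method == "adafrag":
                frag = adafrag_fragment(mol, mixed_vocab)
            elif method == "atoms_only":
                frag = baseline_fragment(mol, "atoms_only")
            else:
                frag = baseline_fragment(mol, "principal_subgraph", psub_vocab)
            frag.validate(mol)
            assert canonical_key(reassemble(mol, frag)) == canonical_key(mol)

    def test_bad_cut_bond_index_rejected(self, diglycine):
        frag = amiibo_fragment(diglycine)
        broken = Fragmentation(
            fragments=frag.fragments,
            cut_bonds=[((4, 99), "SINGLE")],
            fragment_keys=frag.fragment_keys,
            method="amiibo",
        )
        with pytest.raises(IntegrityError):
            reassemble(diglycine, broken)
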