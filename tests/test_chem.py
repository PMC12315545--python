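"""Monomer chemistry: library IO, condensation, tokenization, canonical keys."""

import pytest
from rdkit import Chem

from peplearn.chem import (
    Monomer,
    builtin_library,
    canonical_key,
    load_monomer_library,
    molecule_from_smiles,
    read_structures,
    sequence_to_molecule,
    tokenize_sequence,
    write_structures,
)
from peplearn.errors import ChemistryError, LibraryError, UnknownMonomerError
from peplearn.simulate import CorpusSpec, generate_corpus


class TestMonomerLibrary:
    def test_builtin_covers_canonical_twenty(self, lib):
        canonical = set("ARNDCEQGHILKMFPSTWYV")
        assert canonical <= set(lib.codes(canonical=True))
        assert len(lib.codes(canonical=False)) >= 5

    def test_load_tsv_round(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "code\tsmiles\tis_canonical\tside_chain_atoms\n"
            "G\t[*:1]NCC(=O)[*:2]\ttrue\t\n"
        )
        loaded = load_monomer_library(p)
        assert loaded["G"].is_canonical and loaded["G"].n_heavy_atoms == 5

    def test_duplicate_code_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "code\tsmiles\tis_canonical\tside_chain_atoms\n"
            "A\t[*:1]N[C@@H](C)C(=O)[*:2]\ttrue\t\n"
            "A\t[*:1]N[C@@H](C)C(=O)[*:2]\ttrue\t\n"
        )
        with pytest.raises(LibraryError, match="duplicate"):
            load_monomer_library(p)

    def test_invalid_smiles_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "code\tsmiles\tis_canonical\tside_chain_atoms\nX\tC(C\ttrue\t\n"
        )
        with pytest.raises(ChemistryError, match="X"):
            load_monomer_library(p)

    def test_monomer_needs_attachment_points(self):
        with pytest.raises(ChemistryError, match="attachment"):
            Monomer(code="bad", smiles="NCC(=O)O", is_canonical=True)


class TestCondensation:
    def test_single_glycine_is_free_amino_acid(self, lib):
        mol = sequence_to_molecule(["G"], lib)
        assert mol.canonical_smiles == Chem.CanonSmiles("NCC(=O)O")

    def test_diglycine_atoms_bonds_and_amide(self, diglycine):
        # H2N-CH2-C(=O)-NH-CH2-COOH: 9 heavy atoms, 8 bonds, 1 backbone amide
        assert diglycine.n_atoms == 9
        assert diglycine.n_bonds == 8
        inter = {
            b for b in diglycine.amide_bonds()
            if len({diglycine.residue_of_atom[a] for a in b}) == 2
        }
        assert len(inter) == 1

    def test_unknown_code_raises(self, lib):
        with pytest.raises(UnknownMonomerError):
            sequence_to_molecule(["G", "X?"], lib)

    def test_empty_sequence_raises(self, lib):
        with pytest.raises(ValueError):
            sequence_to_molecule([], lib)

    @pytest.mark.parametrize("n", [2, 4, 7, 10])
    def test_amide_count_law(self, lib, n, rng):
        """n-residue proline-free linear canonical peptides: n-1 inter-residue amides."""
        pool = [c for c in lib.codes(canonical=True) if c != "P"]
        seq = [pool[int(i)] for i in rng.integers(len(pool), size=n)]
        mol = sequence_to_molecule(seq, lib)
        inter = {
            b for b in mol.amide_bonds()
            if len({mol.residue_of_atom[a] for a in b}) == 2
        }
        assert len(inter) == n - 1

    def test_atom_conservation(self, lib, rng):
        """Heavy atoms = sum of monomer heavy atoms - (n-1) lost hydroxyls."""
        codes = list(lib.codes())
        for _ in range(10):
            n = int(rng.integers(2, 9))
            seq = [codes[int(i)] for i in rng.integers(len(codes), size=n)]
            mol = sequence_to_molecule(seq, lib)
            assert mol.n_atoms == sum(lib[c].n_heavy_atoms for c in seq) - (n - 1)

    def test_d_and_l_alanine_keys_differ(self, lib):
        l_form = sequence_to_molecule(["A", "G"], lib)
        d_form = sequence_to_molecule(["dA", "G"], lib)
        assert canonical_key(l_form) != canonical_key(d_form)

    def test_head_to_tail_cyclization(self, lib):
        cyc = sequence_to_molecule(["G", "A", "G", "A"], lib, cyclic=True)
        lin = sequence_to_molecule(["G", "A", "G", "A"], lib)
        assert cyc.n_atoms == lin.n_atoms - 1  # loses the terminal hydroxyl
        assert cyc.n_bonds == cyc.n_atoms  # single macrocycle


class TestReadWrite:
    def test_smiles_lines(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("NCC(=O)O\nNC(C)C(=O)O\n")
        mols = read_structures(p, "smiles_lines")
        assert [m.n_atoms for m in mols] == [5, 6]

    def test_fasta_matches_sequence_construction(self, tmp_path, lib):
        p = tmp_path / "in.fasta"
        p.write_text(">p1\nGA\n")
        (mol,) = read_structures(p, "fasta", lib=lib)
        assert mol.mol_id == "p1"
        assert canonical_key(mol) == canonical_key(sequence_to_molecule(["G", "A"], lib))

    def test_bracketed_codes(self, tmp_path, lib):
        p = tmp_path / "in.txt"
        p.write_text("G[Aib]G\n")
        (mol,) = read_structures(p, "sequence_lines", lib=lib)
        assert max(mol.residue_of_atom.values()) == 2

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.smi"
        p.write_text("")
        assert read_structures(p, "smiles_lines") == []

    def test_bad_record_names_index(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("NCC(=O)O\nC(C\n")
        with pytest.raises(ChemistryError, match="record 1"):
            read_structures(p, "smiles_lines")

    def test_write_read_round_trip(self, tmp_path, lib, mixed_corpus):
        p = tmp_path / "out.smi"
        write_structures(mixed_corpus, p)
        back = read_structures(p, "smiles_lines")
        assert [canonical_key(m) for m in back] == [canonical_key(m) for m in mixed_corpus]


class TestTokenizer:
    def test_plain_and_bracketed(self):
        assert tokenize_sequence("G[Aib]G") == ["G", "Aib", "G"]
        assert tokenize_sequence("GA") == ["G", "A"]

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            tokenize_sequence("G-[A")


class TestCanonicalKey:
    def test_smiles_writing_order_irrelevant(self):
        a = molecule_from_smiles("OC(=O)CN")
        b = molecule_from_smiles("NCC(O)=O")
        assert canonical_key(a) == canonical_key(b)

    def test_subset_order_irrelevant(self, diglycine):
        sub = [0, 1, 2, 3]
        assert canonical_key(diglycine, sub) == canonical_key(diglycine, reversed(sub))

    def test_methyl_fragment_caps_to_methane(self, lib):
        ala = sequence_to_molecule(["A"], lib)
        methyl = [
            a.GetIdx() for a in ala.mol.GetAtoms()
            if a.GetSymbol() == "C" and a.GetTotalNumHs() == 3
        ]
        assert canonical_key(ala, methyl) == Chem.CanonSmiles("C")
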