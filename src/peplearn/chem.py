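"""Monomer chemistry: building peptide molecules from residue sequences.

A :class:`Monomer` is an amino-acid building block written as SMILES with
two attachment points marked by dummy atoms: map number 1 on the amine
(N-terminal) side and map number 2 on the carboxyl (C-terminal) side.
Capping monomers carry a single attachment point.  A peptide is assembled
by amide-bond condensation: the carboxyl carbon of residue *i* is bonded
to the amine nitrogen of residue *i+1* and one hydroxyl is lost per bond
formed.  Hydrogens are implicit throughout; only heavy atoms are graph
nodes.  D-amino acids are carried as atom chirality tags and survive
canonicalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import ChemistryError, LibraryError, UnknownMonomerError

RDLogger.DisableLog("rdApp.*")

AMINE_MAP = 1
CARBOXYL_MAP = 2

_AMIDE_SMARTS = Chem.MolFromSmarts("[CX3](=O)[NX3]")


@dataclass(frozen=True)
class Monomer:
    """An amino-acid building block with attachment chemistry.

    ``smiles`` uses dummy atoms ``[*:1]`` (amine side) and ``[*:2]``
    (carboxyl side); capping monomers have exactly one of the two.
    """

    code: str
    smiles: str
    is_canonical: bool
    side_chain_atoms: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ChemistryError(f"monomer {self.code!r}: invalid SMILES {self.smiles!r}")
        amine, carboxyl = _attachment_indices(mol)
        n_attach = (amine is not None) + (carboxyl is not None)
        if n_attach == 0:
            raise ChemistryError(
                f"monomer {self.code!r}: no attachment points (need [*:1]/[*:2])"
            )

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)

    @property
    def is_capping(self) -> bool:
        amine, carboxyl = _attachment_indices(self.mol)
        return amine is None or carboxyl is None

    @property
    def n_heavy_atoms(self) -> int:
        """Heavy atoms of the free (capped) monomer: dummies replaced by H/OH."""
        mol = self.mol
        n_dummy = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
        amine, carboxyl = _attachment_indices(mol)
        # amine dummy -> H (not heavy); carboxyl dummy -> hydroxyl O (heavy)
        return mol.GetNumAtoms() - n_dummy + (1 if carboxyl is not None else 0)


def _attachment_indices(mol: Chem.Mol) -> tuple[int | None, int | None]:
    amine = carboxyl = None
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            if atom.GetAtomMapNum() == AMINE_MAP:
                amine = atom.GetIdx()
            elif atom.GetAtomMapNum() == CARBOXYL_MAP:
                carboxyl = atom.GetIdx()
    return amine, carboxyl


@dataclass
class MonomerLibrary:
    """Code-indexed collection of monomers (canonical + non-canonical)."""

    monomers: dict[str, Monomer]
    provenance: str = ""

    def __getitem__(self, code: str) -> Monomer:
        try:
            return self.monomers[code]
        except KeyError:
            raise UnknownMonomerError(f"unknown monomer code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.monomers

    def __len__(self) -> int:
        return len(self.monomers)

    def codes(self, canonical: bool | None = None) -> list[str]:
        return [
            c
            for c, m in self.monomers.items()
            if canonical is None or m.is_canonical == canonical
        ]


def load_monomer_library(path: str | Path) -> MonomerLibrary:
    """Read a monomer TSV (columns: code, smiles, is_canonical, side_chain_atoms).

    ``side_chain_atoms`` is a semicolon-separated list of within-monomer atom
    indices and may be empty.  Raises :class:`LibraryError` on malformed rows
    or duplicate codes, :class:`ChemistryError` on invalid SMILES.
    """
    path = Path(path)
    monomers: dict[str, Monomer] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["code", "smiles", "is_canonical", "side_chain_atoms"]
        if header != expected:
            raise LibraryError(f"{path}: header must be {expected!r}, got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) == 3:  # empty trailing side_chain_atoms column
                cols.append("")
            if len(cols) != 4:
                raise LibraryError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            code, smiles, canon, side = cols
            if code in monomers:
                raise LibraryError(f"{path}:{lineno}: duplicate monomer code {code!r}")
            if canon.lower() not in {"true", "false"}:
                raise LibraryError(f"{path}:{lineno}: is_canonical must be true/false")
            side_idx = frozenset(int(t) for t in side.split(";") if t)
            monomers[code] = Monomer(
                code=code,
                smiles=smiles,
                is_canonical=canon.lower() == "true",
                side_chain_atoms=side_idx,
            )
    return MonomerLibrary(monomers=monomers, provenance=str(path))


def builtin_library() -> MonomerLibrary:
    """The packaged library: 20 canonical amino acids + a non-canonical set
    (D-Ala, D-Phe, sarcosine, N-methyl-Phe, Aib, homoserine, norleucine)."""
    ref = resources.files("peplearn.data").joinpath("monomers.tsv")
    with resources.as_file(ref) as p:
        lib = load_monomer_library(p)
    lib.provenance = "peplearn built-in"
    return lib


@dataclass
class PeptideMolecule:
    """A 2D heavy-atom molecular graph, optionally with residue provenance.

    Wraps an RDKit molecule; ``residue_of_atom`` maps atom index to residue
    ordinal when the molecule was built from a sequence.
    """

    mol: Chem.Mol
    residue_of_atom: dict[int, int] | None = None
    source: str = "smiles"
    mol_id: str = ""

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def n_bonds(self) -> int:
        return self.mol.GetNumBonds()

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def bonds(self) -> list[tuple[int, int]]:
        return [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in self.mol.GetBonds()]

    def neighbors(self, idx: int) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtomWithIdx(idx).GetNeighbors()]

    def amide_bonds(self) -> set[frozenset[int]]:
        """Index pairs of amide C(=O)-N bonds (backbone and side chain)."""
        out: set[frozenset[int]] = set()
        for match in self.mol.GetSubstructMatches(_AMIDE_SMARTS):
            c, _o, n = match
            out.add(frozenset((c, n)))
        return out


TOKEN_RE = re.compile(r"\[([^\[\]]+)\]|([A-Za-z])")


def tokenize_sequence(seq: str) -> list[str]:
    """Split ``"G[Aib]G"`` into monomer codes ``["G", "Aib", "G"]``."""
    tokens: list[str] = []
    pos = 0
    for m in TOKEN_RE.finditer(seq):
        if m.start() != pos:
            raise ValueError(f"cannot tokenize sequence {seq!r} at position {pos}")
        tokens.append(m.group(1) or m.group(2))
        pos = m.end()
    if pos != len(seq):
        raise ValueError(f"cannot tokenize sequence {seq!r} at position {pos}")
    return tokens


def sequence_to_molecule(
    seq: Sequence[str] | str,
    lib: MonomerLibrary,
    cyclic: bool = False,
    mol_id: str = "",
) -> PeptideMolecule:
    """Condense a monomer-code sequence into a peptide molecule.

    Monomers are joined N-to-C: the carboxyl carbon of residue *i* is bonded
    to the amine nitrogen of residue *i+1*, losing the hydroxyl.  With
    ``cyclic=True`` the terminal carboxyl condenses onto the first residue's
    amine (head-to-tail macrocycle) instead of being capped.
    """
    codes = tokenize_sequence(seq) if isinstance(seq, str) else list(seq)
    if not codes:
        raise ValueError("empty sequence")
    monomers = [lib[c] for c in codes]
    for m in monomers[1:-1]:
        if m.is_capping:
            raise ChemistryError(f"capping monomer {m.code!r} used mid-sequence")

    combined = Chem.RWMol()
    dummies: list[tuple[int | None, int | None]] = []
    for i, monomer in enumerate(monomers):
        mol = monomer.mol
        amine, carboxyl = _attachment_indices(mol)
        offset = combined.GetNumAtoms()
        for atom in mol.GetAtoms():
            new = Chem.Atom(atom.GetAtomicNum())
            new.SetFormalCharge(atom.GetFormalCharge())
            new.SetChiralTag(atom.GetChiralTag())
            new.SetIsAromatic(atom.GetIsAromatic())
            new.SetNumExplicitHs(atom.GetNumExplicitHs())
            new.SetIntProp("resid", i)
            combined.AddAtom(new)
        for bond in mol.GetBonds():
            combined.AddBond(
                bond.GetBeginAtomIdx() + offset,
                bond.GetEndAtomIdx() + offset,
                bond.GetBondType(),
            )
        dummies.append(
            (
                amine + offset if amine is not None else None,
                carboxyl + offset if carboxyl is not None else None,
            )
        )

    def anchor(dummy_idx: int) -> int:
        nbrs = combined.GetAtomWithIdx(dummy_idx).GetNeighbors()
        return nbrs[0].GetIdx()

    n = len(monomers)
    for i in range(n - 1):
        c_dummy, n_dummy = dummies[i][1], dummies[i + 1][0]
        if c_dummy is None or n_dummy is None:
            raise ChemistryError(
                f"cannot condense {codes[i]!r}->{codes[i + 1]!r}: missing attachment"
            )
        combined.AddBond(anchor(c_dummy), anchor(n_dummy), Chem.BondType.SINGLE)

    to_remove: list[int] = []
    head_amine, tail_carboxyl = dummies[0][0], dummies[-1][1]
    if cyclic:
        if n < 2:
            raise ChemistryError("head-to-tail cyclization needs >= 2 residues")
        if head_amine is None or tail_carboxyl is None:
            raise ChemistryError("cyclization requires free amine and carboxyl termini")
        combined.AddBond(anchor(tail_carboxyl), anchor(head_amine), Chem.BondType.SINGLE)
        to_remove += [head_amine, tail_carboxyl]
    else:
        # N-terminal dummy becomes an implicit hydrogen; C-terminal dummy
        # becomes the free-acid hydroxyl oxygen.
        if head_amine is not None:
            to_remove.append(head_amine)
        if tail_carboxyl is not None:
            atom = combined.GetAtomWithIdx(tail_carboxyl)
            atom.SetAtomicNum(8)
            atom.SetAtomMapNum(0)
            atom.SetIntProp("resid", n - 1)
    for i in range(1, n):
        if dummies[i][0] is not None:
            to_remove.append(dummies[i][0])
    for i in range(n - 1):
        if dummies[i][1] is not None:
            to_remove.append(dummies[i][1])
    for idx in sorted(set(to_remove), reverse=True):
        combined.RemoveAtom(idx)

    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - defensive
        raise ChemistryError(f"condensation of {codes!r} failed sanitization: {exc}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    residue_of_atom = {a.GetIdx(): a.GetIntProp("resid") for a in mol.GetAtoms()}
    return PeptideMolecule(
        mol=mol, residue_of_atom=residue_of_atom, source="sequence", mol_id=mol_id
    )


def molecule_from_smiles(smiles: str, mol_id: str = "") -> PeptideMolecule:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"invalid SMILES {smiles!r}")
    return PeptideMolecule(mol=mol, source="smiles", mol_id=mol_id)


def read_structures(
    path: str | Path,
    format: str = "smiles_lines",
    lib: MonomerLibrary | None = None,
) -> list[PeptideMolecule]:
    """Read molecules from ``smiles_lines``, ``fasta`` or ``sequence_lines`` files.

    FASTA and sequence formats require a monomer library; bracketed tokens in
    sequences denote multi-character monomer codes.  An empty file yields an
    empty list.  Errors name the offending record index.
    """
    path = Path(path)
    if format not in {"smiles_lines", "fasta", "sequence_lines"}:
        raise ValueError(f"unknown format {format!r}")
    if format in {"fasta", "sequence_lines"} and lib is None:
        raise ValueError(f"format {format!r} requires a monomer library")

    records: list[tuple[str, str]] = []  # (id, payload)
    text = path.read_text()
    if format == "fasta":
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            records.append((rec.id, str(rec.seq)))
    else:
        idx = 0
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            payload = parts[0]
            rec_id = parts[1] if len(parts) > 1 else f"rec{idx}"
            records.append((rec_id, payload))
            idx += 1

    out: list[PeptideMolecule] = []
    for i, (rec_id, payload) in enumerate(records):
        try:
            if format == "smiles_lines":
                out.append(molecule_from_smiles(payload, mol_id=rec_id))
            else:
                out.append(sequence_to_molecule(payload, lib, mol_id=rec_id))
        except Exception as exc:
            raise ChemistryError(f"record {i} ({rec_id!r}): {exc}") from exc
    return out


def write_structures(mols: Iterable[PeptideMolecule], path: str | Path) -> None:
    """Write canonical SMILES, one per line, with the molecule id."""
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.canonical_smiles}\t{m.mol_id}\n" if m.mol_id else f"{m.canonical_smiles}\n")


def canonical_key(
    mol: PeptideMolecule | Chem.Mol, atom_indices: Iterable[int] | None = None
) -> str:
    """Canonical SMILES key of a molecule or induced heavy-atom subgraph.

    Cut bonds are capped with implicit hydrogens.  Isomorphic (sub)structures
    map to equal keys and the result is deterministic across runs.  For
    subsets the parent is kekulized first, so a subset that slices through an
    aromatic ring keys by its kekulized bond orders; subsets containing whole
    rings re-aromatize and key identically regardless of kekulization phase.
    """
    rdmol = mol.mol if isinstance(mol, PeptideMolecule) else mol
    if atom_indices is None:
        return Chem.MolToSmiles(rdmol)
    subset = sorted(set(atom_indices))
    if not subset:
        raise ValueError("empty atom subset")
    if max(subset) >= rdmol.GetNumAtoms() or min(subset) < 0:
        raise ValueError("atom index out of range")
    work = Chem.RWMol(rdmol)
    Chem.Kekulize(work, clearAromaticFlags=True)
    keep = set(subset)
    for idx in range(rdmol.GetNumAtoms() - 1, -1, -1):
        if idx not in keep:
            work.RemoveAtom(idx)
    sub = work.GetMol()
    for atom in sub.GetAtoms():
        atom.SetAtomMapNum(0)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
    try:
        Chem.SanitizeMol(sub)
    except Exception as exc:
        raise ChemistryError(f"capped subgraph is not sanitizable: {exc}") from exc
    Chem.AssignStereochemistry(sub, cleanIt=True, force=True)
    return Chem.MolToSmiles(sub)
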