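"""Peptide fragmentation operators and fragment vocabularies.

Two operators drive the package:

* **amiibo** — a domain-knowledge operator that cuts only acyclic single
  N–Cα bonds whose nitrogen sits in an amide group, so the amide C(=O)–N
  linkage itself is never broken and every ring stays intact.  A
  proline-free linear peptide of *n* residues yields exactly *n*
  fragments; proline's N–Cα bond is in the pyrrolidine ring, so Pro merges
  with the preceding fragment.
* **adafrag** — a data-driven refinement: amiibo fragments whose canonical
  key is missing from a learned vocabulary (or that exceed the size cap)
  are recursively split along BRICS bonds, and irreducible out-of-vocabulary
  remainders fall back to single atoms, whose per-element keys are always
  reserved in the vocabulary.  Encoding is therefore total.

Two baselines bracket the granularity spectrum: ``atoms_only`` (every atom
its own fragment) and ``principal_subgraph`` (BRICS over the whole molecule
plus frequency mining, with no amide protection).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import BRICS

from .chem import PeptideMolecule, canonical_key
from .errors import EncodingError, IntegrityError

METHODS = ("amiibo", "adafrag", "atoms_only", "principal_subgraph")

# Element alphabet shared with the heterograph featurizer.  "*" is the
# reserved key for elements outside the alphabet.
ELEMENT_ALPHABET = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Se")
OTHER_ELEMENT_KEY = "*"


def _single_atom_key(symbol: str) -> str:
    """Canonical key of a lone H-capped atom of the given element."""
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom(symbol))
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToSmiles(m)


_RESERVED_KEYS: list[str] = [_single_atom_key(s) for s in ELEMENT_ALPHABET] + [
    OTHER_ELEMENT_KEY
]


@dataclass
class Fragmentation:
    """An exact partition of a molecule's heavy atoms into connected fragments.

    ``cut_bonds`` lists every inter-fragment bond once, with its original
    bond order; ``fragment_keys`` are canonical SMILES of the H-capped
    induced subgraphs, aligned with ``fragments``.
    """

    fragments: list[frozenset[int]]
    cut_bonds: list[tuple[tuple[int, int], str]]
    fragment_keys: list[str]
    method: str

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def fragment_of_atom(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for fi, atoms in enumerate(self.fragments):
            for a in atoms:
                out[a] = fi
        return out

    def validate(self, mol: PeptideMolecule) -> None:
        """Check the partition law and cut-bond completeness against *mol*."""
        seen: set[int] = set()
        for atoms in self.fragments:
            if seen & atoms:
                raise IntegrityError("fragments overlap")
            seen |= atoms
        if seen != set(range(mol.n_atoms)):
            raise IntegrityError("fragments do not cover all heavy atoms")
        fof = self.fragment_of_atom()
        cut_pairs = {frozenset(p) for p, _ in self.cut_bonds}
        if len(cut_pairs) != len(self.cut_bonds):
            raise IntegrityError("duplicate cut bonds")
        inter = {
            frozenset((i, j)) for i, j in mol.bonds() if fof[i] != fof[j]
        }
        if cut_pairs != inter:
            raise IntegrityError("cut_bonds do not match inter-fragment bonds")
        for atoms in self.fragments:
            if not _is_connected(mol, atoms):
                raise IntegrityError("fragment induces a disconnected subgraph")


def _is_connected(mol: PeptideMolecule, atoms: frozenset[int]) -> bool:
    atoms = set(atoms)
    if not atoms:
        return False
    stack = [next(iter(atoms))]
    seen = {stack[0]}
    while stack:
        a = stack.pop()
        for nb in mol.neighbors(a):
            if nb in atoms and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == atoms


def _components(mol: PeptideMolecule, atoms: set[int], forbidden: set[frozenset[int]]) -> list[frozenset[int]]:
    """Connected components of the subgraph on *atoms* after removing *forbidden* bonds."""
    remaining = set(atoms)
    comps: list[frozenset[int]] = []
    while remaining:
        start = min(remaining)
        comp = {start}
        stack = [start]
        while stack:
            a = stack.pop()
            for nb in mol.neighbors(a):
                if nb in remaining and nb not in comp and frozenset((a, nb)) not in forbidden:
                    comp.add(nb)
                    stack.append(nb)
        comps.append(frozenset(comp))
        remaining -= comp
    return comps


def _bond_order(mol: PeptideMolecule, i: int, j: int) -> str:
    bond = mol.mol.GetBondBetweenAtoms(i, j)
    return str(bond.GetBondType())


def _finalize(mol: PeptideMolecule, fragments: list[frozenset[int]], method: str) -> Fragmentation:
    fragments = sorted(fragments, key=min)
    fof: dict[int, int] = {}
    for fi, atoms in enumerate(fragments):
        for a in atoms:
            fof[a] = fi
    cut_bonds = [
        ((i, j), _bond_order(mol, i, j))
        for i, j in mol.bonds()
        if fof[i] != fof[j]
    ]
    keys = [canonical_key(mol, atoms) for atoms in fragments]
    return Fragmentation(fragments=fragments, cut_bonds=cut_bonds, fragment_keys=keys, method=method)


def amiibo_cut_bonds(mol: PeptideMolecule) -> set[frozenset[int]]:
    """Acyclic single N–Cα bonds whose nitrogen belongs to an amide group."""
    cuts: set[frozenset[int]] = set()
    rdmol = mol.mol
    for bond in rdmol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        for n_atom, c_atom in ((a, b), (b, a)):
            if n_atom.GetSymbol() != "N" or c_atom.GetSymbol() != "C":
                continue
            if _is_carbonyl_carbon(c_atom):
                continue  # never cut the amide C(=O)-N itself
            if _is_amide_nitrogen(n_atom):
                cuts.add(frozenset((n_atom.GetIdx(), c_atom.GetIdx())))
    return cuts


def _is_carbonyl_carbon(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "C":
        return False
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetSymbol() == "O" and bond.GetBondType() == Chem.BondType.DOUBLE:
            return True
    return False


def _is_amide_nitrogen(atom: Chem.Atom) -> bool:
    for nb in atom.GetNeighbors():
        bond = atom.GetOwningMol().GetBondBetweenAtoms(atom.GetIdx(), nb.GetIdx())
        if bond.GetBondType() == Chem.BondType.SINGLE and _is_carbonyl_carbon(nb):
            return True
    return False


def amiibo_fragment(mol: PeptideMolecule) -> Fragmentation:
    """Domain-knowledge fragmentation preserving amide-bond integrity."""
    cuts = amiibo_cut_bonds(mol)
    comps = _components(mol, set(range(mol.n_atoms)), cuts)
    return _finalize(mol, comps, "amiibo")


def brics_split(mol: PeptideMolecule, atom_subset: Iterable[int]) -> list[frozenset[int]]:
    """Cut all BRICS-rule bonds internal to a connected atom subset.

    Returns the resulting components; if no BRICS bond lies inside the
    subset the subset itself is returned as a singleton list.  Ring bonds
    are never BRICS-cleavable, so rings stay whole.
    """
    subset = frozenset(atom_subset)
    if not _is_connected(mol, subset):
        raise ValueError("atom_subset must induce a connected subgraph")
    internal = {
        frozenset(pair)
        for pair, _labels in BRICS.FindBRICSBonds(mol.mol)
        if pair[0] in subset and pair[1] in subset
    }
    if not internal:
        return [subset]
    return _components(mol, set(subset), internal)


@dataclass
class FragmentVocabulary:
    """Corpus-derived map from canonical fragment keys to dense integer ids.

    Ids ``0..E-1`` are reserved for per-element single-atom keys (plus the
    "*" other-element key), which guarantees that any molecule can be
    encoded by falling back to single atoms.  Non-reserved entries carry
    their exact corpus frequency.
    """

    entries: dict[str, tuple[int, int]]  # key -> (id, freq)
    params: dict = field(default_factory=dict)

    @property
    def reserved_keys(self) -> list[str]:
        return list(_RESERVED_KEYS)

    @property
    def size(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def id_of(self, key: str) -> int:
        try:
            return self.entries[key][0]
        except KeyError:
            raise EncodingError(f"fragment key {key!r} not in vocabulary") from None

    def single_atom_id(self, symbol: str) -> int:
        key = _single_atom_key(symbol) if symbol in ELEMENT_ALPHABET else OTHER_ELEMENT_KEY
        return self.entries[key][0]

    def save(self, path: str | Path) -> None:
        blob = {
            "entries": {k: {"id": i, "freq": f} for k, (i, f) in self.entries.items()},
            "params": self.params,
        }
        Path(path).write_text(json.dumps(blob, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "FragmentVocabulary":
        blob = json.loads(Path(path).read_text())
        entries = {k: (v["id"], v["freq"]) for k, v in blob["entries"].items()}
        return cls(entries=entries, params=blob.get("params", {}))


def _mining_fragments(
    mol: PeptideMolecule, max_fragment_atoms: int, amiibo_first: bool
) -> list[frozenset[int]]:
    """Fragments counted during vocabulary learning.

    With ``amiibo_first`` the molecule is amiibo-fragmented and oversized
    fragments are BRICS-split (recursively, while still oversized and
    reducible).  Without it, BRICS is applied to the whole molecule — the
    purely data-driven baseline pipeline.
    """
    if amiibo_first:
        pool = list(amiibo_fragment(mol).fragments)
    else:
        pool = brics_split(mol, range(mol.n_atoms))
    out: list[frozenset[int]] = []
    while pool:
        frag = pool.pop(0)
        if len(frag) > max_fragment_atoms:
            parts = brics_split(mol, frag)
            if len(parts) > 1:
                pool = parts + pool
                continue
        out.append(frag)
    return out


def count_fragment_keys(
    corpus: Sequence[PeptideMolecule],
    max_fragment_atoms: int = 20,
    amiibo_first: bool = True,
) -> dict[str, int]:
    """Exact fragment-key frequencies over a corpus (the mining pipeline)."""
    counts: dict[str, int] = {}
    for mol in corpus:
        for frag in _mining_fragments(mol, max_fragment_atoms, amiibo_first):
            key = canonical_key(mol, frag)
            counts[key] = counts.get(key, 0) + 1
    return counts


def learn_vocabulary(
    corpus: Sequence[PeptideMolecule],
    min_freq: int = 2,
    max_vocab: int = 2000,
    max_fragment_atoms: int = 20,
    amiibo_first: bool = True,
) -> FragmentVocabulary:
    """Mine a fragment vocabulary from a corpus.

    Ranking is by frequency (descending) with lexicographic key as the tie
    break, truncated at ``max_vocab`` non-reserved entries with frequency
    >= ``min_freq``.  Reserved single-atom keys always get ids ``0..E-1``.
    """
    if not corpus:
        raise ValueError("empty corpus")
    counts = count_fragment_keys(corpus, max_fragment_atoms, amiibo_first)
    ranked = sorted(
        (k for k, c in counts.items() if c >= min_freq and k not in _RESERVED_KEYS),
        key=lambda k: (-counts[k], k),
    )[:max_vocab]
    entries: dict[str, tuple[int, int]] = {}
    for i, key in enumerate(_RESERVED_KEYS):
        entries[key] = (i, counts.get(key, 0))
    offset = len(_RESERVED_KEYS)
    for j, key in enumerate(ranked):
        entries[key] = (offset + j, counts[key])
    return FragmentVocabulary(
        entries=entries,
        params={
            "min_freq": min_freq,
            "max_vocab": max_vocab,
            "max_fragment_atoms": max_fragment_atoms,
            "amiibo_first": amiibo_first,
        },
    )


def _encode_with_fallback(
    mol: PeptideMolecule, initial: list[frozenset[int]], vocab: FragmentVocabulary
) -> list[frozenset[int]]:
    """Recursively BRICS-split out-of-vocabulary / oversized fragments.

    Irreducible unknown fragments decompose into single atoms (reserved
    keys), so the result is always fully encodable.  Fragments are
    processed in ascending first-atom-index order for determinism.
    """
    max_atoms = int(vocab.params.get("max_fragment_atoms", 20))
    pool = sorted(initial, key=min)
    final: list[frozenset[int]] = []
    while pool:
        frag = pool.pop(0)
        if len(frag) == 1:
            # single atoms are always encodable (reserved per-element ids,
            # "*" for elements outside the alphabet)
            final.append(frag)
            continue
        key = canonical_key(mol, frag)
        if key in vocab and len(frag) <= max_atoms:
            final.append(frag)
            continue
        parts = brics_split(mol, frag)
        if len(parts) > 1:
            pool = sorted(parts, key=min) + pool
        else:
            final.extend(frozenset((a,)) for a in sorted(frag))
    return final


def adafrag_fragment(mol: PeptideMolecule, vocab: FragmentVocabulary) -> Fragmentation:
    """Amiibo fragmentation refined by the learned vocabulary.

    Out-of-vocabulary or oversized fragments are recursively BRICS-split;
    irreducible unknowns fall back to single atoms.  Every final fragment
    key is in the vocabulary.
    """
    frags = _encode_with_fallback(mol, list(amiibo_fragment(mol).fragments), vocab)
    out = _finalize(mol, frags, "adafrag")
    for atoms, key in zip(out.fragments, out.fragment_keys):
        if key not in vocab and len(atoms) > 1:
            raise EncodingError(f"fragment key {key!r} escaped vocabulary fallback")
    return out


def baseline_fragment(
    mol: PeptideMolecule, mode: str, vocab: FragmentVocabulary | None = None
) -> Fragmentation:
    """Granularity baselines: per-atom graphs and amide-blind mining.

    ``atoms_only`` makes every heavy atom its own fragment.
    ``principal_subgraph`` BRICS-cuts the whole molecule and applies the
    vocabulary fallback; it requires a vocabulary learned with
    ``amiibo_first=False`` and may freely cut amide C(=O)–N bonds.
    """
    if mode == "atoms_only":
        frags = [frozenset((a,)) for a in range(mol.n_atoms)]
        return _finalize(mol, frags, "atoms_only")
    if mode == "principal_subgraph":
        if vocab is None:
            raise ValueError("principal_subgraph mode requires a vocabulary")
        initial = brics_split(mol, range(mol.n_atoms))
        frags = _encode_with_fallback(mol, initial, vocab)
        return _finalize(mol, frags, "principal_subgraph")
    raise ValueError(f"unknown baseline mode {mode!r}")


def fragment(
    mol: PeptideMolecule, method: str, vocab: FragmentVocabulary | None = None
) -> Fragmentation:
    """Dispatch to one of the four fragmentation methods."""
    if method == "amiibo":
        return amiibo_fragment(mol)
    if method == "adafrag":
        if vocab is None:
            raise ValueError("adafrag requires a vocabulary")
        return adafrag_fragment(mol, vocab)
    if method in {"atoms_only", "principal_subgraph"}:
        return baseline_fragment(mol, method, vocab)
    raise ValueError(f"unknown fragmentation method {method!r}")


def reassemble(mol: PeptideMolecule, frag: Fragmentation) -> PeptideMolecule:
    """Rebuild the molecule from fragment subgraphs plus cut bonds.

    Serves as the round-trip oracle: the reassembled molecule's canonical
    key equals the input's for any valid fragmentation.
    """
    n = mol.n_atoms
    seen: set[int] = set()
    for atoms in frag.fragments:
        for a in atoms:
            if not (0 <= a < n):
                raise IntegrityError(f"fragment atom index {a} out of range")
            if a in seen:
                raise IntegrityError(f"atom {a} appears in two fragments")
            seen.add(a)
    if seen != set(range(n)):
        raise IntegrityError("fragments do not cover the molecule")
    for (i, j), _order in frag.cut_bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise IntegrityError(f"cut bond ({i},{j}) references a missing atom")
        if mol.mol.GetBondBetweenAtoms(i, j) is None:
            raise IntegrityError(f"cut bond ({i},{j}) absent from molecule")

    work = Chem.RWMol(mol.mol)
    Chem.Kekulize(work, clearAromaticFlags=True)
    fof = frag.fragment_of_atom()
    cut_pairs = {frozenset(p) for p, _ in frag.cut_bonds}
    rebuilt = Chem.RWMol()
    for idx in range(n):
        src = work.GetAtomWithIdx(idx)
        atom = Chem.Atom(src.GetAtomicNum())
        atom.SetFormalCharge(src.GetFormalCharge())
        atom.SetChiralTag(src.GetChiralTag())
        rebuilt.AddAtom(atom)
    for bond in work.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        intra = fof[i] == fof[j]
        if intra or frozenset((i, j)) in cut_pairs:
            rebuilt.AddBond(i, j, bond.GetBondType())
    out = rebuilt.GetMol()
    Chem.SanitizeMol(out)
    Chem.AssignStereochemistry(out, cleanIt=True, force=True)
    return PeptideMolecule(
        mol=out,
        residue_of_atom=mol.residue_of_atom,
        source=mol.source,
        mol_id=mol.mol_id,
    )
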