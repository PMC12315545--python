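"""Multi-view heterogeneous graph construction and featurization.

The graph holds two typed node sets — atoms and fragments — and three
typed edge sets: atom–atom bonds (the atom view), fragment–fragment edges
induced by cut bonds (the fragment view), and atom↔fragment membership
edges (the junction view).  All edges are stored directed in both
directions so message passing needs no symmetrization.  Indexing is
0-based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import PeptideMolecule
from .errors import EncodingError, IntegrityError
from .fragment import ELEMENT_ALPHABET, Fragmentation, FragmentVocabulary

logger = logging.getLogger(__name__)

# Atom feature columns: element, degree bucket, charge bucket, aromatic,
# implicit-H bucket, chirality.
OTHER_ELEMENT_INDEX = len(ELEMENT_ALPHABET)  # reserved "other element"
N_ELEMENT_CLASSES = len(ELEMENT_ALPHABET) + 1
ATOM_MASK_CLASS = N_ELEMENT_CLASSES  # extra embedding row for masked atoms

N_DEGREE = 6      # 0..5, clipped
N_CHARGE = 5      # -2..+2, clipped
N_HS = 5          # 0..4, clipped
N_CHIRAL = 3      # none / CW / CCW

BOND_ORDERS = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
N_BOND_ORDERS = 4

_CHIRAL_INDEX = {
    Chem.ChiralType.CHI_UNSPECIFIED: 0,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
}


@dataclass
class HeteroGraph:
    """Typed node/edge arrays for one peptide molecule.

    ``atom_features`` is (n_atoms, 6) int; ``fragment_ids`` is (n_frags,)
    vocabulary ids; edge index arrays are (2, n_edges) with row 0 = source.
    """

    atom_features: np.ndarray
    fragment_ids: np.ndarray
    edges_aa: np.ndarray
    bond_features: np.ndarray  # (n_aa_edges, 3): order, conjugated, in_ring
    edges_ff: np.ndarray
    edges_junction_af: np.ndarray  # atom -> fragment membership
    edges_junction_fa: np.ndarray  # fragment -> atom membership
    # atom indices sorted by canonical SMILES rank: the fixed node order
    # used by order-dependent (gated recurrent) pooling
    atom_canonical_order: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    mol_ref: str = ""

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.fragment_ids.shape[0]

    @property
    def n_junction_edges(self) -> int:
        return self.edges_junction_af.shape[1] + self.edges_junction_fa.shape[1]

    def copy(self) -> "HeteroGraph":
        return HeteroGraph(
            atom_features=self.atom_features.copy(),
            fragment_ids=self.fragment_ids.copy(),
            edges_aa=self.edges_aa,
            bond_features=self.bond_features,
            edges_ff=self.edges_ff,
            edges_junction_af=self.edges_junction_af,
            edges_junction_fa=self.edges_junction_fa,
            atom_canonical_order=self.atom_canonical_order,
            mol_ref=self.mol_ref,
        )

    def to_json_dict(self) -> dict:
        """Debug dump; not a performance path."""
        return {
            "mol_ref": self.mol_ref,
            "atom_features": self.atom_features.tolist(),
            "fragment_ids": self.fragment_ids.tolist(),
            "edges_aa": self.edges_aa.tolist(),
            "bond_features": self.bond_features.tolist(),
            "edges_ff": self.edges_ff.tolist(),
            "edges_junction_af": self.edges_junction_af.tolist(),
            "edges_junction_fa": self.edges_junction_fa.tolist(),
        }


def atom_feature_row(atom: Chem.Atom) -> list[int]:
    symbol = atom.GetSymbol()
    if symbol in ELEMENT_ALPHABET:
        elem = ELEMENT_ALPHABET.index(symbol)
    else:
        logger.warning("element %s outside alphabet; using reserved index", symbol)
        elem = OTHER_ELEMENT_INDEX
    return [
        elem,
        min(atom.GetDegree(), N_DEGREE - 1),
        int(np.clip(atom.GetFormalCharge(), -2, 2)) + 2,
        int(atom.GetIsAromatic()),
        min(atom.GetTotalNumHs(), N_HS - 1),
        _CHIRAL_INDEX.get(atom.GetChiralTag(), 0),
    ]


def _fragment_vocab_id(
    mol: PeptideMolecule, atoms: frozenset[int], key: str, vocab: FragmentVocabulary
) -> int:
    if key in vocab:
        return vocab.id_of(key)
    if len(atoms) == 1:
        symbol = mol.mol.GetAtomWithIdx(next(iter(atoms))).GetSymbol()
        return vocab.single_atom_id(symbol)
    raise EncodingError(
        f"fragment key {key!r} missing from vocabulary; fragment with adafrag"
    )


def build_heterograph(
    mol: PeptideMolecule, frag: Fragmentation, vocab: FragmentVocabulary
) -> HeteroGraph:
    """Assemble the atom/fragment/junction heterograph for one molecule.

    Count laws: atom nodes = heavy atoms; atom–atom edges = 2 × bonds;
    fragment–fragment edges = 2 × cut bonds; junction edges = 2 × atoms.
    """
    n = mol.n_atoms
    fof = frag.fragment_of_atom()
    if set(fof) != set(range(n)):
        raise IntegrityError("fragmentation does not cover the molecule")

    atom_features = np.array(
        [atom_feature_row(a) for a in mol.mol.GetAtoms()], dtype=np.int64
    ).reshape(n, 6)
    fragment_ids = np.array(
        [
            _fragment_vocab_id(mol, atoms, key, vocab)
            for atoms, key in zip(frag.fragments, frag.fragment_keys)
        ],
        dtype=np.int64,
    )

    aa_src, aa_dst, bf = [], [], []
    for bond in mol.mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        row = [
            BOND_ORDERS[bond.GetBondType()],
            int(bond.GetIsConjugated()),
            int(bond.IsInRing()),
        ]
        aa_src += [i, j]
        aa_dst += [j, i]
        bf += [row, row]

    ff_src, ff_dst = [], []
    for (i, j), _order in frag.cut_bonds:
        fi, fj = fof[i], fof[j]
        ff_src += [fi, fj]
        ff_dst += [fj, fi]

    atoms_idx = np.arange(n, dtype=np.int64)
    frag_of = np.array([fof[a] for a in range(n)], dtype=np.int64)
    ranks = np.array(Chem.CanonicalRankAtoms(mol.mol, breakTies=True), dtype=np.int64)
    canonical_order = np.argsort(ranks, kind="stable")

    return HeteroGraph(
        atom_features=atom_features,
        fragment_ids=fragment_ids,
        edges_aa=np.array([aa_src, aa_dst], dtype=np.int64).reshape(2, -1),
        bond_features=np.array(bf, dtype=np.int64).reshape(-1, 3),
        edges_ff=np.array([ff_src, ff_dst], dtype=np.int64).reshape(2, -1),
        edges_junction_af=np.vstack([atoms_idx, frag_of]),
        edges_junction_fa=np.vstack([frag_of, atoms_idx]),
        atom_canonical_order=canonical_order,
        mol_ref=mol.mol_id,
    )


def backbone_atoms(mol: PeptideMolecule) -> set[int] | None:
    """Atoms of the maximal peptide backbone, or None if no backbone exists.

    The backbone is the longest chain of N–Cα–C(=O) units linked by amide
    bonds, plus each unit's carbonyl oxygen and the terminal carboxyl
    oxygens.  N-substituents (e.g. N-methyl groups) and Cα substituents
    count as side chain.
    """
    rdmol = mol.mol
    units: list[tuple[int, int, int]] = []  # (N, CA, C) with C carbonyl
    for match in rdmol.GetSubstructMatches(Chem.MolFromSmarts("[NX3][CX4][CX3](=O)")):
        n_idx, ca, c, _o = match
        units.append((n_idx, ca, c))
    if not units:
        # single-unit fallback: a lone N-C-C(=O) where C may be the free acid
        return None

    # link unit i -> unit j when C_i is amide-bonded to N_j
    succ: dict[int, list[int]] = {i: [] for i in range(len(units))}
    for i, (_, _, c_i) in enumerate(units):
        for j, (n_j, _, _) in enumerate(units):
            if i == j:
                continue
            if rdmol.GetBondBetweenAtoms(c_i, n_j) is not None:
                succ[i].append(j)

    def longest_from(i: int, visited: frozenset[int]) -> list[int]:
        best = [i]
        for j in succ[i]:
            if j in visited:
                continue
            cand = [i] + longest_from(j, visited | {j})
            if len(cand) > len(best):
                best = cand
        return best

    best_path: list[int] = []
    for i in range(len(units)):
        path = longest_from(i, frozenset({i}))
        if len(path) > len(best_path):
            best_path = path

    atoms: set[int] = set()
    for k in best_path:
        n_idx, ca, c = units[k]
        atoms |= {n_idx, ca, c}
        for nb in rdmol.GetAtomWithIdx(c).GetNeighbors():
            if nb.GetSymbol() == "O":
                atoms.add(nb.GetIdx())  # carbonyl O, and terminal OH on last C
    return atoms


def side_chain_atoms(mol: PeptideMolecule) -> set[int]:
    """Complement of the peptide backbone.

    Molecules without an identifiable backbone return all atoms (with a
    logged warning): they have no backbone to protect, so the whole
    molecule is treated as side chain.
    """
    backbone = backbone_atoms(mol)
    if backbone is None:
        logger.warning(
            "no peptide backbone found in %s; treating all atoms as side chain",
            mol.mol_id or mol.canonical_smiles,
        )
        return set(range(mol.n_atoms))
    return set(range(mol.n_atoms)) - backbone


def quotient_graph_edges(mol: PeptideMolecule, frag: Fragmentation) -> set[tuple[int, int]]:
    """Directed fragment-adjacency edges computed naively from the atom view.

    Independent oracle for the fragment view: contract each fragment and
    keep one directed edge pair per adjacent fragment pair.
    """
    fof = frag.fragment_of_atom()
    edges: set[tuple[int, int]] = set()
    for i, j in mol.bonds():
        fi, fj = fof[i], fof[j]
        if fi != fj:
            edges.add((fi, fj))
            edges.add((fj, fi))
    return edges
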