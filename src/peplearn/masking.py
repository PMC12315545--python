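"""Masking strategies for masked-attribute self-supervised pretraining.

Peptides are structurally repetitive — every residue contributes an amide
unit — so uniformly random atom masking makes the prediction task largely
trivial.  Four strategies with different spatial structure are provided:

* ``random`` — uniform sample of atoms without replacement.
* ``bulk`` — a breadth-first ball grown from a random seed atom, so the
  masked set is connected.
* ``sidechain`` — uniform sample restricted to side-chain atoms (falls
  back to random, with a logged warning, when side chains are scarce).
* ``fragment`` — whole fragments sampled without replacement until the
  atom target is reached; their vocabulary ids become extra labels.

Targets are ``ceil(ratio × n_atoms)`` atoms, honoured to ±1 atom (±1
fragment for the fragment strategy).  Labels are recorded before any
feature is overwritten.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chem import PeptideMolecule
from .errors import IntegrityError
from .fragment import Fragmentation
from .graph import ATOM_MASK_CLASS, HeteroGraph, side_chain_atoms

logger = logging.getLogger(__name__)

STRATEGIES = ("random", "bulk", "sidechain", "fragment")


@dataclass
class MaskPlan:
    masked_atoms: frozenset[int]
    masked_fragments: frozenset[int]
    atom_labels: dict[int, int]       # atom index -> element-class index
    fragment_labels: dict[int, int]   # fragment index -> vocab id
    strategy: str
    target_ratio: float


def _bfs_ball(mol: PeptideMolecule, seed: int, target: int) -> set[int]:
    chosen = {seed}
    frontier = [seed]
    while len(chosen) < target and frontier:
        nxt: list[int] = []
        for a in frontier:
            for nb in sorted(mol.neighbors(a)):
                if nb not in chosen:
                    chosen.add(nb)
                    nxt.append(nb)
                    if len(chosen) >= target:
                        return chosen
        frontier = nxt
    return chosen


def plan_mask(
    graph: HeteroGraph,
    mol: PeptideMolecule,
    frag: Fragmentation,
    strategy: str,
    ratio: float,
    rng: np.random.Generator,
) -> MaskPlan:
    """Choose which atoms (and, for ``fragment``, which fragments) to mask."""
    if graph.n_atoms == 0:
        raise ValueError("empty graph")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"mask ratio must be in (0,1), got {ratio}")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown masking strategy {strategy!r}")

    n = graph.n_atoms
    target = max(1, math.ceil(ratio * n))
    masked_fragments: set[int] = set()

    if strategy == "random":
        masked_atoms = set(rng.choice(n, size=target, replace=False).tolist())
    elif strategy == "bulk":
        seed = int(rng.integers(n))
        masked_atoms = _bfs_ball(mol, seed, target)
    elif strategy == "sidechain":
        pool = sorted(side_chain_atoms(mol))
        if len(pool) < target:
            logger.warning(
                "side chains (%d atoms) smaller than mask target (%d); "
                "falling back to random masking",
                len(pool),
                target,
            )
            masked_atoms = set(rng.choice(n, size=target, replace=False).tolist())
        else:
            masked_atoms = set(
                np.asarray(pool)[rng.choice(len(pool), size=target, replace=False)].tolist()
            )
    else:  # fragment
        order = rng.permutation(graph.n_fragments)
        masked_atoms = set()
        for fi in order:
            masked_fragments.add(int(fi))
            masked_atoms |= set(frag.fragments[int(fi)])
            if len(masked_atoms) >= target:
                break

    atom_labels = {a: int(graph.atom_features[a, 0]) for a in sorted(masked_atoms)}
    fragment_labels = {
        fi: int(graph.fragment_ids[fi]) for fi in sorted(masked_fragments)
    }
    return MaskPlan(
        masked_atoms=frozenset(masked_atoms),
        masked_fragments=frozenset(masked_fragments),
        atom_labels=atom_labels,
        fragment_labels=fragment_labels,
        strategy=strategy,
        target_ratio=ratio,
    )


def apply_mask(graph: HeteroGraph, plan: MaskPlan) -> tuple[HeteroGraph, MaskPlan]:
    """Overwrite masked attributes with reserved MASK classes.

    Only the element column of masked atoms and the vocabulary id of
    masked fragments change; everything else is untouched.  Idempotent.
    Returns the masked graph and the plan (whose labels are the training
    targets).
    """
    for a in plan.masked_atoms:
        if not 0 <= a < graph.n_atoms:
            raise IntegrityError(f"masked atom {a} out of range")
    for fi in plan.masked_fragments:
        if not 0 <= fi < graph.n_fragments:
            raise IntegrityError(f"masked fragment {fi} out of range")
    masked = graph.copy()
    if plan.masked_atoms:
        idx = np.fromiter(plan.masked_atoms, dtype=np.int64)
        masked.atom_features[idx, 0] = ATOM_MASK_CLASS
    if plan.masked_fragments:
        fidx = np.fromiter(plan.masked_fragments, dtype=np.int64)
        masked.fragment_ids[fidx] = -1  # resolved to the MASK row at embedding time
    return masked, plan
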