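# peplearn

Fragment-level representation learning for peptides built from canonical
**and non-canonical** amino acids (D-stereoisomers, N-methylated residues,
Aib, homoserine, norleucine, …).

Protein language models operate on the 20-letter alphabet and cannot see
residue chemistries outside it, while generic small-molecule models ignore
the strong structural regularities of peptides. `peplearn` works at the
molecular-graph level but injects peptide knowledge through
*fragmentation*: a peptide molecule is partitioned into chemically
meaningful fragments, encoded as a heterogeneous graph with three views —
atoms, fragments, and the atom↔fragment *junction* incidence — and
pretrained by masked-attribute prediction so that the resulting embeddings
transfer to downstream property prediction (e.g. cell permeability or
binding affinity regression).

## Method

**Fragmentation.**

* `amiibo` (domain knowledge): cut exactly the acyclic single N–Cα bonds
  whose nitrogen belongs to an amide group C(=O)–N. The amide bond itself
  is never cut and rings stay intact, so a proline-free linear peptide of
  *n* residues yields exactly *n* fragments, each an amide-intact residue
  unit.
* `adafrag` (data driven): learn a fragment vocabulary
  `V = {key → (id, freq)}` by counting canonical-SMILES keys of amiibo
  fragments over a corpus (oversized fragments are split along BRICS
  bonds). At encoding time, any fragment whose key is out of vocabulary is
  recursively BRICS-split; irreducible unknowns decompose into single
  atoms, whose per-element keys are always reserved — encoding is total.
* Baselines: `atoms_only` (each atom its own fragment) and
  `principal_subgraph` (whole-molecule BRICS + frequency mining, no amide
  protection).

**Heterogeneous graph.** Atom nodes carry (element, degree, charge,
aromaticity, implicit-H count, chirality); fragment nodes carry vocabulary
ids; edges are atom–atom bonds, fragment–fragment contacts (one per cut
bond) and atom↔fragment membership (the junction view). Message passing
applies a per-edge-type linear transform with sum aggregation and a shared
residual update. Four node-state variants — A, F (within-view) and AJ, FJ
(joint propagation with junction edges) — feed the fusion strategies A&F,
AJ&F and AJ&FJ; each side is pooled (Max, Avg, or a GRU over the canonical
atom order) and concatenated into a graph embedding of length
2·`hidden_dim`.

**Pretraining.** Masked-attribute prediction: hide the element class of a
subset of atoms (and, under FragmentMasking, the vocabulary id of whole
fragments) and minimise

```
L = CE(masked-atom element) + λ_frag · CE(masked-fragment id)
```

with four masking strategies (Random, Bulk, SideChain, Fragment) and a
two-stage schedule: first canonical-only peptides, then continued training
on non-canonical peptides. Downstream heads are scored by Spearman
correlation (regression) or ROC AUC (classification).

## Worked example

```python
import numpy as np
from peplearn import (
    builtin_library, sequence_to_molecule, amiibo_fragment,
    learn_vocabulary, adafrag_fragment, build_heterograph,
    ModelConfig, init_params, encode,
)

lib = builtin_library()                      # 20 canonical + 7 non-canonical
mol = sequence_to_molecule("G[Aib]F", lib)   # bracketed = multi-letter codes
frag = amiibo_fragment(mol)
print(mol.canonical_smiles)
print(frag.n_fragments, frag.fragment_keys)

vocab = learn_vocabulary([mol] * 2, min_freq=2)
graph = build_heterograph(mol, adafrag_fragment(mol, vocab), vocab)
cfg = ModelConfig(hidden_dim=32, n_layers=2)
params = init_params(cfg, vocab.size, np.random.default_rng(0))
emb = encode(graph, params, cfg).graph_embedding
print(emb.shape)
```

prints

```
CC(C)(NC(=O)CN)C(=O)N[C@@H](Cc1ccccc1)C(=O)O
3 ['NCC(N)=O', 'CC(C)C(N)=O', 'O=C(O)CCc1ccccc1']
(64,)
```

— the tripeptide Gly–Aib–Phe splits into three amide-intact residue
units whose cut N–Cα bonds are hydrogen-capped in the keys (the Phe unit's
Cα stereocentre disappears once its nitrogen is replaced by H), and the
encoder returns a 64-dimensional graph embedding (2 × `hidden_dim`).

The same pipeline is available from the shell:

```bash
peplearn simulate --n 100 --pool mixed --seed 1 --out corpus.smi
peplearn vocab --in corpus.smi --out vocab.json
peplearn fragment --method adafrag --vocab vocab.json --in corpus.smi --out frags.tsv
peplearn pretrain --stage1 corpus.smi --seed 1 --out ckpt/
peplearn embed --ckpt ckpt/ --in corpus.smi --out emb.tsv
```

Every run writes a manifest (command, config hash, input digests, seed,
version) next to its outputs.

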