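# Methods

This note documents the models and procedures implemented in `peplearn`,
the defaults that matter, the synthetic data the test suite runs on, and
the design choices made where several reasonable options existed.

## Peptide construction

Monomers are stored as SMILES with two attachment points: a dummy atom
with map number 1 marks the amine (N-terminal) side, map number 2 the
carboxyl (C-terminal) side; capping monomers carry one. Condensation
joins the carboxyl carbon of residue *i* to the amine nitrogen of residue
*i+1* with loss of one hydroxyl per bond, so an *n*-residue peptide has
Σ(monomer heavy atoms) − (n−1) heavy atoms. Terminal dummies resolve to
an implicit hydrogen (N-terminus) and a hydroxyl oxygen (C-terminus);
with `cyclic=True` they condense onto each other instead (head-to-tail
macrocycles only — side-chain cyclization is out of scope). Hydrogens
are implicit throughout; only heavy atoms are graph nodes.
Stereochemistry is carried as RDKit chiral tags, so D-residues key
differently from their L-counterparts. The sequence tokenizer treats
single letters as canonical codes and bracketed substrings (`[Aib]`) as
literal codes.

The built-in library ships the 20 canonical L-amino acids plus seven
non-canonical monomers spanning the common modification classes:
D-alanine and D-phenylalanine (stereo inversion), sarcosine and
N-methyl-phenylalanine (backbone N-methylation), Aib (Cα dialkylation),
homoserine and norleucine (side-chain variants).

## Fragment keys

A fragment is keyed by the canonical SMILES of its induced heavy-atom
subgraph with cut bonds replaced by implicit hydrogens. Attachment-
labelled keys were deliberately not used: they multiply the vocabulary by
the number of attachment patterns without adding signal at this scale.
Two numerical details follow from H-capping:

* The parent molecule is kekulized before taking subsets. A subset
  containing a whole aromatic ring re-aromatizes on sanitization and keys
  identically regardless of kekulization phase; a subset slicing through
  a ring (only possible under the atoms-only baseline) keys by its
  kekulized bond orders.
* Stereocentres that lose a distinguishing substituent to capping are
  dropped (`AssignStereochemistry(cleanIt=True)`), which keeps keys
  deterministic.

## Fragmentation operators

**amiibo.** Cut set = all acyclic single N–Cα bonds whose nitrogen has a
single-bonded carbonyl-carbon neighbour (i.e. sits in an amide); the
amide C(=O)–N bond itself and all ring bonds are never cut. The main
design commitment here is the cut-bond choice: cutting N–Cα (rather than
Cα–C(=O)) puts each residue's carbonyl together with the next residue's
nitrogen in one fragment, keeping every amide group intact inside a
fragment, and yields exactly one fragment per residue for proline-free
linear peptides. Proline's N–Cα bond is in the pyrrolidine ring, so Pro
merges with the preceding residue's fragment — documented behaviour, not
a bug.

**Vocabulary mining.** Each corpus molecule is amiibo-fragmented;
fragments larger than `max_fragment_atoms` (default 20, enough for every
single-residue unit including Trp) are recursively BRICS-split while
reducible. Canonical keys are counted exactly; the vocabulary keeps the
up-to-`max_vocab` (default 2000) most frequent keys with frequency ≥
`min_freq` (default 2), ranked by frequency descending with lexicographic
key as tie-break for determinism. Ids 0..11 are reserved for single-atom
keys of the element alphabet {C,N,O,S,P,F,Cl,Br,I,B,Se} plus an
"other-element" slot, which makes every molecule encodable.

**adafrag.** Start from amiibo; any fragment whose key is out of
vocabulary or oversized is recursively BRICS-split (fragments processed
in ascending first-atom-index order for determinism); irreducible
unknowns decompose into single atoms. BRICS never cleaves ring bonds, so
rings survive unless the whole fragment falls back to atoms.

**Baselines.** `atoms_only` puts every atom in its own fragment.
`principal_subgraph` applies BRICS to the whole molecule and uses a
vocabulary mined the same way but *without* the amiibo stage; it has no
amide protection and does cut amide bonds (BRICS rule L1–L5), which is
exactly the property the comparison is meant to expose. It stands in for
iterative principal-subgraph merging, which is not reproduced in full.

## Heterogeneous graph

Node features are small categorical indices: element (12 classes
including "other", plus a reserved MASK class), degree 0–5, formal
charge −2..+2, aromaticity, implicit-H count 0–4, chirality
(none/CW/CCW); bonds carry order/conjugation/ring flags. Fragment nodes
carry vocabulary ids (one extra embedding row serves as the fragment MASK
id). All edges are stored directed in both directions so message passing
needs no symmetrization; junction membership contributes exactly
2 × (heavy atoms) directed edges. The junction view is realized as typed
membership *edges* between the atom and fragment node sets rather than a
third node set — the minimal reading consistent with treating it as a
view, and isolated behind the graph type should dedicated junction nodes
ever be wanted.

The backbone/side-chain split matches N–Cα–C(=O) units via SMARTS, links
units through amide bonds, takes the longest such chain, and adds
carbonyl plus terminal carboxyl oxygens. N-substituents (e.g. N-methyl
groups) count as side chain. Molecules with no identifiable backbone are
treated as all side chain with a logged warning.

## Masking and pretraining

Targets are `ceil(ratio × heavy atoms)` with ratio default 0.15 (a
standard masked-modelling rate; no value is prescribed by the problem),
honoured to ±1 atom, or to +at-most-one-fragment overshoot under
FragmentMasking. Only node attributes are masked — the element class of
atoms and the vocabulary id of fragments; edge attributes are left
untouched as the simplest faithful objective. SideChainMasking falls
back to random masking with a logged warning when side-chain atoms are
scarcer than the target (e.g. poly-glycine). Labels are recorded before
features are overwritten; masking is idempotent.

The objective is mean cross-entropy over masked-atom element classes plus
`λ_frag` (default 1.0) times cross-entropy over masked-fragment ids.
Note that masking replaces only the element index: degree and implicit-H
features remain visible and correlate with element identity, so
masked-atom accuracy is expected to be well above the majority-element
baseline once training starts — the baseline comparison checks learning,
not task difficulty.

Optimization is Adam (lr 1e-3, batch 16 molecules with gradient
averaging), fully seeded; a non-finite loss aborts with a diagnostic
rather than training on NaNs. Output-head weights are initialized at
scale 0.01 so the epoch-0 evaluation loss sits near log(12), the
uniform-softmax cross-entropy over element classes — a calibration check,
not a tuned quantity. A held-out split (10%) is evaluated with masks
fixed by a derived seed so per-epoch accuracies are comparable.

Two-stage training runs canonical-only peptides first, then continues —
without re-initialization — on non-canonical peptides, mirroring the
scarcity of non-canonical data relative to canonical data. Both stages
share one vocabulary learned on the union of corpora so the fragment
embedding table never changes shape mid-training. A one-stage mode
supports the schedule ablation; the stage-1 checkpoint is returned either
way.

## Encoder, fusion, pooling, heads

Each message-passing layer computes, per edge type, `msg = h_src @ W_t`
(bond-feature embeddings are added to the source state on atom–atom
edges), sums incoming messages per node, and updates with a shared linear
transform, residual connection and ReLU. Variants A and F propagate only
within their view; AJ and FJ come from joint propagation including both
junction directions. Fusion picks the (atom-side, fragment-side) pair;
each side is pooled separately and the two pooled vectors concatenated —
pooling jointly across views was the open alternative, but per-side
pooling matches the pairwise naming of the fusion strategies and keeps
the two halves interpretable.

Max and average pooling are order-invariant. GRU pooling (the default)
runs a single-layer gated recurrent pass from a zero state and is
order-*dependent*; the node order is fixed to the canonical-SMILES atom
ranking (fragments by minimum atom index), so identical inputs give
identical embeddings across runs regardless of input atom numbering.

The fine-tuning head is a two-layer perceptron on the graph embedding
(hidden width 64), with squared-error loss for regression and logistic
loss for binary tasks. `frozen_probe` mode precomputes embeddings and
trains only the head — the backbone is asserted bit-identical afterwards;
`full` mode backpropagates through the encoder. Spearman correlation and
ROC AUC are computed by scipy/scikit-learn behind a strict interface that
raises on constant input or a missing class instead of returning NaN.

All neural components run on a small reverse-mode autodiff core over
NumPy arrays (`peplearn.nn`), with gradients verified against finite
differences in the test suite. At the corpus sizes this package targets
(hundreds of peptides, hidden dimensions ≤ 128) this is fast enough and
keeps the dependency surface to the scientific Python stack.

## Synthetic data: what it does and does not show

`generate_corpus` samples monomer sequences uniformly over a pool and a
length range (default 2–30 residues, the short-peptide regime this
package targets), with an optional planted motif inserted into an exact
fraction of sequences; background sequences are rejection-sampled so the
carrier count is exact. Labels are linear in fragment-key counts with
Gaussian noise, or their median split (ties positive). This gives every
stage a measurable ground truth: vocabulary mining must recover the
planted motif, and frozen-probe fine-tuning must recover the linear
fragment-count signal (held-out Spearman ≥ 0.7 with noise at 10% of the
signal's standard deviation).

What the generator does **not** emulate: amino-acid composition biases of
real proteomes, motif grammar beyond one planted subsequence, any real
property physics (permeability, binding), or structural (3D) effects.
Passing tests therefore demonstrate that the machinery is correct and
that embeddings carry fragment-composition information — not that the
defaults are optimal for any particular assay.

## Problem sizes and runtime

The acceptance-level checks run on 500 synthetic peptides (fragmentation,
graph and masking laws; pretraining with hidden dimension 64 for 5
epochs; probes with a 400/100 split over 3 seeds) and a 100+100-molecule
two-corpus setup over several seeds for the directional ablation — sizes
chosen so the whole suite completes in minutes on a single CPU while
keeping every statistical margin comfortable.

## Known limitations

* The amiibo cut rule and the vocabulary algorithm are this package's
  explicit formalization of amide-preserving and data-driven
  fragmentation; both are isolated behind the `fragment` module interface
  so alternative rules can be swapped in.
* Proline (and any N–Cα-in-ring monomer) merges with its predecessor.
* The principal-subgraph baseline is frequency-mined BRICS, not the full
  iterative-merge algorithm.
* Edge attributes are never masked; junction edges carry no features.
* Head-to-tail is the only supported cyclization.
* GRU pooling's canonical order makes it reproducible but still
  order-sensitive by construction; permutation-invariant readouts are the
  Max/Avg options.
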