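"""Masked-attribute self-supervised pretraining, in one or two stages.

The model is trained to recover masked node attributes from graph
context: the element class of masked atoms and, under the fragment
strategy, the vocabulary id of masked fragments.  The objective is

    L = CE(masked-atom element) + λ_frag · CE(masked-fragment id)

Because non-canonical peptide data is scarce relative to canonical data,
training is split into two sub-phases: a first stage on canonical-only
peptides establishes backbone regularities, and a second stage continues
from those parameters (no re-initialization) on non-canonical peptides.
Both stages share one vocabulary learned on the union of the corpora so
the fragment embedding table never changes shape mid-training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .chem import PeptideMolecule
from .errors import ConfigError
from .fragment import FragmentVocabulary, adafrag_fragment
from .graph import N_ELEMENT_CLASSES, HeteroGraph, build_heterograph
from .masking import apply_mask, plan_mask
from .model import ModelConfig, _propagate, init_params
from .nn import Tensor


@dataclass
class PretrainConfig:
    mask_ratio: float = 0.15
    strategy: str = "fragment"
    epochs_stage1: int = 5
    epochs_stage2: int = 3
    batch_size: int = 16
    lr: float = 1e-3
    seed: int = 0
    lambda_frag: float = 1.0
    holdout_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_ratio < 1.0:
            raise ConfigError("mask_ratio must be in (0,1)")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ConfigError("holdout_fraction must be in [0,1)")


@dataclass
class PreparedMolecule:
    mol: PeptideMolecule
    frag: object
    graph: HeteroGraph


def prepare_corpus(
    corpus: list[PeptideMolecule], vocab: FragmentVocabulary
) -> list[PreparedMolecule]:
    """Fragment (adafrag) and build heterographs once, up front."""
    out = []
    for mol in corpus:
        frag = adafrag_fragment(mol, vocab)
        out.append(PreparedMolecule(mol, frag, build_heterograph(mol, frag, vocab)))
    return out


def _molecule_loss(
    prep: PreparedMolecule,
    params: dict[str, Tensor],
    model_config: ModelConfig,
    config: PretrainConfig,
    rng: np.random.Generator,
) -> tuple[Tensor, Tensor | None, int, int, int, int]:
    """(atom loss, frag loss, n_masked_atoms, n_atom_correct, n_masked_frags, n_frag_correct)."""
    plan = plan_mask(prep.graph, prep.mol, prep.frag, config.strategy, config.mask_ratio, rng)
    masked, plan = apply_mask(prep.graph, plan)
    h_atom, h_frag = _propagate(masked, params, model_config, use_junction=True)

    atom_idx = np.array(sorted(plan.atom_labels), dtype=np.int64)
    atom_lab = np.array([plan.atom_labels[a] for a in atom_idx], dtype=np.int64)
    logits_a = nn.gather_rows(h_atom, atom_idx) @ params["head/atom_out"] + params["head/atom_out_b"]
    loss_a = nn.cross_entropy(logits_a, atom_lab)
    correct_a = int((logits_a.data.argmax(axis=1) == atom_lab).sum())

    loss_f = None
    n_f = correct_f = 0
    if plan.fragment_labels and config.lambda_frag > 0:
        frag_idx = np.array(sorted(plan.fragment_labels), dtype=np.int64)
        frag_lab = np.array([plan.fragment_labels[f] for f in frag_idx], dtype=np.int64)
        logits_f = nn.gather_rows(h_frag, frag_idx) @ params["head/frag_out"] + params["head/frag_out_b"]
        loss_f = nn.cross_entropy(logits_f, frag_lab)
        n_f = len(frag_idx)
        correct_f = int((logits_f.data.argmax(axis=1) == frag_lab).sum())
    return loss_a, loss_f, len(atom_idx), correct_a, n_f, correct_f


def _evaluate(
    prepared: list[PreparedMolecule],
    params: dict[str, Tensor],
    model_config: ModelConfig,
    config: PretrainConfig,
    eval_seed: int,
) -> dict:
    """Masked-attribute loss/accuracy with evaluation masks fixed by seed."""
    rng = np.random.default_rng(eval_seed)
    tot_la = tot_lf = 0.0
    n_a = c_a = n_f = c_f = 0
    n_lf = 0
    for prep in prepared:
        la, lf, na, ca, nf, cf = _molecule_loss(prep, params, model_config, config, rng)
        tot_la += float(la.data)
        n_a += na
        c_a += ca
        n_f += nf
        c_f += cf
        if lf is not None:
            tot_lf += float(lf.data)
            n_lf += 1
    return {
        "atom_loss": tot_la / max(len(prepared), 1),
        "frag_loss": tot_lf / max(n_lf, 1) if n_lf else None,
        "atom_accuracy": c_a / max(n_a, 1),
        "frag_accuracy": c_f / max(n_f, 1) if n_f else None,
        "n_masked_atoms": n_a,
        "n_masked_fragments": n_f,
    }


def majority_element_baseline(prepared: list[PreparedMolecule]) -> float:
    """Accuracy of always predicting the corpus's most common element class."""
    counts = np.zeros(N_ELEMENT_CLASSES, dtype=np.int64)
    for prep in prepared:
        elems = prep.graph.atom_features[:, 0]
        counts += np.bincount(elems, minlength=N_ELEMENT_CLASSES)
    return counts.max() / counts.sum()


def pretrain(
    corpus: list[PeptideMolecule] | list[PreparedMolecule],
    vocab: FragmentVocabulary,
    config: PretrainConfig,
    model_config: ModelConfig,
    params: dict[str, Tensor] | None = None,
    epochs: int | None = None,
) -> tuple[dict[str, Tensor], list[dict]]:
    """Train the masked-attribute objective; returns parameters and per-epoch metrics.

    The metrics list starts with an epoch-0 entry evaluated before any
    update (its ``atom_loss`` sits near ``log(n_element_classes)`` at a
    fresh initialization).  A held-out split provides masked-attribute
    accuracy; evaluation masks are fixed by seed so epochs are comparable.
    """
    if not corpus:
        raise ValueError("empty corpus")
    prepared = (
        list(corpus)
        if isinstance(corpus[0], PreparedMolecule)
        else prepare_corpus(corpus, vocab)
    )
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_params(model_config, vocab.size, rng)
    n_epochs = config.epochs_stage1 if epochs is None else epochs

    n_hold = int(math.floor(config.holdout_fraction * len(prepared)))
    if n_hold == 0 and config.holdout_fraction > 0 and len(prepared) > 1:
        n_hold = 1
    perm = rng.permutation(len(prepared))
    hold = [prepared[i] for i in perm[:n_hold]]
    train = [prepared[i] for i in perm[n_hold:]]
    eval_set = hold if hold else train
    eval_seed = int(rng.integers(2**31 - 1))

    opt = nn.Adam(params, lr=config.lr)
    metrics: list[dict] = []
    entry = _evaluate(eval_set, params, model_config, config, eval_seed)
    entry.update(epoch=0, train_loss=None)
    metrics.append(entry)

    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(len(train))
        epoch_loss = 0.0
        batch: list[int] = []
        for pos, mi in enumerate(order):
            batch.append(int(mi))
            if len(batch) == config.batch_size or pos == len(order) - 1:
                opt.zero_grad()
                batch_loss = 0.0
                for bi in batch:
                    la, lf, *_ = _molecule_loss(train[bi], params, model_config, config, rng)
                    loss = la if lf is None else la + Tensor(np.array(config.lambda_frag)) * lf
                    nn.backward(loss)
                    batch_loss += float(loss.data)
                if not np.isfinite(batch_loss):
                    raise FloatingPointError("pretraining loss diverged (non-finite)")
                # average accumulated gradients over the batch
                for p in params.values():
                    if p.grad is not None:
                        p.grad /= len(batch)
                opt.step()
                epoch_loss += batch_loss
                batch = []
        entry = _evaluate(eval_set, params, model_config, config, eval_seed)
        entry.update(epoch=epoch, train_loss=epoch_loss / max(len(train), 1))
        metrics.append(entry)
    return params, metrics


def two_stage_pretrain(
    stage1_corpus: list[PeptideMolecule],
    stage2_corpus: list[PeptideMolecule],
    vocab: FragmentVocabulary,
    config: PretrainConfig,
    model_config: ModelConfig,
    one_stage_only: bool = False,
) -> tuple[dict[str, Tensor], dict]:
    """Canonical-corpus pretraining continued on non-canonical peptides.

    Stage 2 resumes from the stage-1 parameters.  ``one_stage_only=True``
    (or ``epochs_stage2=0``) skips stage 2, for the ablation; the returned
    ``stage1_checkpoint`` is a deep copy taken between stages either way.
    """
    if not stage1_corpus or not stage2_corpus:
        raise ValueError("both corpora must be non-empty")
    params, metrics1 = pretrain(
        stage1_corpus, vocab, config, model_config, epochs=config.epochs_stage1
    )
    checkpoint = {k: nn.parameter(p.data.copy()) for k, p in params.items()}
    metrics2: list[dict] = []
    if not one_stage_only and config.epochs_stage2 > 0:
        stage2_cfg = replace(config, seed=config.seed + 1)
        params, metrics2 = pretrain(
            stage2_corpus, vocab, stage2_cfg, model_config,
            params=params, epochs=config.epochs_stage2,
        )
    return params, {
        "stage1": metrics1,
        "stage2": metrics2,
        "stage1_checkpoint": checkpoint,
    }
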