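"""Downstream property prediction on top of graph embeddings.

A two-layer perceptron head maps the ``2 × hidden_dim`` graph embedding to
a scalar; squared-error loss for regression, logistic loss for binary
classification.  ``frozen_probe`` mode leaves the backbone untouched and
trains the head on precomputed embeddings (a linear-probe-style readout);
``full`` mode backpropagates through the encoder as well.  Held-out
performance is Spearman correlation (regression) or ROC AUC (binary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .chem import PeptideMolecule
from .errors import ConfigError
from .fragment import FragmentVocabulary
from .metrics import auc, spearman
from .model import ModelConfig, graph_embedding_tensors
from .nn import Tensor
from .pretrain import PreparedMolecule, prepare_corpus


@dataclass
class FinetuneConfig:
    task: str = "regression"          # or "binary"
    mode: str = "frozen_probe"        # or "full"
    head_hidden: int = 64
    epochs: int = 200
    lr: float = 1e-2
    batch_size: int = 32
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in {"regression", "binary"}:
            raise ConfigError(f"unknown task {self.task!r}")
        if self.mode not in {"frozen_probe", "full"}:
            raise ConfigError(f"unknown mode {self.mode!r}")


def _head_params(d_in: int, d_hidden: int, rng: np.random.Generator) -> dict[str, Tensor]:
    return {
        "head/W1": nn.parameter(rng.normal(0, 1.0 / np.sqrt(d_in), (d_in, d_hidden))),
        "head/b1": nn.parameter(np.zeros((1, d_hidden))),
        "head/W2": nn.parameter(rng.normal(0, 1.0 / np.sqrt(d_hidden), (d_hidden, 1))),
        "head/b2": nn.parameter(np.zeros((1, 1))),
    }


def _head_forward(emb: Tensor, head: dict[str, Tensor]) -> Tensor:
    hidden = nn.relu(emb @ head["head/W1"] + head["head/b1"])
    return hidden @ head["head/W2"] + head["head/b2"]


def finetune(
    train: list[tuple[PeptideMolecule, float]],
    vocab: FragmentVocabulary,
    backbone_params: dict[str, Tensor],
    model_config: ModelConfig,
    config: FinetuneConfig,
    test: list[tuple[PeptideMolecule, float]] | None = None,
) -> tuple[dict[str, Tensor], dict]:
    """Fit the prediction head (and optionally the backbone); report held-out metrics.

    When ``test`` is None a seeded ``test_fraction`` split is carved from
    ``train``.  Returns the head parameters and a metrics dict with the
    task metric (``spearman`` or ``auc``), predictions and labels.
    """
    if not train:
        raise ValueError("empty training set")
    labels_all = np.array([y for _, y in train], dtype=float)
    if not np.all(np.isfinite(labels_all)):
        raise ValueError("labels must be finite")
    if config.task == "binary" and test is None and np.unique(labels_all).size < 2:
        raise ValueError("binary task needs both classes in the training set")

    rng = np.random.default_rng(config.seed)
    if test is None:
        perm = rng.permutation(len(train))
        n_test = max(1, int(round(config.test_fraction * len(train))))
        test = [train[i] for i in perm[:n_test]]
        train = [train[i] for i in perm[n_test:]]
    if config.task == "binary":
        if np.unique([y for _, y in train]).size < 2:
            raise ValueError("binary task degenerate: single class after split")

    train_prep = prepare_corpus([m for m, _ in train], vocab)
    test_prep = prepare_corpus([m for m, _ in test], vocab)
    y_train = np.array([y for _, y in train], dtype=float)
    y_test = np.array([y for _, y in test], dtype=float)

    head = _head_params(2 * model_config.hidden_dim, config.head_hidden, rng)
    backbone_before = {k: p.data.copy() for k, p in backbone_params.items()}

    def embedding_tensor(prep: PreparedMolecule) -> Tensor:
        _, _, emb = graph_embedding_tensors(prep.graph, backbone_params, model_config)
        return emb

    if config.mode == "frozen_probe":
        # embeddings are constants: compute once, detach from the backbone
        X_train = Tensor(np.stack([embedding_tensor(p).data for p in train_prep]))
        X_test = np.stack([embedding_tensor(p).data for p in test_prep])
        trainable = dict(head)
        opt = nn.Adam(trainable, lr=config.lr)
        n = X_train.shape[0]
        for _epoch in range(config.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, config.batch_size):
                idx = order[lo : lo + config.batch_size]
                opt.zero_grad()
                pred = _head_forward(nn.gather_rows(X_train, idx), head)
                target = y_train[idx].reshape(-1, 1)
                if config.task == "regression":
                    loss = nn.mse(pred, target)
                else:
                    loss = nn.binary_cross_entropy_with_logits(pred, target)
                nn.backward(loss)
                opt.step()
        pred_test = _head_forward(Tensor(X_test), head).data.reshape(-1)
        # frozen mode must leave the backbone bit-identical
        for k, p in backbone_params.items():
            assert np.array_equal(p.data, backbone_before[k])
    else:  # full
        trainable = dict(head)
        trainable.update(backbone_params)
        opt = nn.Adam(trainable, lr=config.lr)
        n = len(train_prep)
        for _epoch in range(config.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, config.batch_size):
                idx = order[lo : lo + config.batch_size]
                opt.zero_grad()
                embs = nn.concat([_reshape_row(embedding_tensor(train_prep[i])) for i in idx], axis=0)
                pred = _head_forward(embs, head)
                target = y_train[idx].reshape(-1, 1)
                if config.task == "regression":
                    loss = nn.mse(pred, target)
                else:
                    loss = nn.binary_cross_entropy_with_logits(pred, target)
                nn.backward(loss)
                for p in trainable.values():
                    if p.grad is not None:
                        p.grad /= len(idx)
                opt.step()
        pred_test = np.array(
            [_head_forward(_reshape_row(embedding_tensor(p)), head).data.item() for p in test_prep]
        )

    metrics: dict = {
        "task": config.task,
        "mode": config.mode,
        "n_train": len(train_prep),
        "n_test": len(test_prep),
        "predictions": pred_test.tolist(),
        "labels": y_test.tolist(),
    }
    if config.task == "regression":
        metrics["spearman"] = spearman(pred_test, y_test)
    else:
        metrics["auc"] = auc(pred_test, y_test.astype(int))
    return head, metrics


def _reshape_row(emb: Tensor) -> Tensor:
    """(2h,) -> (1, 2h) while keeping the tape intact."""
    d = emb.shape[0]

    def back(g: np.ndarray) -> None:
        emb._accumulate(g.reshape(d))

    return Tensor(emb.data.reshape(1, d), (emb,), back)
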