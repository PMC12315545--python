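"""Ablation harness: masking strategy x pretraining schedule x readout.

Mirrors the framework's component studies at desk scale on synthetic
corpora: pretrain under each masking strategy with one- and two-stage
schedules, score the non-canonical held-out masked-fragment accuracy,
and probe each pooling x fusion readout with a frozen-probe fit on
linear fragment-count labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chem import builtin_library
from .finetune import FinetuneConfig, finetune
from .fragment import FragmentVocabulary, fragment, learn_vocabulary
from .masking import STRATEGIES
from .model import FUSIONS, POOLINGS, ModelConfig
from .pretrain import (
    PretrainConfig,
    prepare_corpus,
    pretrain,
    two_stage_pretrain,
    _evaluate,
)
from .simulate import CorpusSpec, generate_corpus


@dataclass
class AblationSettings:
    """Problem sizes for the sweep; ``quick`` trades fidelity for speed."""

    n_canonical: int = 150
    n_noncanonical: int = 150
    n_holdout: int = 40
    min_length: int = 2
    max_length: int = 15
    epochs_stage1: int = 3
    epochs_stage2: int = 2
    hidden_dim: int = 48
    n_layers: int = 2
    probe_epochs: int = 120
    label_rel_noise: float = 0.1

    @classmethod
    def quick(cls) -> "AblationSettings":
        return cls(
            n_canonical=40, n_noncanonical=40, n_holdout=15, max_length=8,
            epochs_stage1=1, epochs_stage2=1, hidden_dim=24, n_layers=2,
            probe_epochs=40,
        )


@dataclass
class AblationData:
    """Corpora, vocabulary and prepared graphs shared across conditions."""

    canonical: list
    noncanonical: list
    nc_holdout_prepared: list
    vocab: FragmentVocabulary
    label_pairs: list  # (molecule, float label) on the non-canonical corpus


def top_frequent_keys(vocab: FragmentVocabulary, k: int = 2) -> list[str]:
    """Most frequent non-reserved vocabulary keys (freq desc, key asc)."""
    reserved = set(vocab.reserved_keys)
    ranked = sorted(
        ((key, idf[1]) for key, idf in vocab.entries.items() if key not in reserved),
        key=lambda t: (-t[1], t[0]),
    )
    return [key for key, _ in ranked[:k]]


def linear_fragment_labels(
    mols: list, vocab: FragmentVocabulary, keys: list[str],
    rel_noise: float, seed: int,
) -> np.ndarray:
    """Unit-weight linear fragment-count labels with noise at ``rel_noise``
    times the clean-signal standard deviation."""
    clean = np.array(
        [sum(fragment(m, "adafrag", vocab).fragment_keys.count(k) for k in keys) for m in mols],
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    sd = clean.std()
    if rel_noise > 0 and sd > 0:
        clean = clean + rng.normal(0.0, rel_noise * sd, size=len(mols))
    return clean


def build_ablation_data(seed: int, settings: AblationSettings) -> AblationData:
    """Fixed study corpora: canonical stage-1, mixed non-canonical stage-2,
    a non-canonical held-out evaluation set, and probe labels."""
    lib = builtin_library()
    canonical_pool = tuple(lib.codes(canonical=True))
    mixed_pool = tuple(lib.codes())
    c1 = [m for _, _, m in generate_corpus(
        CorpusSpec(n_molecules=settings.n_canonical, min_length=settings.min_length,
                   max_length=settings.max_length, monomer_pool=canonical_pool, seed=seed), lib)]
    c2 = [m for _, _, m in generate_corpus(
        CorpusSpec(n_molecules=settings.n_noncanonical, min_length=settings.min_length,
                   max_length=settings.max_length, monomer_pool=mixed_pool, seed=seed + 1), lib)]
    hold = [m for _, _, m in generate_corpus(
        CorpusSpec(n_molecules=settings.n_holdout, min_length=settings.min_length,
                   max_length=settings.max_length, monomer_pool=mixed_pool, seed=seed + 2), lib)]
    vocab = learn_vocabulary(c1 + c2)
    keys = top_frequent_keys(vocab, k=2)
    labels = linear_fragment_labels(c2, vocab, keys, settings.label_rel_noise, seed + 3)
    return AblationData(
        canonical=c1,
        noncanonical=c2,
        nc_holdout_prepared=prepare_corpus(hold, vocab),
        vocab=vocab,
        label_pairs=list(zip(c2, labels.tolist())),
    )


def nc_fragment_accuracy(
    params, data: AblationData, model_cfg: ModelConfig, eval_seed: int = 12345
) -> float:
    """Masked-fragment accuracy on the non-canonical held-out set
    (fragment-strategy evaluation masks fixed by seed)."""
    eval_cfg = PretrainConfig(strategy="fragment")
    entry = _evaluate(data.nc_holdout_prepared, params, model_cfg, eval_cfg, eval_seed)
    return float(entry["frag_accuracy"] or 0.0)


def pretrain_condition(
    data: AblationData,
    strategy: str,
    two_stage: bool,
    seed: int,
    settings: AblationSettings,
) -> tuple[dict, float]:
    """Pretrain one (masking, schedule) condition; returns params and the
    non-canonical held-out masked-fragment accuracy."""
    model_cfg = ModelConfig(hidden_dim=settings.hidden_dim, n_layers=settings.n_layers, seed=seed)
    pre_cfg = PretrainConfig(
        strategy=strategy, epochs_stage1=settings.epochs_stage1,
        epochs_stage2=settings.epochs_stage2, seed=seed,
    )
    params, info = two_stage_pretrain(
        data.canonical, data.noncanonical, data.vocab, pre_cfg, model_cfg,
        one_stage_only=not two_stage,
    )
    chosen = params if two_stage else info["stage1_checkpoint"]
    return chosen, nc_fragment_accuracy(chosen, data, model_cfg)


def probe_readout(
    params, data: AblationData, settings: AblationSettings,
    pooling: str, fusion: str, seed: int,
) -> float:
    """Frozen-probe Spearman of a (pooling, fusion) readout on the
    linear fragment-count task."""
    model_cfg = ModelConfig(
        hidden_dim=settings.hidden_dim, n_layers=settings.n_layers,
        pooling=pooling, fusion=fusion, seed=seed,
    )
    fin_cfg = FinetuneConfig(
        task="regression", mode="frozen_probe", epochs=settings.probe_epochs, seed=seed
    )
    _, metrics = finetune(data.label_pairs, data.vocab, params, model_cfg, fin_cfg)
    return float(metrics["spearman"])


def run_ablation(seed: int = 0, quick: bool = False,
                 settings: AblationSettings | None = None) -> list[dict]:
    """Full sweep over masking x schedule x pooling x fusion (4x2x3x3 rows)."""
    settings = settings or (AblationSettings.quick() if quick else AblationSettings())
    data = build_ablation_data(seed, settings)
    rows: list[dict] = []
    for strategy in STRATEGIES:
        for two_stage in (False, True):
            params, acc = pretrain_condition(data, strategy, two_stage, seed, settings)
            for pooling in POOLINGS:
                for fusion in FUSIONS:
                    rho = probe_readout(params, data, settings, pooling, fusion, seed)
                    rows.append({
                        "masking": strategy,
                        "stages": "two" if two_stage else "one",
                        "pooling": pooling,
                        "fusion": fusion,
                        "frag_accuracy": acc,
                        "spearman": rho,
                    })
    return rows
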