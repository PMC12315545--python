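"""Heterogeneous message passing, view fusion, pooling and embeddings.

Four node-embedding variants are computed with shared layer weights:

* **A** — atoms propagated over atom–atom bond edges only;
* **F** — fragments propagated over fragment–fragment edges only;
* **AJ** — atom states after joint propagation over bond *and* junction
  edges (fragment context flows into atoms);
* **FJ** — fragment states after the same joint propagation.

A fusion strategy picks the (atom-side, fragment-side) pair — A&F, AJ&F
or AJ&FJ — each side is pooled independently (max, average, or a gated
recurrent unit over the canonical node order) and the two pooled vectors
are concatenated into the graph embedding of length ``2 × hidden_dim``.

Each message-passing layer applies a per-edge-type linear transform to the
source state (bond-feature embeddings are added on bond edges), sums
incoming messages per node, and applies a shared linear update with a
residual connection and ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import ConfigError
from .graph import (
    HeteroGraph,
    N_BOND_ORDERS,
    N_CHARGE,
    N_CHIRAL,
    N_DEGREE,
    N_ELEMENT_CLASSES,
    N_HS,
)
from .nn import Tensor

FUSIONS = ("A_F", "AJ_F", "AJ_FJ")
POOLINGS = ("max", "avg", "gru")


@dataclass
class ModelConfig:
    hidden_dim: int = 128
    n_layers: int = 3
    fusion: str = "AJ_FJ"
    pooling: str = "gru"
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim <= 0:
            raise ConfigError("hidden_dim must be positive")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if self.fusion not in FUSIONS:
            raise ConfigError(f"fusion must be one of {FUSIONS}, got {self.fusion!r}")
        if self.pooling not in POOLINGS:
            raise ConfigError(f"pooling must be one of {POOLINGS}, got {self.pooling!r}")


@dataclass
class EmbeddingResult:
    atom_embeddings: np.ndarray
    fragment_embeddings: np.ndarray
    graph_embedding: np.ndarray


def _gru_param_names(side: str) -> list[str]:
    return [f"pool/{side}/{g}{m}" for g in ("z", "r", "h") for m in ("W", "U", "b")]


def init_params(
    config: ModelConfig, vocab_size: int, rng: np.random.Generator
) -> dict[str, Tensor]:
    """Initialize all trainable parameters from a seeded generator.

    Output-head weights start small so initial logits are near-uniform.
    """
    h = config.hidden_dim
    p: dict[str, Tensor] = {}

    def table(name: str, rows: int, scale: float = 0.1) -> None:
        p[name] = nn.parameter(rng.normal(0.0, scale, size=(rows, h)))

    def weight(name: str, d_in: int, d_out: int, scale: float | None = None) -> None:
        s = scale if scale is not None else 1.0 / np.sqrt(d_in)
        p[name] = nn.parameter(rng.normal(0.0, s, size=(d_in, d_out)))

    table("emb/elem", N_ELEMENT_CLASSES + 1)  # +1: reserved MASK class
    table("emb/deg", N_DEGREE)
    table("emb/charge", N_CHARGE)
    table("emb/arom", 2)
    table("emb/hs", N_HS)
    table("emb/chiral", N_CHIRAL)
    table("emb/frag", vocab_size + 1)  # last row: reserved MASK id
    table("emb/bond_order", N_BOND_ORDERS)
    table("emb/bond_conj", 2)
    table("emb/bond_ring", 2)

    for layer in range(config.n_layers):
        for name in ("W_aa", "W_ff", "W_af", "W_fa", "W_upd_atom", "W_upd_frag"):
            weight(f"layer{layer}/{name}", h, h)
        p[f"layer{layer}/b_atom"] = nn.parameter(np.zeros((1, h)))
        p[f"layer{layer}/b_frag"] = nn.parameter(np.zeros((1, h)))

    weight("head/atom_out", h, N_ELEMENT_CLASSES, scale=0.01)
    p["head/atom_out_b"] = nn.parameter(np.zeros((1, N_ELEMENT_CLASSES)))
    weight("head/frag_out", h, vocab_size, scale=0.01)
    p["head/frag_out_b"] = nn.parameter(np.zeros((1, vocab_size)))

    for side in ("atom", "frag"):
        for g in ("z", "r", "h"):
            weight(f"pool/{side}/{g}W", h, h)
            weight(f"pool/{side}/{g}U", h, h)
            p[f"pool/{side}/{g}b"] = nn.parameter(np.zeros((1, h)))
    return p


def _input_states(
    graph: HeteroGraph, params: dict[str, Tensor]
) -> tuple[Tensor, Tensor]:
    feats = graph.atom_features
    h_atom = nn.gather_rows(params["emb/elem"], feats[:, 0])
    for col, name in ((1, "emb/deg"), (2, "emb/charge"), (3, "emb/arom"),
                      (4, "emb/hs"), (5, "emb/chiral")):
        h_atom = h_atom + nn.gather_rows(params[name], feats[:, col])
    # masked fragments carry the -1 sentinel, which indexes the last
    # (reserved MASK) row of the fragment embedding table
    h_frag = nn.gather_rows(params["emb/frag"], graph.fragment_ids)
    return h_atom, h_frag


def _bond_embeddings(graph: HeteroGraph, params: dict[str, Tensor]) -> Tensor:
    bf = graph.bond_features
    out = nn.gather_rows(params["emb/bond_order"], bf[:, 0])
    out = out + nn.gather_rows(params["emb/bond_conj"], bf[:, 1])
    out = out + nn.gather_rows(params["emb/bond_ring"], bf[:, 2])
    return out


def _propagate(
    graph: HeteroGraph,
    params: dict[str, Tensor],
    config: ModelConfig,
    use_junction: bool,
    atom_side: bool = True,
    frag_side: bool = True,
) -> tuple[Tensor | None, Tensor | None]:
    """Run ``n_layers`` of typed message passing; returns final states."""
    h_atom, h_frag = _input_states(graph, params)
    if not atom_side:
        h_atom = None
    if not frag_side:
        h_frag = None
    bond_emb = _bond_embeddings(graph, params) if atom_side else None
    na, nf = graph.n_atoms, graph.n_fragments

    for layer in range(config.n_layers):
        new_atom, new_frag = h_atom, h_frag
        if h_atom is not None:
            agg_a: Tensor | None = None
            if graph.edges_aa.shape[1] > 0:
                src = nn.gather_rows(h_atom, graph.edges_aa[0])
                msg = (src + bond_emb) @ params[f"layer{layer}/W_aa"]
                agg_a = nn.scatter_sum(msg, graph.edges_aa[1], na)
            if use_junction and h_frag is not None:
                src_f = nn.gather_rows(h_frag, graph.edges_junction_fa[0])
                msg_fa = src_f @ params[f"layer{layer}/W_fa"]
                contrib = nn.scatter_sum(msg_fa, graph.edges_junction_fa[1], na)
                agg_a = contrib if agg_a is None else agg_a + contrib
            if agg_a is not None:
                upd = agg_a @ params[f"layer{layer}/W_upd_atom"] + params[f"layer{layer}/b_atom"]
                new_atom = nn.relu(h_atom + upd)
        if h_frag is not None:
            agg_f: Tensor | None = None
            if graph.edges_ff.shape[1] > 0:
                src = nn.gather_rows(h_frag, graph.edges_ff[0])
                msg = src @ params[f"layer{layer}/W_ff"]
                agg_f = nn.scatter_sum(msg, graph.edges_ff[1], nf)
            if use_junction and h_atom is not None:
                src_a = nn.gather_rows(h_atom, graph.edges_junction_af[0])
                msg_af = src_a @ params[f"layer{layer}/W_af"]
                contrib = nn.scatter_sum(msg_af, graph.edges_junction_af[1], nf)
                agg_f = contrib if agg_f is None else agg_f + contrib
            if agg_f is not None:
                upd = agg_f @ params[f"layer{layer}/W_upd_frag"] + params[f"layer{layer}/b_frag"]
                new_frag = nn.relu(h_frag + upd)
        h_atom, h_frag = new_atom, new_frag
    return h_atom, h_frag


def forward_views(
    graph: HeteroGraph, params: dict[str, Tensor], config: ModelConfig
) -> dict[str, Tensor]:
    """Node-state variants A, F (within-view) and AJ, FJ (joint propagation)."""
    a_only, _ = _propagate(graph, params, config, use_junction=False, frag_side=False)
    _, f_only = _propagate(graph, params, config, use_junction=False, atom_side=False)
    aj, fj = _propagate(graph, params, config, use_junction=True)
    return {"A": a_only, "F": f_only, "AJ": aj, "FJ": fj}


def _gru_pool(x: Tensor, params: dict[str, Tensor], side: str) -> Tensor:
    h = Tensor(np.zeros((1, x.shape[1])))
    for t in range(x.shape[0]):
        xt = nn.gather_rows(x, np.array([t]))
        z = nn.sigmoid(xt @ params[f"pool/{side}/zW"] + h @ params[f"pool/{side}/zU"] + params[f"pool/{side}/zb"])
        r = nn.sigmoid(xt @ params[f"pool/{side}/rW"] + h @ params[f"pool/{side}/rU"] + params[f"pool/{side}/rb"])
        cand = nn.tanh(xt @ params[f"pool/{side}/hW"] + (r * h) @ params[f"pool/{side}/hU"] + params[f"pool/{side}/hb"])
        one = Tensor(np.ones_like(z.data))
        h = (one - z) * h + z * cand
    return h


def pool(
    node_vectors: Tensor | np.ndarray,
    method: str,
    params: dict[str, Tensor] | None = None,
    side: str = "atom",
) -> Tensor:
    """Aggregate node vectors (in canonical node order) into one vector.

    ``max``/``avg`` are elementwise and order-invariant; ``gru`` runs a
    single-layer gated recurrent pass from a zero initial state over the
    given order and returns the final hidden state.
    """
    x = node_vectors if isinstance(node_vectors, Tensor) else Tensor(node_vectors)
    if x.shape[0] == 0:
        raise ValueError("cannot pool an empty node set")
    if method == "max":
        return nn.max_rows(x)
    if method == "avg":
        return nn.mean_rows(x)
    if method == "gru":
        if params is None:
            raise ValueError("gru pooling requires recurrent parameters")
        out = _gru_pool(x, params, side)
        return nn.gather_rows(out, np.asarray(0))  # final state as a flat vector
    raise ValueError(f"unknown pooling method {method!r}")


def graph_embedding_tensors(
    graph: HeteroGraph,
    params: dict[str, Tensor],
    config: ModelConfig,
    views: dict[str, Tensor] | None = None,
) -> tuple[Tensor, Tensor, Tensor]:
    """(atom-side states, fragment-side states, pooled graph embedding)."""
    if views is None:
        views = forward_views(graph, params, config)
    atom_key, frag_key = {
        "A_F": ("A", "F"),
        "AJ_F": ("AJ", "F"),
        "AJ_FJ": ("AJ", "FJ"),
    }[config.fusion]
    h_atom, h_frag = views[atom_key], views[frag_key]
    h_atom_ord = nn.gather_rows(h_atom, graph.atom_canonical_order)
    pooled_a = pool(h_atom_ord, config.pooling, params, side="atom")
    pooled_f = pool(h_frag, config.pooling, params, side="frag")
    emb = nn.concat([pooled_a, pooled_f], axis=0)
    return h_atom, h_frag, emb


def encode(
    graph: HeteroGraph, params: dict[str, Tensor], config: ModelConfig
) -> EmbeddingResult:
    """Deterministic embedding of one molecule graph.

    ``graph_embedding`` has length ``2 × hidden_dim``: pooled atom-side and
    fragment-side representations, concatenated.
    """
    h_atom, h_frag, emb = graph_embedding_tensors(graph, params, config)
    vec = emb.data.reshape(-1)
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError("non-finite graph embedding")
    return EmbeddingResult(
        atom_embeddings=h_atom.data.copy(),
        fragment_embeddings=h_frag.data.copy(),
        graph_embedding=vec.copy(),
    )


def save_params(params: dict[str, Tensor], path) -> None:
    np.savez(path, **{k: p.data for k, p in params.items()})


def load_params(path) -> dict[str, Tensor]:
    blob = np.load(path)
    return {k: nn.parameter(blob[k]) for k in blob.files}
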