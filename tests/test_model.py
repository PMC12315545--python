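"""Encoder: pooling oracles, fusion behaviour, determinism, metrics."""

import numpy as np
import pytest

from peplearn.errors import ConfigError, MetricError
from peplearn.fragment import adafrag_fragment
from peplearn.graph import build_heterograph
from peplearn.metrics import auc, spearman
from peplearn.model import ModelConfig, encode, init_params, pool
from peplearn.nn import Tensor


@pytest.fixture(scope="module")
def encoded_setup(mixed_corpus, mixed_vocab):
    cfg = ModelConfig(hidden_dim=16, n_layers=2, seed=0)
    rng = np.random.default_rng(0)
    params = init_params(cfg, mixed_vocab.size, rng)
    mol = mixed_corpus[0]
    frag = adafrag_fragment(mol, mixed_vocab)
    graph = build_heterograph(mol, frag, mixed_vocab)
    return cfg, params, graph


class TestPooling:
    def test_avg_and_max_hand_values(self):
        x = np.array([[1.0, 3.0], [3.0, 5.0]])
        assert np.allclose(pool(x, "avg").data, [2.0, 4.0])
        assert np.allclose(pool(x, "max").data, [3.0, 5.0])

    def test_gru_single_vector_matches_hand_rolled_recurrence(self):
        """One GRU step from zero state, recomputed with plain NumPy."""
        rng = np.random.default_rng(3)
        h = 4
        from peplearn import nn as pnn

        params = {}
        for g in ("z", "r", "h"):
            params[f"pool/atom/{g}W"] = pnn.parameter(rng.normal(size=(h, h)))
            params[f"pool/atom/{g}U"] = pnn.parameter(rng.normal(size=(h, h)))
            params[f"pool/atom/{g}b"] = pnn.parameter(rng.normal(size=(1, h)))
        x = rng.normal(size=(1, h))
        out = pool(x, "gru", params, side="atom").data

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        h0 = np.zeros((1, h))
        z = sig(x @ params["pool/atom/zW"].data + h0 @ params["pool/atom/zU"].data + params["pool/atom/zb"].data)
        r = sig(x @ params["pool/atom/rW"].data + h0 @ params["pool/atom/rU"].data + params["pool/atom/rb"].data)
        cand = np.tanh(x @ params["pool/atom/hW"].data + (r * h0) @ params["pool/atom/hU"].data + params["pool/atom/hb"].data)
        expected = ((1 - z) * h0 + z * cand).reshape(-1)
        assert np.allclose(out, expected)

    def test_permutation_invariance_of_max_and_avg(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(7, 5))
        perm = rng.permutation(7)
        for method in ("max", "avg"):
            assert np.allclose(pool(x, method).data, pool(x[perm], method).data)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool(np.zeros((0, 3)), "avg")

    def test_gru_requires_params(self):
        with pytest.raises(ValueError):
            pool(np.zeros((2, 3)), "gru")


class TestEncode:
    def test_deterministic(self, encoded_setup):
        cfg, params, graph = encoded_setup
        a = encode(graph, params, cfg).graph_embedding
        b = encode(graph, params, cfg).graph_embedding
        assert np.array_equal(a, b)
        assert a.shape == (2 * cfg.hidden_dim,)

    def test_embeddings_finite_over_corpus(self, mixed_corpus, mixed_vocab):
        cfg = ModelConfig(hidden_dim=16, n_layers=2)
        params = init_params(cfg, mixed_vocab.size, np.random.default_rng(1))
        for mol in mixed_corpus[:10]:
            frag = adafrag_fragment(mol, mixed_vocab)
            g = build_heterograph(mol, frag, mixed_vocab)
            res = encode(g, params, cfg)
            assert np.all(np.isfinite(res.graph_embedding))
            assert np.all(np.isfinite(res.atom_embeddings))
            assert np.all(np.isfinite(res.fragment_embeddings))

    @pytest.mark.parametrize("seed", range(5))
    def test_fusion_changes_embedding(self, mixed_corpus, mixed_vocab, seed):
        """Junction messages perturb atom states: A&F differs from AJ&FJ."""
        mol = mixed_corpus[seed]
        frag = adafrag_fragment(mol, mixed_vocab)
        g = build_heterograph(mol, frag, mixed_vocab)
        params = init_params(ModelConfig(hidden_dim=16), mixed_vocab.size,
                             np.random.default_rng(seed))
        emb_af = encode(g, params, ModelConfig(hidden_dim=16, fusion="A_F")).graph_embedding
        emb_ajfj = encode(g, params, ModelConfig(hidden_dim=16, fusion="AJ_FJ")).graph_embedding
        assert not np.allclose(emb_af, emb_ajfj)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_layers=0)
        with pytest.raises(ConfigError):
            ModelConfig(hidden_dim=0)
        with pytest.raises(ConfigError):
            ModelConfig(fusion="AF")


class TestMetrics:
    def test_spearman_concordant_discordant(self):
        assert spearman([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_spearman_hand_computed(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (2,-1,-1) -> 1 - 36/24 = -0.5
        assert spearman([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_spearman_constant_input_error(self):
        with pytest.raises(MetricError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_auc_examples(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)
        assert auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == pytest.approx(0.5)
        # pairs: (0.35 vs 0.1, 0.4), (0.8 vs 0.1, 0.4): 3 of 4 concordant
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_auc_single_class_error(self):
        with pytest.raises(MetricError):
            auc([0.1, 0.2], [1, 1])
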