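"""Global population model: snowball blocks, fusion, classification."""

import numpy as np
import pytest

from neurofuse.global_model import (GlobalConfig, Snowball, SubjectGnn,
                                    dense_laplacian, laplacian_tensor)
from neurofuse.nn import Tensor, softmax
from neurofuse.nn.autodiff import use_dtype
from neurofuse.population import SubjectGraph

from _oracles import snowball_naive


def _config(**kw):
    base = dict(channel_dims={"functional": 6, "structural": 4,
                              "demographic": 3},
                n_sites=2, snowball_layers=2, layer_width=4,
                collapse_width=5, embedding_dim=3, mc_projection=4)
    base.update(kw)
    return GlobalConfig(**base)


def _graph_inputs(rng, s=8):
    w = rng.uniform(0, 1, size=(s, s))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


class TestSnowball:
    def test_matches_hand_computed_oracle(self):
        rng = np.random.default_rng(0)
        with use_dtype(np.float64):
            config = _config(snowball_layers=2)
            block = Snowball(3, config, np.random.default_rng(1))
            w = _graph_inputs(rng, 4)
            lap = dense_laplacian(w).astype(np.float64)
            x = rng.normal(size=(4, 3))
            out = block(Tensor(lap), Tensor(x)).data
            expected = snowball_naive(
                lap, x,
                [l.weight.data for l in block.layer_weights],
                [l.bias.data for l in block.layer_weights],
                block.collapse.weight.data, block.collapse.bias.data,
                block.out.weight.data, block.out.bias.data, p=0)
        assert np.abs(out - expected).max() < 1e-9

    def test_p_flag_adds_one_laplacian_multiplication(self):
        rng = np.random.default_rng(2)
        with use_dtype(np.float64):
            config = _config()
            block = Snowball(3, config, np.random.default_rng(3))
            w = _graph_inputs(rng, 5)
            lap = dense_laplacian(w).astype(np.float64)
            x = rng.normal(size=(5, 3))
            block.p = 1
            out_p1 = block(Tensor(lap), Tensor(x)).data
            expected = snowball_naive(
                lap, x,
                [l.weight.data for l in block.layer_weights],
                [l.bias.data for l in block.layer_weights],
                block.collapse.weight.data, block.collapse.bias.data,
                block.out.weight.data, block.out.bias.data, p=1)
        assert np.abs(out_p1 - expected).max() < 1e-9

    def test_output_rows_unit_norm(self, rng):
        config = _config()
        block = Snowball(6, config, np.random.default_rng(4))
        lap = dense_laplacian(_graph_inputs(rng))
        out = block(Tensor(lap), Tensor(rng.normal(size=(8, 6))
                                        .astype(np.float32))).data
        assert np.abs(np.linalg.norm(out, axis=1) - 1).max() < 1e-5

    def test_layer_count_validated(self):
        with pytest.raises(ValueError):
            _config(snowball_layers=0)


class TestBlocks:
    def _inputs(self, rng, dims, s=8):
        w = _graph_inputs(rng, s)
        laps = {ch: Tensor(dense_laplacian(w)) for ch in dims}
        feats = {ch: rng.normal(size=(s, d)).astype(np.float32)
                 for ch, d in dims.items()}
        return laps, feats

    def test_ms_independent_weights_differ(self, rng):
        dims = {"functional": 5, "structural": 5, "demographic": 5}
        model = SubjectGnn(_config(channel_dims=dims),
                           np.random.default_rng(5))
        laps, feats = self._inputs(rng, dims)
        shared_feat = feats["functional"]
        same = {ch: shared_feat for ch in dims}
        out = model.ms_gcn(laps, same)
        assert not np.allclose(out["functional"].data, out["structural"].data)

    def test_ms_equals_direct_snowball_calls(self, rng):
        dims = {"functional": 5, "structural": 4, "demographic": 3}
        model = SubjectGnn(_config(channel_dims=dims),
                           np.random.default_rng(6))
        laps, feats = self._inputs(rng, dims)
        out = model.ms_gcn(laps, feats)
        for ch in dims:
            direct = model.ms_blocks[ch](laps[ch], Tensor(feats[ch]))
            assert np.array_equal(out[ch].data, direct.data)

    def test_mc_identical_channels_identical_commons(self, rng):
        dims = {"functional": 5, "structural": 5, "demographic": 5}
        model = SubjectGnn(_config(channel_dims=dims),
                           np.random.default_rng(7))
        # identical projections so the shared trunk sees identical inputs
        for ch in dims:
            model.mc_projections[ch].load_state_dict(
                model.mc_projections["functional"].state_dict())
        laps, feats = self._inputs(rng, dims)
        same = {ch: feats["functional"] for ch in dims}
        per_channel, common = model.mc_gcn(laps, same)
        for ch in dims:
            assert np.allclose(per_channel[ch].data,
                               per_channel["functional"].data, atol=1e-6)
        assert np.allclose(common.data, per_channel["functional"].data,
                           atol=1e-6)

    def test_mc_weights_equal_and_validated(self, rng):
        dims = {"functional": 4, "structural": 4, "demographic": 4}
        model = SubjectGnn(_config(channel_dims=dims),
                           np.random.default_rng(8))
        assert all(w == pytest.approx(1 / 3) for w in model.mc_weights.values())
        with pytest.raises(ValueError, match="sum to 1"):
            SubjectGnn(_config(channel_dims=dims), np.random.default_rng(9),
                       mc_weights={ch: 1.0 for ch in dims})

    def test_shared_trunk_gradient_from_every_channel(self, rng):
        """Finite differences confirm the shared collapse weight's gradient
        sums contributions from all channels: perturbing one channel's
        input changes the shared gradient."""
        dims = {"functional": 3, "structural": 3, "demographic": 3}
        with use_dtype(np.float64):
            model = SubjectGnn(_config(channel_dims=dims, snowball_layers=1),
                               np.random.default_rng(10))
            laps, feats = self._inputs(rng, dims, s=5)

            def shared_grad(features):
                for p in model.parameters():
                    p.grad = None
                _, common = model.mc_gcn(laps, features)
                (common ** 2).sum().backward()
                return model.mc_trunk.collapse.weight.grad.copy()

            g1 = shared_grad(feats)
            bumped = dict(feats)
            bumped["structural"] = feats["structural"] + 0.5
            g2 = shared_grad(bumped)
            assert np.abs(g1 - g2).max() > 1e-6

            # numeric check of the shared-weight gradient itself
            w = model.mc_trunk.collapse.weight
            g_auto = shared_grad(feats)
            eps = 1e-6
            idx = (0, 0)
            orig = w.data[idx]
            w.data[idx] = orig + eps
            _, c_plus = model.mc_gcn(laps, feats)
            w.data[idx] = orig - eps
            _, c_minus = model.mc_gcn(laps, feats)
            w.data[idx] = orig
            numeric = (float((c_plus ** 2).sum().data)
                       - float((c_minus ** 2).sum().data)) / (2 * eps)
            assert g_auto[idx] == pytest.approx(numeric, abs=1e-5)


class TestAttentionAndClassifier:
    def test_identical_embeddings_equal_scores(self, rng):
        dims = {"functional": 4, "structural": 4, "demographic": 4}
        model = SubjectGnn(_config(channel_dims=dims),
                           np.random.default_rng(11))
        for name in model.attention_heads:
            model.attention_heads[name].load_state_dict(
                model.attention_heads["common"].state_dict())
        h = Tensor(rng.normal(size=(6, 3)).astype(np.float32))
        fused, scores, order = model.m_attention(
            {ch: h for ch in dims}, h)
        assert np.abs(scores.data - 0.25).max() < 1e-6
        assert np.allclose(fused.data, h.data, atol=1e-6)

    def test_scores_sum_to_one_per_node(self, rng):
        dims = {"functional": 4, "structural": 4, "demographic": 4}
        model = SubjectGnn(_config(channel_dims=dims),
                           np.random.default_rng(12))
        specific = {ch: Tensor(rng.normal(size=(6, 3)).astype(np.float32))
                    for ch in dims}
        _, scores, _ = model.m_attention(
            specific, Tensor(rng.normal(size=(6, 3)).astype(np.float32)))
        assert np.abs(scores.data.sum(axis=1) - 1).max() < 1e-6

    def test_scalar_fusion_hand_oracle(self):
        """1-dim embeddings with hand-set attention weights reproduce the
        scalar softmax combination."""
        dims = {"functional": 1, "structural": 1, "demographic": 1}
        with use_dtype(np.float64):
            model = SubjectGnn(
                _config(channel_dims=dims, embedding_dim=1, attention_dim=1),
                np.random.default_rng(13))
            values = {"functional": 2.0, "structural": -1.0,
                      "demographic": 0.5}
            embeddings = {ch: Tensor(np.array([[v]]))
                          for ch, v in values.items()}
            common = Tensor(np.array([[1.0]]))
            for i, name in enumerate(model.channels + ["common"]):
                model.attention_heads[name].weight.data = np.array([[0.3 * (i + 1)]])
                model.attention_heads[name].bias.data = np.array([0.1 * i])
            fused, scores, order = model.m_attention(embeddings, common)
        vals = {**values, "common": 1.0}
        logits = [np.tanh(0.3 * (i + 1) * vals[n] + 0.1 * i)
                  for i, n in enumerate(order)]
        e = np.exp(logits - np.max(logits))
        att = e / e.sum()
        expected = sum(a * vals[n] for a, n in zip(att, order))
        assert np.abs(scores.data[0] - att).max() < 1e-9
        assert fused.data[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        dims = {"functional": 4, "structural": 4, "demographic": 4}
        model = SubjectGnn(_config(channel_dims=dims),
                           np.random.default_rng(14))
        specific = {ch: Tensor(rng.normal(size=(6, 3)).astype(np.float32))
                    for ch in dims}
        with pytest.raises(ValueError, match="shape mismatch"):
            model.m_attention(specific,
                              Tensor(rng.normal(size=(6, 2)).astype(np.float32)))

    def test_classifier_probabilities(self, rng):
        dims = {"functional": 4, "structural": 4, "demographic": 4}
        model = SubjectGnn(_config(channel_dims=dims),
                           np.random.default_rng(15))
        h = rng.normal(size=(5, 3)).astype(np.float32)
        h[1] = h[0]
        probs = softmax(model.classify(Tensor(h)), axis=-1).data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0
        assert np.allclose(probs[0], probs[1])


class TestFullModel:
    def test_subject_permutation_invariance(self, rng):
        """Conjugating the node order permutes the logits identically."""
        dims = {"functional": 5, "structural": 4, "demographic": 3}
        s = 10
        with use_dtype(np.float64):
            model = SubjectGnn(_config(channel_dims=dims),
                               np.random.default_rng(16), eta_dim=3)
            w = {ch: _graph_inputs(rng, s) for ch in dims}
            feats = {ch: rng.normal(size=(s, d)) for ch, d in dims.items()}
            support = np.ones((s, s), dtype=bool)
            np.fill_diagonal(support, False)

            def forward(perm):
                laps = {}
                for ch in ("functional", "structural"):
                    laps[ch] = Tensor(dense_laplacian(
                        w[ch][perm][:, perm].astype(np.float64)))
                graph = SubjectGraph(
                    node_features=feats["demographic"][perm],
                    weights=np.zeros((s, s)), channel="demographic",
                    support=support)
                laps["demographic"] = model.channel_laplacian(graph)
                f = {ch: feats[ch][perm] for ch in dims}
                _, logits = model(laps, f)
                return logits.data

            ident = forward(np.arange(s))
            perm = np.random.default_rng(17).permutation(s)
            assert np.abs(forward(perm) - ident[perm]).max() < 1e-9

    def test_channel_mismatch_rejected(self, rng):
        dims = {"functional": 4, "structural": 4, "demographic": 4}
        model = SubjectGnn(_config(channel_dims=dims),
                           np.random.default_rng(18))
        with pytest.raises(ValueError, match="channel mismatch"):
            model.ms_gcn({}, {})


def test_laplacian_tensor_matches_dense(rng):
    w = _graph_inputs(rng, 6).astype(np.float32)
    dense = dense_laplacian(w)
    diff = laplacian_tensor(Tensor(w)).data - dense
    assert np.abs(diff).max() < 1e-6
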