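"""The composite objective: cross-entropy, HSIC, Gram similarity, domain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofuse import nn
from neurofuse.losses import (classification_loss, cmd_loss, cross_entropy,
                              hsic, modality_similarity_loss,
                              modality_specific_loss, site_adversarial_loss,
                              total_loss)
from neurofuse.nn import MLP, Tensor, grad_reverse
from neurofuse.nn.autodiff import use_dtype

from _oracles import cmd_naive, cross_entropy_naive, hsic_trace


class TestCrossEntropy:
    def test_perfect_confident_predictions_vanish(self):
        logits = Tensor(np.array([[30.0, -30.0], [-30.0, 30.0]],
                                 dtype=np.float32))
        loss = cross_entropy(logits, np.array([0, 1]))
        assert float(loss.data) < 1e-6

    def test_matches_naive_log_softmax(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(3, 2))
        targets = np.array([0, 1, 1])
        with use_dtype(np.float64):
            ours = float(cross_entropy(Tensor(logits), targets).data)
        assert ours == pytest.approx(cross_entropy_naive(logits, targets),
                                     abs=1e-10)

    def test_lambda_weighting(self):
        rng = np.random.default_rng(1)
        g = Tensor(rng.normal(size=(4, 2)).astype(np.float32))
        l = Tensor(rng.normal(size=(4, 2)).astype(np.float32))
        labels = np.array([0, 1, 0, 1])
        mask = np.arange(4)
        total0, ce_g, _ = classification_loss(g, l, labels, mask, 0.0)
        assert float(total0.data) == pytest.approx(float(ce_g.data))
        total2, ce_g, ce_l = classification_loss(g, l, labels, mask, 0.2)
        assert float(total2.data) == pytest.approx(
            float(ce_g.data) + 0.2 * float(ce_l.data), abs=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cross_entropy(Tensor(np.zeros((3, 2))), np.zeros(3, dtype=int),
                          np.zeros(3, dtype=bool))


class TestHsic:
    def test_constant_channel_gives_zero(self, rng):
        hs = rng.normal(size=(10, 4))
        hc = np.full((10, 2), 3.3)
        with use_dtype(np.float64):
            assert abs(float(hsic(hs, hc).data)) < 1e-12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_trace_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hs = rng.normal(size=(6, 3))
        hc = rng.normal(size=(6, 4))
        with use_dtype(np.float64):
            ours = float(hsic(hs, hc).data)
        assert ours == pytest.approx(hsic_trace(hs, hc), abs=1e-10)

    def test_joint_row_permutation_invariant(self, rng):
        hs = rng.normal(size=(8, 3))
        hc = rng.normal(size=(8, 3))
        perm = np.random.default_rng(1).permutation(8)
        with use_dtype(np.float64):
            a = float(hsic(hs, hc).data)
            b = float(hsic(hs[perm], hc[perm]).data)
        assert a == pytest.approx(b, abs=1e-10)

    def test_gaussian_kernel_nonnegative(self, rng):
        hs = rng.normal(size=(7, 3))
        hc = rng.normal(size=(7, 3))
        val = float(hsic(hs, hc, kernel="gaussian").data)
        assert val >= -1e-7

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hsic(np.zeros((1, 2)), np.zeros((1, 2)))


class TestModalityLosses:
    def test_specific_is_sum_of_hsic_terms(self, rng):
        specific = {ch: rng.normal(size=(6, 3)) for ch in ("a", "b", "c")}
        common = rng.normal(size=(6, 3))
        with use_dtype(np.float64):
            total = float(modality_specific_loss(specific, Tensor(common)).data)
            parts = sum(float(hsic(h, common).data)
                        for h in specific.values())
        assert total == pytest.approx(parts, abs=1e-10)

    def test_orthogonal_constructed_specifics_near_zero(self):
        """Specific embeddings orthogonal (after centering) to the common
        one have vanishing linear-kernel HSIC."""
        m = 6
        common = np.zeros((m, 2))
        common[:, 0] = [1, -1, 1, -1, 0, 0]
        specific = np.zeros((m, 2))
        specific[:, 0] = [1, 1, -1, -1, 0, 0]  # centered and orthogonal
        with use_dtype(np.float64):
            val = float(hsic(specific, common).data)
        assert abs(val) < 1e-10

    def test_single_channel_single_term(self, rng):
        h = rng.normal(size=(5, 2))
        c = rng.normal(size=(5, 2))
        with use_dtype(np.float64):
            total = float(modality_specific_loss({"only": h}, Tensor(c)).data)
        assert total == pytest.approx(hsic_trace(h, c), abs=1e-10)

    def test_identical_commons_zero_similarity_loss(self, rng):
        h = rng.normal(size=(5, 3))
        commons = {"functional": h, "structural": h.copy(),
                   "demographic": h.copy()}
        with use_dtype(np.float64):
            val = float(modality_similarity_loss(commons).data)
        assert val < 1e-5

    def test_two_subject_gram_difference_oracle(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        b = np.array([[1.0, 0.0], [1.0, 0.0]])
        with use_dtype(np.float64):
            val = float(modality_similarity_loss(
                {"functional": a, "demographic": b},
                pairs=[("functional", "demographic")]).data)
        na = a @ a.T                       # rows already unit norm
        nb = (b / np.linalg.norm(b, axis=1, keepdims=True))
        nb = nb @ nb.T
        assert val == pytest.approx(np.linalg.norm(na - nb), abs=1e-6)

    def test_row_sign_flip_changes_loss(self, rng):
        """The Gram-matrix loss is NOT invariant to per-row sign flips."""
        h = rng.normal(size=(4, 3))
        flipped = h.copy()
        flipped[1] *= -1
        with use_dtype(np.float64):
            base = float(modality_similarity_loss(
                {"functional": h, "demographic": h.copy()},
                pairs=[("functional", "demographic")]).data)
            changed = float(modality_similarity_loss(
                {"functional": h, "demographic": flipped},
                pairs=[("functional", "demographic")]).data)
        assert base <= 2e-6 < changed

    def test_absent_channel_pairs_dropped(self, rng):
        commons = {"functional": rng.normal(size=(4, 2)),
                   "structural": rng.normal(size=(4, 2))}
        val = float(modality_similarity_loss(commons).data)
        assert np.isfinite(val)


class TestDomain:
    def test_constant_logits_give_chance_level(self):
        sites = np.array([0, 1, 2] * 5)
        logits = Tensor(np.zeros((15, 3), dtype=np.float32))
        val = float(site_adversarial_loss(logits, sites).data)
        assert val == pytest.approx(np.log(3), abs=1e-6)

    def test_single_site_warns(self):
        with pytest.warns(UserWarning, match="vacuous"):
            site_adversarial_loss(Tensor(np.zeros((4, 2))), np.zeros(4, int))

    def test_grl_zero_blocks_feature_gradients(self, rng):
        fused = Tensor(rng.normal(size=(6, 3)).astype(np.float32),
                       requires_grad=True)
        head = MLP([3, 4, 2], np.random.default_rng(0))
        sites = np.array([0, 1] * 3)
        loss = site_adversarial_loss(head(grad_reverse(fused, 0.0)), sites)
        loss.backward()
        assert np.abs(fused.grad).max() == 0.0

    def test_grl_backward_sign_flipped(self, rng):
        """The gradient through the reversal layer is the negated gradient
        of the same head without reversal."""
        x0 = rng.normal(size=(5, 3))
        head = MLP([3, 4, 2], np.random.default_rng(1))
        sites = np.array([0, 1, 0, 1, 0])
        with use_dtype(np.float64):
            x = Tensor(x0, requires_grad=True)
            site_adversarial_loss(head(grad_reverse(x, 1.0)), sites).backward()
            g_rev = x.grad.copy()
            x2 = Tensor(x0, requires_grad=True)
            site_adversarial_loss(head(x2), sites).backward()
            g_fwd = x2.grad.copy()
        assert np.abs(g_rev + g_fwd).max() < 1e-10

    def test_cmd_identical_distributions_zero(self, rng):
        x = rng.normal(size=(6, 3))
        both = np.concatenate([x, x])
        sites = np.array([0] * 6 + [1] * 6)
        with use_dtype(np.float64):
            val = float(cmd_loss(both, sites).data)
        assert val < 2e-5

    def test_cmd_pure_mean_shift_closed_form(self):
        """1-d sites with identical spread: only the first moment differs,
        so CMD = shift / (b - a) after rescaling."""
        delta = 0.6
        a = np.array([0.0, 0.2])
        b = a + delta
        x = np.concatenate([a, b])[:, None]
        sites = np.array([0, 0, 1, 1])
        with use_dtype(np.float64):
            val = float(cmd_loss(x, sites).data)
        assert val == pytest.approx(delta / (delta + 0.2), abs=1e-4)

    def test_cmd_matches_naive_oracle(self, rng):
        x = rng.normal(size=(18, 4))
        sites = np.array([0, 1, 2] * 6)
        with use_dtype(np.float64):
            ours = float(cmd_loss(x, sites).data)
        assert ours == pytest.approx(cmd_naive(x, sites), abs=1e-9)

    def test_cmd_symmetric_in_site_order(self, rng):
        x = rng.normal(size=(12, 3))
        sites = np.array([0] * 6 + [1] * 6)
        with use_dtype(np.float64):
            a = float(cmd_loss(x, sites).data)
            b = float(cmd_loss(x, 1 - sites).data)
        assert a == pytest.approx(b, abs=1e-10)


class TestTotal:
    def test_zero_components_zero_total(self):
        z = Tensor(np.zeros(()))
        assert float(total_loss(z, z, z, z, z).data) == 0.0

    def test_equals_manual_sum(self, rng):
        vals = [Tensor(np.array(v)) for v in (0.7, 0.2, 1.5, 0.4, 0.3)]
        total = float(total_loss(*vals).data)
        assert total == pytest.approx(sum(float(v.data) for v in vals),
                                      abs=1e-6)

    def test_unknown_weight_key_rejected(self):
        z = Tensor(np.zeros(()))
        with pytest.raises(ValueError, match="unknown loss weights"):
            total_loss(z, z, z, z, z, weights={"typo": 1.0})

    def test_gradient_is_sum_of_component_gradients(self, rng):
        """Numeric check on a tiny shared parameter feeding every term."""
        x0 = rng.normal(size=(4, 2))
        sites = np.array([0, 1, 0, 1])
        labels = np.array([0, 1, 1, 0])

        def build(v):
            x = v if isinstance(v, Tensor) else Tensor(v)
            cls = cross_entropy(x, labels)
            spec = hsic(x, x * 2.0)
            common = modality_similarity_loss(
                {"functional": x, "demographic": x * 0.5},
                pairs=[("functional", "demographic")])
            site = cross_entropy(x * 0.5, sites)
            # CMD's min-max rescaling constants are detached by design, so
            # its finite differences would disagree at the extreme entries;
            # additivity is exercised through the other four terms.
            zero = Tensor(np.zeros(()))
            return total_loss(cls, spec, common, site, zero)

        with use_dtype(np.float64):
            x = Tensor(x0, requires_grad=True)
            build(x).backward()
            grad = x.grad.copy()
        eps = 1e-6
        num = np.zeros_like(x0)
        for idx in np.ndindex(*x0.shape):
            xp = x0.copy(); xp[idx] += eps
            xm = x0.copy(); xm[idx] -= eps
            with use_dtype(np.float64):
                num[idx] = (float(build(Tensor(xp)).data)
                            - float(build(Tensor(xm)).data)) / (2 * eps)
        assert np.abs(grad - num).max() < 1e-5
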