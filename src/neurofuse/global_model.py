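"""The global model: snowball GCN blocks on population graphs, multimodal
fusion, and the final node-level classifier.

Each modality channel runs through a *snowball* GCN — a densely connected
stack in which layer ``l+1`` consumes the concatenation of the input and all
previous layers' outputs, which counteracts oversmoothing at depth.  The
modality-specific block (MS-GCN) uses independent weights per channel; the
modality-common block (MC-GCN) shares its trainable matrices across channels
(behind per-channel linear input projections, since channel widths differ)
and averages the per-channel outputs with fixed equal weights.  A softmax
attention over the specific embeddings and the common embedding fuses them
into one representation per subject, classified by an MLP.  A site classifier
behind a gradient-reversal layer provides the adversarial branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .population import PairwiseAssociationEncoder, SubjectGraph

__all__ = [
    "GlobalConfig",
    "EmbeddingBundle",
    "Snowball",
    "SubjectGnn",
    "dense_laplacian",
    "laplacian_tensor",
]


@dataclass(frozen=True)
class GlobalConfig:
    channel_dims: dict            # channel name -> input feature width
    n_sites: int = 3
    snowball_layers: int = 9
    layer_width: int = 32
    collapse_width: int = 64
    embedding_dim: int = 32
    p: int = 0                    # extra Laplacian multiplication on output
    mc_projection: int = 64
    attention_dim: int | None = None
    pae_hidden: int = 16
    pae_out: int = 8
    classifier_hidden: int = 16
    site_hidden: int = 16
    grl_lambda: float = 1.0

    def __post_init__(self):
        if self.snowball_layers < 1:
            raise ValueError("snowball_layers must be >= 1")
        if self.p not in (0, 1):
            raise ValueError("p must be 0 or 1")


@dataclass
class EmbeddingBundle:
    """Population embeddings produced by one global forward pass."""

    specific: dict                # channel -> (S, embedding_dim) Tensor
    common_per_channel: dict      # channel -> (S, embedding_dim) Tensor
    common: Tensor                # H_c
    fused: Tensor                 # H
    attention: Tensor             # (S, n_channels + 1) softmax scores
    attention_order: list         # channel names + "common"
    modality_weights: dict        # fixed MC combination weights


def dense_laplacian(weights: np.ndarray) -> np.ndarray:
    """Self-loops plus symmetric normalization, as a constant matrix."""
    a = weights + np.eye(weights.shape[0], dtype=weights.dtype)
    dinv = 1.0 / np.sqrt(a.sum(axis=1))
    return a * dinv[:, None] * dinv[None, :]


def laplacian_tensor(weights: Tensor) -> Tensor:
    """Differentiable version of :func:`dense_laplacian` (demographic graph)."""
    s = weights.shape[0]
    a = weights + Tensor(np.eye(s, dtype=np.float32))
    dinv = a.sum(axis=1) ** -0.5
    return a * dinv.reshape(s, 1) * dinv.reshape(1, s)


class Snowball(nn.Module):
    """Densely connected GCN stack with tanh activations.

    ``H_0 = X``; ``H_{l+1} = tanh(L [H_0 .. H_l] W_l)``;
    ``C = tanh([H_0 .. H_n] W_n)``; output ``normalize(L^p C W_c)`` with
    row-wise L2 normalization.
    """

    def __init__(self, in_dim: int, config: GlobalConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.p = config.p
        w = config.layer_width
        self.layer_weights = [
            nn.Linear(in_dim + l * w, w, rng)
            for l in range(config.snowball_layers)
        ]
        total = in_dim + config.snowball_layers * w
        self.collapse = nn.Linear(total, config.collapse_width, rng)
        self.out = nn.Linear(config.collapse_width, config.embedding_dim, rng)

    def __call__(self, laplacian: Tensor, x: Tensor,
                 return_layers: bool = False):
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite node features")
        hs = [x]
        for weight in self.layer_weights:
            stacked = hs[0] if len(hs) == 1 else nn.concatenate(hs, axis=-1)
            hs.append(weight(laplacian @ stacked).tanh())
        c = self.collapse(nn.concatenate(hs, axis=-1)).tanh()
        if self.p == 1:
            c = laplacian @ c
        out = nn.row_normalize(self.out(c))
        if return_layers:
            return out, hs
        return out


class SubjectGnn(nn.Module):
    """MS-GCN + MC-GCN + M-attention + classifier + adversarial site head."""

    def __init__(self, config: GlobalConfig, rng: np.random.Generator,
                 mc_weights: dict | None = None, eta_dim: int | None = None):
        super().__init__()
        self.config = config
        channels = list(config.channel_dims)
        self.channels = channels
        if mc_weights is None:
            mc_weights = {ch: 1.0 / len(channels) for ch in channels}
        if abs(sum(mc_weights.values()) - 1.0) > 1e-6:
            raise ValueError("MC combination weights must sum to 1")
        self.mc_weights = mc_weights

        self.ms_blocks = {ch: Snowball(dim, config, rng)
                          for ch, dim in config.channel_dims.items()}
        self.mc_projections = {ch: nn.Linear(dim, config.mc_projection, rng)
                               for ch, dim in config.channel_dims.items()}
        self.mc_trunk = Snowball(config.mc_projection, config, rng)

        d = config.embedding_dim
        att_d = config.attention_dim or d
        self.attention_heads = {name: nn.Linear(d, att_d, rng)
                                for name in channels + ["common"]}
        self.classifier = nn.MLP([d, config.classifier_hidden, 2], rng)
        self.site_head = nn.MLP([d, config.site_hidden, config.n_sites], rng)
        if eta_dim is not None:
            self.pae = PairwiseAssociationEncoder(
                eta_dim, config.pae_hidden, config.pae_out, rng)
        else:
            self.pae = None

    # -- graph plumbing -------------------------------------------------------

    def channel_laplacian(self, graph: SubjectGraph,
                          eta: np.ndarray | None = None) -> Tensor:
        """Laplacian for one channel; the demographic channel re-weights its
        fixed KNN support through the trainable PAE on every call."""
        if graph.channel == "demographic" and self.pae is not None:
            if graph.support is None:
                raise ValueError("demographic graph needs a KNN support")
            eta = graph.node_features if eta is None else eta
            weights = self.pae.edge_weights(np.asarray(eta), graph.support)
            return laplacian_tensor(weights)
        return Tensor(dense_laplacian(graph.weights))

    # -- blocks ---------------------------------------------------------------

    def ms_gcn(self, laplacians: dict, features: dict) -> dict:
        """Modality-specific embeddings (independent snowball per channel)."""
        self._check_channels(laplacians, features)
        return {ch: self.ms_blocks[ch](laplacians[ch], _tensor(features[ch]))
                for ch in self.channels}

    def mc_gcn(self, laplacians: dict, features: dict) -> tuple[dict, Tensor]:
        """Modality-common embeddings through the shared trunk, then the
        fixed equal-weight combination ``H_c``."""
        self._check_channels(laplacians, features)
        per_channel = {}
        for ch in self.channels:
            projected = self.mc_projections[ch](_tensor(features[ch]))
            per_channel[ch] = self.mc_trunk(laplacians[ch], projected)
        common = None
        for ch in self.channels:
            term = per_channel[ch] * self.mc_weights[ch]
            common = term if common is None else common + term
        return per_channel, common

    def m_attention(self, specific: dict, common: Tensor) -> tuple[Tensor, Tensor, list]:
        """Softmax attention over the specific embeddings and the common one.

        Per channel, the score logit is the mean over dimensions of
        ``tanh(W_a H + b)``; the softmax is taken per node across channels.
        """
        order = self.channels + ["common"]
        embeddings = {**specific, "common": common}
        shapes = {e.shape for e in embeddings.values()}
        if len(shapes) != 1:
            raise ValueError(f"embedding shape mismatch: {shapes}")
        logits = [self.attention_heads[name](embeddings[name]).tanh()
                  .mean(axis=-1, keepdims=True) for name in order]
        scores = nn.softmax(nn.concatenate(logits, axis=-1), axis=-1)
        fused = None
        for idx, name in enumerate(order):
            term = embeddings[name] * scores[:, idx:idx + 1]
            fused = term if fused is None else fused + term
        return fused, scores, order

    def classify(self, fused: Tensor) -> Tensor:
        return self.classifier(fused)

    def site_logits(self, fused: Tensor, grl_lambda: float | None = None) -> Tensor:
        lam = self.config.grl_lambda if grl_lambda is None else grl_lambda
        return self.site_head(nn.grad_reverse(fused, lam))

    # -- full forward ---------------------------------------------------------

    def __call__(self, laplacians: dict, features: dict) -> tuple[EmbeddingBundle, Tensor]:
        specific = self.ms_gcn(laplacians, features)
        per_channel, common = self.mc_gcn(laplacians, features)
        fused, scores, order = self.m_attention(specific, common)
        logits = self.classify(fused)
        bundle = EmbeddingBundle(specific=specific,
                                 common_per_channel=per_channel,
                                 common=common, fused=fused,
                                 attention=scores, attention_order=order,
                                 modality_weights=dict(self.mc_weights))
        return bundle, logits

    def _check_channels(self, laplacians: dict, features: dict) -> None:
        if set(laplacians) != set(self.channels) or set(features) != set(self.channels):
            raise ValueError(
                f"channel mismatch: model {self.channels}, "
                f"laplacians {sorted(laplacians)}, features {sorted(features)}")


def _tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
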