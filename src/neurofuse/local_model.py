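"""The local model: per-subject ROI graphs learned from BOLD time series.

Pipeline per subject: a shared-weight bidirectional GRU encodes each ROI's
standardized signal into a regional embedding ``h_e`` (one row per ROI); the
graph generator turns the Gram matrix of these embeddings into a learnable
adjacency ``A = n * softmax(h_e h_e^T)`` (row-wise softmax, scaled by the
number of ROIs so edge weights do not vanish); a three-layer GCN with
symmetric degree normalization propagates the Pearson-FC node features; an
attention readout over ROIs produces the graph embedding and a small MLP head
the local class prediction.

All operations are batched over subjects and are equivariant to ROI
permutation because the recurrent weights are shared across ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LocalConfig",
    "LocalOutput",
    "RoiGnn",
    "generate_graph",
    "gcn_layer",
    "attention_readout",
]


@dataclass(frozen=True)
class LocalConfig:
    n_rois: int = 32
    n_timepoints: int = 120
    gru_hidden: int = 32                 # regional embedding d = 2 * hidden
    gcn_widths: tuple = (64, 32, 16)
    head_hidden: int = 64


@dataclass
class LocalOutput:
    """Per-batch outputs of the local model."""

    graph_embedding: Tensor       # (S, n_rois * gcn_widths[-1])
    local_logits: Tensor          # (S, 2)
    roi_attention: Tensor         # (S, n_rois), nonnegative, sums to n
    learned_adjacency: Tensor     # (S, n_rois, n_rois), rows sum to n
    regional_embedding: Tensor    # (S, n_rois, d)


def generate_graph(embedding: Tensor) -> tuple[Tensor, Tensor]:
    """Learnable adjacency from regional embeddings.

    Returns ``(A, scores)`` where ``scores = h_e h_e^T`` and
    ``A = n * softmax(scores)`` row-wise, so every row of ``A`` sums to the
    number of ROIs.  Softmax is computed with row-max subtraction.
    """
    if not np.isfinite(embedding.data).all():
        raise ValueError("non-finite regional embedding")
    n = embedding.shape[-2]
    scores = embedding @ embedding.swapaxes(-1, -2)
    adjacency = nn.softmax(scores, axis=-1) * float(n)
    return adjacency, scores


def _normalized_laplacian(adjacency: Tensor) -> Tensor:
    """Symmetric degree normalization ``D^{-1/2} A D^{-1/2}``."""
    degree = adjacency.sum(axis=-1)
    if (degree.data <= 0).any():
        raise ValueError("zero-degree node in adjacency")
    dinv = degree ** -0.5
    left = dinv.reshape(*degree.shape, 1)
    right = dinv.reshape(*degree.shape[:-1], 1, degree.shape[-1])
    return adjacency * left * right


def gcn_layer(h_prev: Tensor, adjacency: Tensor, weight: nn.MLP) -> Tensor:
    """One graph-convolution layer ``tanh(D^{-1/2} A D^{-1/2} H W)`` with the
    layer weight realized as a two-layer perceptron."""
    lap = _normalized_laplacian(adjacency)
    return weight(lap @ h_prev).tanh()


def attention_readout(h: Tensor, scores: Tensor) -> tuple[Tensor, Tensor]:
    """ROI attention over row sums of the score matrix, then weighted concat.

    ``a = n * softmax_i(sum_j scores_ij)``; the graph embedding concatenates
    every ROI's node embedding scaled by its attention weight, giving a
    vector of length ``n_rois * d_out`` per subject.
    """
    n = h.shape[-2]
    att = nn.softmax(scores.sum(axis=-1), axis=-1) * float(n)
    weighted = h * att.reshape(*att.shape, 1)
    return weighted.reshape(h.shape[0], -1) if h.ndim == 3 else weighted.reshape(-1), att


class RoiGnn(nn.Module):
    """Local ROI GNN: encoder, graph generator, GCN predictor, class head."""

    def __init__(self, config: LocalConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.encoder = nn.BiGRU(1, config.gru_hidden, rng)
        widths = (config.n_rois,) + tuple(config.gcn_widths)
        self.gcn_weights = [nn.MLP([a, b, b], rng)
                            for a, b in zip(widths[:-1], widths[1:])]
        emb_dim = config.n_rois * config.gcn_widths[-1]
        self.norm = nn.BatchNorm1d(emb_dim)
        self.head = nn.MLP([emb_dim, config.head_hidden, 2], rng)

    @property
    def embedding_dim(self) -> int:
        return self.config.n_rois * self.config.gcn_widths[-1]

    def encode_series(self, series: Tensor) -> Tensor:
        """Encode (S, n_rois, t) standardized series into (S, n_rois, d).

        Each ROI's scalar sequence passes through the shared bi-GRU; a row of
        the regional embedding is the concatenated final forward and backward
        hidden states (d = 2 * gru_hidden).
        """
        if not np.isfinite(series.data).all():
            raise ValueError("non-finite time series input")
        s, n, t = series.shape
        flat = series.reshape(s * n, t, 1)
        return self.encoder(flat).reshape(s, n, 2 * self.config.gru_hidden)

    def __call__(self, series: Tensor, node_features: Tensor) -> LocalOutput:
        """Full local forward pass.

        Parameters
        ----------
        series : (S, n_rois, t) standardized BOLD-like signals
        node_features : (S, n_rois, n_rois) Pearson-FC node features F
        """
        h_e = self.encode_series(series)
        adjacency, scores = generate_graph(h_e)
        h = node_features
        for weight in self.gcn_weights:
            h = gcn_layer(h, adjacency, weight)
        embedding, attention = attention_readout(h, scores)
        logits = self.head(self.norm(embedding))
        return LocalOutput(graph_embedding=embedding, local_logits=logits,
                           roi_attention=attention,
                           learned_adjacency=adjacency,
                           regional_embedding=h_e)
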