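"""Population (subject) graphs for the three data channels.

Functional and structural graphs are k-nearest-neighbor graphs under cosine
similarity of node features (per-node top-k, union-symmetrized, negative
similarities clipped to zero).  The demographic graph keeps a fixed KNN
support but its edge weights come from a trainable pairwise-association
encoder (PAE): ``w_ij = (cos(MLP(eta_i), MLP(eta_j)) + 1) / 2``, trained
jointly with the rest of the objective.

Construction is transductive: every subject (train and test) is a node;
held-out labels are masked from all losses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor

__all__ = [
    "SubjectGraph",
    "build_knn_graph",
    "knn_support",
    "functional_node_features",
    "encode_demographics",
    "PairwiseAssociationEncoder",
    "pae_edge_weight",
]


@dataclass
class SubjectGraph:
    """One modality channel of the population graph (dense storage)."""

    node_features: np.ndarray          # (S, p)
    weights: np.ndarray                # (S, S) symmetric, zero diagonal
    channel: str                       # functional | structural | demographic
    support: np.ndarray | None = None  # boolean KNN support (demographic)

    def __post_init__(self):
        w = self.weights
        if w.shape[0] != w.shape[1] or not np.allclose(w, w.T, atol=1e-6):
            raise ValueError("edge weights must be square and symmetric")
        if np.abs(np.diag(w)).max() > 0:
            raise ValueError("self-loops are added only at Laplacian time")

    def to_edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame({"i": i, "j": j,
                             "weight": self.weights[i, j],
                             "channel": self.channel})


def _cosine_matrix(features: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(features, axis=1)
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        raise ValueError(f"zero-norm feature row for subject(s) {bad.tolist()}")
    unit = features / norms[:, None]
    sim = unit @ unit.T
    return np.clip((sim + sim.T) / 2.0, -1.0, 1.0)


def knn_support(similarity: np.ndarray, k: int) -> np.ndarray:
    """Boolean union-symmetrized per-node top-k support, self excluded.

    Ties are broken toward the lowest subject index (stable sort).
    """
    s = similarity.shape[0]
    if not 1 <= k < s:
        raise ValueError("need 1 <= k < n_subjects")
    masked = similarity.copy()
    np.fill_diagonal(masked, -np.inf)
    order = np.argsort(-masked, axis=1, kind="stable")
    support = np.zeros((s, s), dtype=bool)
    rows = np.repeat(np.arange(s), k)
    support[rows, order[:, :k].ravel()] = True
    return support | support.T


def build_knn_graph(features: np.ndarray, k: int = 10,
                    channel: str = "functional") -> SubjectGraph:
    """Cosine-similarity KNN graph over subjects.

    Edge weight = cosine similarity of the two feature rows, negative values
    clipped to zero before use as propagation weights.
    """
    features = np.asarray(features, dtype=float)
    sim = _cosine_matrix(features)
    support = knn_support(sim, k)
    weights = np.where(support, np.clip(sim, 0.0, None), 0.0)
    np.fill_diagonal(weights, 0.0)
    return SubjectGraph(node_features=features, weights=weights,
                        channel=channel, support=support)


def functional_node_features(fc_matrices: np.ndarray,
                             local_embedding: Tensor | np.ndarray | None,
                             mode: str = "Concat"):
    """Compose functional node features from FC matrices and local embeddings.

    ``Corr``: strict upper-triangle flattening of each FC matrix.
    ``Emb``: the local model's graph embedding, passed through.
    ``Concat``: their concatenation (default; the best-performing mode).
    Returns a :class:`Tensor` when a Tensor embedding is involved so the
    composition stays differentiable end to end.
    """
    fc_matrices = np.asarray(fc_matrices)
    single = fc_matrices.ndim == 2
    if single:
        fc_matrices = fc_matrices[None]
    n = fc_matrices.shape[-1]
    iu = np.triu_indices(n, k=1)
    corr = fc_matrices[:, iu[0], iu[1]]
    if mode == "Corr":
        return corr[0] if single else corr
    if local_embedding is None:
        raise ValueError(f"mode {mode!r} requires a local-model embedding")
    emb = local_embedding
    if mode == "Emb":
        return emb
    if mode == "Concat":
        if isinstance(emb, Tensor):
            return nn.concatenate([Tensor(corr.astype(np.float32)), emb], axis=-1)
        return np.concatenate([corr, np.asarray(emb)], axis=-1)
    raise ValueError(f"unknown functional feature mode {mode!r}")


def encode_demographics(demographics: pd.DataFrame, n_sites: int) -> np.ndarray:
    """Demographic vector eta: normalized age, one-hot sex, normalized
    education, one-hot site."""
    age = demographics["age"].to_numpy(dtype=float)
    edu = demographics["education"].to_numpy(dtype=float)
    sex = demographics["sex"].to_numpy(dtype=int)
    site = demographics["site"].to_numpy(dtype=int)

    def minmax(v):
        lo, hi = v.min(), v.max()
        return np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)

    sex_oh = np.eye(2)[sex]
    site_oh = np.eye(n_sites)[site]
    return np.column_stack([minmax(age), sex_oh, minmax(edu), site_oh])


class PairwiseAssociationEncoder(nn.Module):
    """Trainable MLP mapping eta to a latent vector; edge weights are the
    affinely rescaled cosine similarities of latent pairs."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.mlp = nn.MLP([in_dim, hidden, out_dim], rng)

    def edge_weights(self, eta: Tensor | np.ndarray,
                     support: np.ndarray) -> Tensor:
        """Dense symmetric weight matrix on the given support."""
        eta = eta if isinstance(eta, Tensor) else Tensor(eta)
        z = self.mlp(eta)
        if not np.isfinite(z.data).all():
            raise ValueError("non-finite PAE output")
        unit = nn.row_normalize(z)
        cos = unit @ unit.T
        weights = (cos + 1.0) * 0.5
        mask = support.astype(np.float32)
        np.fill_diagonal(mask, 0.0)
        return weights * Tensor(mask)


def pae_edge_weight(eta_i: np.ndarray, eta_j: np.ndarray,
                    encoder: PairwiseAssociationEncoder) -> float:
    """Single-pair weight ``(cos(MLP(eta_i), MLP(eta_j)) + 1) / 2``."""
    eta = Tensor(np.stack([eta_i, eta_j]))
    z = encoder.mlp(eta)
    if not np.isfinite(z.data).all():
        raise ValueError("non-finite PAE output")
    unit = nn.row_normalize(z)
    return float((unit.data[0] * unit.data[1]).sum() * 0.5 + 0.5)
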