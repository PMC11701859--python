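"""Independent brute-force reference implementations used by the tests.

Everything here is written in plain float64 numpy loops, deliberately
avoiding the package's own code paths, so each comparison is a genuine
dual-route check.
"""

from __future__ import annotations

import numpy as np


def pearson_two_pass(series: np.ndarray) -> np.ndarray:
    """Textbook covariance/variance Pearson matrix."""
    x = np.asarray(series, dtype=np.float64)
    n, t = x.shape
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi = x[i] - x[i].mean()
            xj = x[j] - x[j].mean()
            out[i, j] = (xi * xj).sum() / np.sqrt((xi * xi).sum()
                                                  * (xj * xj).sum())
    return out


def hsic_trace(hs: np.ndarray, hc: np.ndarray) -> float:
    """(m-1)^-2 tr(Kc R Ks R) with explicit matrix products."""
    hs = np.asarray(hs, dtype=np.float64)
    hc = np.asarray(hc, dtype=np.float64)
    m = hs.shape[0]
    ks = hs @ hs.T
    kc = hc @ hc.T
    r = np.eye(m) - np.ones((m, m)) / m
    return float(np.trace(kc @ r @ ks @ r) / (m - 1) ** 2)


def cross_entropy_naive(logits: np.ndarray, targets: np.ndarray) -> float:
    """-mean log softmax picked at the target class."""
    logits = np.asarray(logits, dtype=np.float64)
    total = 0.0
    for row, t in zip(logits, targets):
        p = np.exp(row) / np.exp(row).sum()
        total -= np.log(p[t])
    return total / len(targets)


def sym_norm_laplacian(a: np.ndarray) -> np.ndarray:
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return a * dinv[:, None] * dinv[None, :]


def gcn_layer_naive(h: np.ndarray, a: np.ndarray, w1: np.ndarray,
                    b1: np.ndarray, w2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """tanh(MLP(D^-1/2 A D^-1/2 H)) with a two-layer perceptron weight."""
    prop = sym_norm_laplacian(np.asarray(a, dtype=np.float64)) @ h
    hidden = np.tanh(prop @ w1 + b1)
    return np.tanh(hidden @ w2 + b2)


def attention_readout_naive(h: np.ndarray, scores: np.ndarray):
    """n * softmax over ROI row sums, then weighted concatenation."""
    n = h.shape[0]
    sums = scores.sum(axis=1)
    e = np.exp(sums - sums.max())
    att = n * e / e.sum()
    emb = np.concatenate([att[i] * h[i] for i in range(n)])
    return emb, att


def snowball_naive(lap: np.ndarray, x: np.ndarray, layer_ws, layer_bs,
                   wn: np.ndarray, bn: np.ndarray, wc: np.ndarray,
                   bc: np.ndarray, p: int) -> np.ndarray:
    """Densely connected stack computed with explicit concatenations."""
    hs = [np.asarray(x, dtype=np.float64)]
    lap = np.asarray(lap, dtype=np.float64)
    for w, b in zip(layer_ws, layer_bs):
        stacked = np.concatenate(hs, axis=1)
        hs.append(np.tanh(lap @ stacked @ w + b))
    c = np.tanh(np.concatenate(hs, axis=1) @ wn + bn)
    out = c @ wc + bc
    if p == 1:
        out = lap @ out
    norms = np.sqrt((out ** 2).sum(axis=1, keepdims=True) + 1e-12)
    return out / norms


def pae_weight_naive(eta_i, eta_j, w1, b1, w2, b2) -> float:
    """(cos(MLP(eta_i), MLP(eta_j)) + 1) / 2 with a tanh-hidden MLP."""

    def mlp(v):
        return np.tanh(np.asarray(v, np.float64) @ w1 + b1) @ w2 + b2

    zi, zj = mlp(eta_i), mlp(eta_j)
    cos = (zi * zj).sum() / (np.linalg.norm(zi) * np.linalg.norm(zj))
    return float((cos + 1.0) / 2.0)


def cmd_naive(x: np.ndarray, sites: np.ndarray, order: int = 5) -> float:
    """Central moment discrepancy with per-batch min-max rescaling."""
    x = np.asarray(x, dtype=np.float64)
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span[span == 0] = 1.0
    x = (x - lo) / span
    groups = [x[sites == s] for s in np.unique(sites)]
    total, pairs = 0.0, 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            total += np.sqrt((((a.mean(0) - b.mean(0)) ** 2).sum()) + 1e-12)
            for k in range(2, order + 1):
                ca = ((a - a.mean(0)) ** k).mean(0)
                cb = ((b - b.mean(0)) ** k).mean(0)
                total += np.sqrt(((ca - cb) ** 2).sum() + 1e-12)
            pairs += 1
    return total / pairs


def auroc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties 0.5)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def confusion_metrics(labels: np.ndarray, pred: np.ndarray) -> dict:
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"ACC": (tp + tn) / len(labels), "precision": precision,
            "recall": recall, "F1": f1}


def gru_naive(x: np.ndarray, w_ih, w_hh, b_ih, b_hh, reverse=False):
    """Single-direction GRU recurrence, one step at a time."""
    x = np.asarray(x, dtype=np.float64)
    b, t, _ = x.shape
    hdim = w_hh.shape[0]
    h = np.zeros((b, hdim))
    order = range(t - 1, -1, -1) if reverse else range(t)
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    for step in order:
        gi = x[:, step, :] @ w_ih + b_ih
        gh = h @ w_hh + b_hh
        r = sig(gi[:, :hdim] + gh[:, :hdim])
        z = sig(gi[:, hdim:2 * hdim] + gh[:, hdim:2 * hdim])
        n = np.tanh(gi[:, 2 * hdim:] + r * gh[:, 2 * hdim:])
        h = (1 - z) * n + z * h
    return h


def knn_support_naive(features: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive cosine sort with lowest-index tie-break, union symmetrized."""
    f = np.asarray(features, dtype=np.float64)
    s = f.shape[0]
    unit = f / np.linalg.norm(f, axis=1, keepdims=True)
    sim = unit @ unit.T
    support = np.zeros((s, s), dtype=bool)
    for i in range(s):
        order = sorted((j for j in range(s) if j != i),
                       key=lambda j: (-sim[i, j], j))
        for j in order[:k]:
            support[i, j] = True
    return support | support.T
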