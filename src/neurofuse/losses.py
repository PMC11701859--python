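"""The composite training objective.

Four terms: (1) weighted local+global cross-entropy; (2) a
Hilbert-Schmidt-independence penalty pushing each modality-specific
embedding away from the common embedding; (3) a similarity penalty pulling
the per-channel common embeddings' normalized Gram matrices together; and
(4) the domain loss — adversarial site classification through a
gradient-reversal layer plus a central-moment-discrepancy term aligning
per-site embedding distributions.  The total is the plain sum of the four.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LossBundle",
    "cross_entropy",
    "classification_loss",
    "hsic",
    "modality_specific_loss",
    "modality_similarity_loss",
    "site_adversarial_loss",
    "cmd_loss",
    "total_loss",
]

_COMMON_PAIRS = (("functional", "demographic"),
                 ("functional", "structural"),
                 ("demographic", "structural"))


@dataclass
class LossBundle:
    """Component values (floats) plus the differentiable total."""

    total: Tensor
    cls_global: float
    cls_local: float
    specific: float
    common: float
    site: float
    cmd: float
    lambda_local: float

    @property
    def cls(self) -> float:
        return self.cls_global + self.lambda_local * self.cls_local

    def as_dict(self) -> dict:
        return {"L_cls_global": self.cls_global, "L_cls_local": self.cls_local,
                "L_specific": self.specific, "L_common": self.common,
                "L_site": self.site, "L_CMD": self.cmd,
                "total": float(self.total.data)}


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  indices: np.ndarray | None = None) -> Tensor:
    """Mean negative log-softmax of the target class over selected rows."""
    targets = np.asarray(targets)
    if indices is not None:
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        if indices.size == 0:
            raise ValueError("empty index mask in cross-entropy")
        logits = logits[indices]
        targets = targets[indices]
    ls = nn.log_softmax(logits, axis=-1)
    picked = ls[np.arange(len(targets)), targets]
    return -picked.mean()


def classification_loss(global_logits: Tensor, local_logits: Tensor,
                        labels: np.ndarray, mask: np.ndarray,
                        lambda_local: float = 0.2) -> tuple[Tensor, Tensor, Tensor]:
    """``L_cls = CE(global) + lambda * CE(local)`` on training nodes only."""
    ce_global = cross_entropy(global_logits, labels, mask)
    ce_local = cross_entropy(local_logits, labels, mask)
    return ce_global + ce_local * lambda_local, ce_global, ce_local


def _gram(h: Tensor, kernel: str, sigma: float | None) -> Tensor:
    if kernel == "linear":
        return h @ h.T
    if kernel == "gaussian":
        sq = (h * h).sum(axis=1, keepdims=True)
        d2 = sq + sq.T - (h @ h.T) * 2.0
        d2_np = np.clip(d2.data, 0.0, None)
        if sigma is None:
            positive = d2_np[d2_np > 0]
            med = np.median(positive) if positive.size else 1.0
            sigma = float(np.sqrt(med / 2.0)) or 1.0
        return (d2 * (-1.0 / (2.0 * sigma ** 2))).exp()
    raise ValueError(f"unknown kernel {kernel!r}")


def hsic(hs: Tensor | np.ndarray, hc: Tensor | np.ndarray,
         kernel: str = "linear", sigma: float | None = None) -> Tensor:
    """Empirical Hilbert-Schmidt independence criterion.

    ``HSIC = (m - 1)^{-2} tr(K_c R K_s R)`` with ``R = I - ee^T / m`` the
    centering matrix and Gram matrices under the chosen kernel (linear by
    default; Gaussian with a median-heuristic bandwidth optional).
    """
    hs = _as_tensor(hs)
    hc = _as_tensor(hc)
    m = hs.shape[0]
    if m < 2 or hc.shape[0] != m:
        raise ValueError("HSIC needs >= 2 paired samples")
    r = np.eye(m) - 1.0 / m
    ks = _gram(hs, kernel, sigma)
    kc = _gram(hc, kernel, sigma)
    a = kc @ Tensor(r)
    b = ks @ Tensor(r)
    # tr(AB) = sum(A * B^T)
    return (a * b.T).sum() * (1.0 / (m - 1) ** 2)


def modality_specific_loss(specific: dict, common: Tensor,
                           kernel: str = "linear") -> Tensor:
    """Sum of HSIC(specific channel, common) over the active channels."""
    out = None
    for ch in sorted(specific):
        term = hsic(specific[ch], common, kernel=kernel)
        out = term if out is None else out + term
    if out is None:
        raise ValueError("no active channels")
    return out


def modality_similarity_loss(common_per_channel: dict,
                             pairs=None, eps: float = 1e-12) -> Tensor:
    """Frobenius distances between the normalized Gram matrices of the
    per-channel common embeddings, summed over the configured pair list.

    With the default three channels the pair list covers all pairs; absent
    channels drop their pairs.
    """
    pairs = _COMMON_PAIRS if pairs is None else pairs
    grams = {ch: (lambda z: z @ z.T)(nn.row_normalize(_as_tensor(h)))
             for ch, h in common_per_channel.items()}
    out = None
    for a, b in pairs:
        if a not in grams or b not in grams:
            continue
        diff = grams[a] - grams[b]
        term = ((diff * diff).sum() + eps).sqrt()
        out = term if out is None else out + term
    if out is None:
        raise ValueError("no channel pairs available")
    return out


def site_adversarial_loss(site_logits: Tensor, sites: np.ndarray) -> Tensor:
    """Cross-entropy of the (gradient-reversed) site classifier.

    With a single site the adversary is vacuous; the loss is still defined
    but a warning is emitted.
    """
    sites = np.asarray(sites)
    if np.unique(sites).size < 2:
        warnings.warn("single site in batch: adversary is vacuous", stacklevel=2)
    return cross_entropy(site_logits, sites)


def cmd_loss(embeddings: Tensor | np.ndarray, sites: np.ndarray,
             order: int = 5) -> Tensor:
    """Central moment discrepancy between per-site embedding distributions.

    Features are min-max rescaled to [0, 1] per batch (constants detached),
    so the CMD normalizers ``(b - a)^k`` are 1; the loss is the mean over
    site pairs of ``||mu_a - mu_b|| + sum_k ||c_k(a) - c_k(b)||`` with
    central moments up to ``order``.
    """
    h = _as_tensor(embeddings)
    sites = np.asarray(sites)
    groups = [np.flatnonzero(sites == s) for s in np.unique(sites)]
    if any(len(g) == 0 for g in groups) or not groups:
        raise ValueError("every site group must be nonempty")
    lo = h.data.min(axis=0)
    span = h.data.max(axis=0) - lo
    span[span == 0] = 1.0
    scaled = (h + Tensor(-lo)) * Tensor(1.0 / span)

    stats = []
    for g in groups:
        hg = scaled[g]
        mu = hg.mean(axis=0)
        centered = hg + (-mu.reshape(1, -1))
        moments = [mu]
        power = centered
        for _ in range(2, order + 1):
            power = power * centered
            moments.append(power.mean(axis=0))
        stats.append(moments)

    out = None
    n_pairs = 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for k in range(order):
                diff = stats[i][k] - stats[j][k]
                term = ((diff * diff).sum() + 1e-12).sqrt()
                out = term if out is None else out + term
            n_pairs += 1
    return out * (1.0 / n_pairs)


def total_loss(cls_total: Tensor, specific: Tensor, common: Tensor,
               site: Tensor, cmd: Tensor, *, weights=None) -> Tensor:
    """``L = L_cls + L_specific + L_common + (L_site + L_CMD)``.

    Per-term weights default to 1 and are exposed for ablations and for the
    training harness's CMD rebalancing (``cmd``/``site`` scale inside the
    domain term, ``domain`` scales the whole term).
    """
    w = {"cls": 1.0, "specific": 1.0, "common": 1.0, "domain": 1.0,
         "site": 1.0, "cmd": 1.0}
    if weights:
        unknown = set(weights) - set(w)
        if unknown:
            raise ValueError(f"unknown loss weights: {sorted(unknown)}")
        w.update(weights)
    return (cls_total * w["cls"] + specific * w["specific"]
            + common * w["common"]
            + (site * w["site"] + cmd * w["cmd"]) * w["domain"])


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))
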