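"""Post-hoc interpretation of trained models.

Functional channel: learned per-subject adjacencies are averaged over the CV
folds in which the subject was a training sample, symmetrized, and averaged
within the case and control groups; the case-minus-control differential
matrix yields the top enhanced/diminished edges and the highest-degree
regions (degree = row sums of the absolute differential).

Anatomical channel: each named structural "character" block is zeroed at
inference across all CV folds; the drop in pooled test AUROC relative to the
unmasked model ranks character importance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .global_model import dense_laplacian
from .population import build_knn_graph
from .training import FoldArtifact, PreparedCohort, _predict, compute_metrics

__all__ = [
    "DifferentialFc",
    "collect_fold_adjacencies",
    "average_learned_fc",
    "group_differential",
    "top_edges",
    "top_regions",
    "mask_character_importance",
]


@dataclass
class DifferentialFc:
    mean_fc_case: np.ndarray
    mean_fc_control: np.ndarray
    diff: np.ndarray
    abs_diff: np.ndarray
    roi_labels: list

    def __post_init__(self):
        assert np.allclose(self.diff,
                           self.mean_fc_case - self.mean_fc_control)
        assert np.allclose(self.abs_diff, np.abs(self.diff))


def collect_fold_adjacencies(artifacts: list[FoldArtifact]) -> dict:
    """Per-subject list of learned adjacencies from the folds in which the
    subject belonged to the training set."""
    per_subject: dict[int, list[np.ndarray]] = {}
    for art in artifacts:
        if art.learned_adjacency is None:
            continue
        for idx in art.train_idx:
            per_subject.setdefault(int(idx), []).append(
                art.learned_adjacency[idx])
    return per_subject


def average_learned_fc(per_fold: dict) -> dict:
    """Elementwise mean per subject across folds."""
    empty = [s for s, mats in per_fold.items() if len(mats) == 0]
    if empty or not per_fold:
        raise ValueError(f"no adjacencies for subject(s) {sorted(empty)}")
    return {s: np.mean(mats, axis=0) for s, mats in per_fold.items()}


def group_differential(subject_fc: dict, labels: np.ndarray,
                       roi_labels: list | None = None) -> DifferentialFc:
    """Case and control group means of the (symmetrized) learned FC and
    their difference (case - control)."""
    labels = np.asarray(labels)
    subjects = sorted(subject_fc)
    ls = labels[subjects]
    if len(np.unique(ls)) < 2:
        raise ValueError("both classes are required")
    stack = np.stack([(subject_fc[s] + subject_fc[s].T) / 2.0
                      for s in subjects])
    case = stack[ls == 1].mean(axis=0)
    control = stack[ls == 0].mean(axis=0)
    diff = case - control
    n = diff.shape[0]
    roi_labels = roi_labels or [f"ROI_{i:02d}" for i in range(n)]
    return DifferentialFc(mean_fc_case=case, mean_fc_control=control,
                          diff=diff, abs_diff=np.abs(diff),
                          roi_labels=list(roi_labels))


def _ranked_upper_edges(diff: np.ndarray) -> pd.DataFrame:
    n = diff.shape[0]
    i, j = np.triu_indices(n, k=1)
    return pd.DataFrame({"i": i, "j": j, "delta": diff[i, j]})


def top_edges(dfc: DifferentialFc, k: int = 5, *,
              allow_empty: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k most positive (enhanced) and most negative (diminished) entries
    of the strict upper triangle; ties break on (i, j) lexicographic order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = _ranked_upper_edges(dfc.diff)
    if k > len(edges):
        raise ValueError(f"k={k} exceeds the {len(edges)} available edges")
    if not allow_empty and np.all(dfc.diff == 0):
        raise ValueError("all-zero differential matrix")

    def pick(frame, ascending):
        ordered = frame.sort_values(["delta", "i", "j"],
                                    ascending=[ascending, True, True],
                                    kind="mergesort").head(k).copy()
        ordered["roi_a"] = [dfc.roi_labels[x] for x in ordered["i"]]
        ordered["roi_b"] = [dfc.roi_labels[x] for x in ordered["j"]]
        ordered["rank"] = np.arange(1, len(ordered) + 1)
        return ordered.reset_index(drop=True)

    enhanced = pick(edges, ascending=False)
    enhanced["direction"] = "enhanced"
    diminished = pick(edges, ascending=True)
    diminished["direction"] = "diminished"
    return enhanced, diminished


def top_regions(dfc: DifferentialFc, k: int = 10) -> pd.DataFrame:
    """Highest-degree ROIs, degree = row sums of the absolute differential."""
    n = dfc.abs_diff.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} regions")
    degree = dfc.abs_diff.sum(axis=1)
    order = np.lexsort((np.arange(n), -degree))[:k]
    return pd.DataFrame({"roi": [dfc.roi_labels[i] for i in order],
                         "roi_index": order, "degree": degree[order],
                         "rank": np.arange(1, k + 1)})


def mask_character_importance(artifacts: list[FoldArtifact],
                              prep: PreparedCohort,
                              character_partition: dict,
                              top_k: int = 5,
                              k_neighbors: int = 10) -> pd.DataFrame:
    """Mask-one-character structural importance over all CV folds.

    For each character block the corresponding structural feature positions
    are zeroed at inference (features are train-fold standardized, so zero
    equals mean imputation) and the inference-time structural KNN graph is
    rebuilt from the masked features; importance = pooled unmasked test
    AUROC minus the masked one.  Output is sorted descending with the top-k
    flagged.
    """
    p = prep.struct.shape[1]
    covered = np.concatenate([np.asarray(v) for v in character_partition.values()])
    if len(covered) != p or len(np.unique(covered)) != p:
        raise ValueError("character partition must cover the structural "
                         "vector exactly once")

    def pooled_auroc(mask_cols: np.ndarray | None) -> float:
        probs, labels = [], []
        for art in artifacts:
            feats = dict(art.features)
            laps = dict(art.laplacians_np)
            struct = np.array(feats["structural"], copy=True)
            if mask_cols is not None:
                struct[:, mask_cols] = 0.0
                graph = build_knn_graph(struct, k_neighbors, "structural")
                laps["structural"] = dense_laplacian(graph.weights)
            feats["structural"] = struct
            pr = _predict(art.global_model, art.graphs, laps, feats)
            probs.append(pr[art.test_idx])
            labels.append(prep.labels[art.test_idx])
        return compute_metrics(np.concatenate(probs),
                               np.concatenate(labels))["AUROC"]

    baseline = pooled_auroc(None)
    rows = []
    for name, cols in character_partition.items():
        rows.append({"character": name,
                     "masked_auroc": pooled_auroc(np.asarray(cols)),
                     "baseline_auroc": baseline})
    out = pd.DataFrame(rows)
    out["auroc_drop"] = out["baseline_auroc"] - out["masked_auroc"]
    out = out.sort_values(["auroc_drop", "character"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["top"] = out["rank"] <= top_k
    return out
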