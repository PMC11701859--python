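"""Training loops, cross-validation harnesses, metrics, and calibration.

Two training regimes are provided.  *Two-stage*: the local ROI model is
trained alone on its classification loss, then frozen; its embeddings seed
the functional population graph and the global model is trained with the
full objective minus the local classification term.  *End-to-end*: one Adam
optimizer covers all parameters and the complete objective; gradients from
the global loss reach the recurrent encoder and graph generator.

Cross-validation is transductive: held-out subjects are present as graph
nodes but their labels never enter any loss, and harmonization is fitted on
training-fold subjects only.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from . import losses as L
from . import nn
from .features import apply_combat, fit_combat, pearson_fc, standardize_series, window_series
from .global_model import GlobalConfig, SubjectGnn, dense_laplacian
from .local_model import LocalConfig, RoiGnn
from .nn import Tensor
from .population import (SubjectGraph, build_knn_graph, encode_demographics,
                         functional_node_features, knn_support)
from .synthetic import CohortBundle

__all__ = [
    "TrainConfig",
    "EvalReport",
    "FoldArtifact",
    "prepare_cohort",
    "train_two_stage",
    "train_end_to_end",
    "kfold_cv",
    "loso_cv",
    "calibration_curve",
    "subgroup_eval",
    "resampled_eval",
    "compute_metrics",
    "fused_embeddings",
    "site_probe_accuracy",
    "snowball_layer_silhouettes",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for both training regimes.

    The optimizer follows the published schedule shape (Adam, learning rate
    halved on a fixed period); epoch counts default to desk-scale values that
    converge on the synthetic cohorts and are fully configurable.
    """

    mode: str = "end_to_end"            # or "two_stage"
    lr: float = 1e-2
    lr_halving_period: int = 100
    max_epochs: int = 40                # global / end-to-end epochs
    stage1_epochs: int = 20             # local-model epochs (two-stage stage 1)
    lambda_local: float = 0.2
    k_neighbors: int = 10
    snowball_layers: int = 9
    seed: int = 0
    feature_mode: str = "Concat"        # Corr | Emb | Concat
    adversarial: bool = True
    grl_lambda: float = 1.0
    cmd_order: int = 5
    harmonize: bool = True
    window_width: int | None = None
    gru_hidden: int = 16
    gcn_widths: tuple = (64, 32, 16)
    layer_width: int = 32
    collapse_width: int = 64
    embedding_dim: int = 32
    snowball_p: int = 0
    cmd_weight: float = 0.3
    loss_weights: dict | None = None

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.max_epochs < 1 or self.stage1_epochs < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.mode not in ("two_stage", "end_to_end"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EvalReport:
    """Pooled and per-fold metrics plus the per-subject probability table."""

    table: pd.DataFrame               # subject, site, label, probability, fold
    per_fold: pd.DataFrame            # one row per fold
    pooled: dict
    loss_log: pd.DataFrame | None = None
    config: TrainConfig | None = None

    def calibration(self, n_bins: int = 10) -> pd.DataFrame:
        return calibration_curve(self.table["probability"].to_numpy(),
                                 self.table["label"].to_numpy(), n_bins)

    def summary(self) -> pd.DataFrame:
        rows = {k: [v] for k, v in self.pooled.items()}
        return pd.DataFrame(rows, index=["pooled"])


@dataclass
class FoldArtifact:
    """Everything needed to re-run inference for one CV fold."""

    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    local_model: RoiGnn | None
    global_model: SubjectGnn
    features: dict                    # channel -> np.ndarray node features
    laplacians_np: dict               # static laplacians (functional/structural)
    graphs: dict
    probabilities: np.ndarray         # all-subject class-1 probabilities
    learned_adjacency: np.ndarray | None  # (S, n, n) eval-mode adjacency


# -- feature pipeline ----------------------------------------------------------


@dataclass
class PreparedCohort:
    series: np.ndarray                # standardized, windowed (S, n, t)
    fc: np.ndarray                    # (S, n, n)
    struct: np.ndarray
    eta: np.ndarray
    labels: np.ndarray
    sites: np.ndarray
    bundle: CohortBundle


def prepare_cohort(bundle: CohortBundle, config: TrainConfig) -> PreparedCohort:
    """Window, standardize, and correlate the time series; encode eta."""
    width = config.window_width or bundle.series.shape[-1]
    series = np.stack([window_series(s, width) for s in bundle.series])
    series = standardize_series(series).astype(np.float32)
    fc = np.stack([pearson_fc(s) for s in series]).astype(np.float32)
    eta = encode_demographics(bundle.demographics, bundle.spec.n_sites)
    return PreparedCohort(series=series, fc=fc,
                          struct=bundle.struct_features.copy(),
                          eta=eta.astype(np.float32),
                          labels=bundle.labels.copy(), sites=bundle.sites,
                          bundle=bundle)


def _harmonized_struct(prep: PreparedCohort, train_idx: np.ndarray,
                       config: TrainConfig) -> np.ndarray:
    """Harmonize then z-score the structural features.

    ComBat is fitted on the training fold only; held-out labels enter as NaN
    (mapped to the training mean, i.e. no label adjustment).  Columns are
    standardized with training-fold statistics so that a zeroed feature at
    inference equals mean imputation (the masking protocol relies on this).
    """
    x = prep.struct.astype(float)
    if config.harmonize and len(np.unique(prep.sites)) > 1:
        demo = prep.bundle.demographics
        label_cov = np.full(len(prep.labels), np.nan)
        label_cov[train_idx] = prep.labels[train_idx]
        cov = np.column_stack([label_cov, demo["age"].to_numpy(),
                               demo["sex"].to_numpy()])
        model = fit_combat(x[train_idx], prep.sites[train_idx], cov[train_idx])
        x = apply_combat(model, x, prep.sites, cov)
    mu = x[train_idx].mean(axis=0)
    sd = x[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    return ((x - mu) / sd).astype(np.float32)


# -- single-fold training ------------------------------------------------------


def _local_forward(model: RoiGnn, prep: PreparedCohort):
    return model(Tensor(prep.series), Tensor(prep.fc))


def _build_graphs(prep: PreparedCohort, x_f: np.ndarray, struct: np.ndarray,
                  config: TrainConfig) -> dict:
    k = config.k_neighbors
    graphs = {
        "functional": build_knn_graph(x_f, k, "functional"),
        "structural": build_knn_graph(struct, k, "structural"),
    }
    # Demographic support from cosine similarity of eta; weights are learned.
    eta = prep.eta
    norms = np.linalg.norm(eta, axis=1, keepdims=True)
    unit = eta / np.where(norms == 0, 1.0, norms)
    support = knn_support(unit @ unit.T, k)
    placeholder = np.where(support, 0.5, 0.0)
    np.fill_diagonal(placeholder, 0.0)
    graphs["demographic"] = SubjectGraph(node_features=eta,
                                         weights=placeholder,
                                         channel="demographic",
                                         support=support)
    return graphs


def _global_setup(prep: PreparedCohort, graphs: dict, channel_dims: dict,
                  config: TrainConfig, rng: np.random.Generator) -> SubjectGnn:
    gconf = GlobalConfig(channel_dims=channel_dims,
                         n_sites=prep.bundle.spec.n_sites,
                         snowball_layers=config.snowball_layers,
                         layer_width=config.layer_width,
                         collapse_width=config.collapse_width,
                         embedding_dim=config.embedding_dim,
                         p=config.snowball_p,
                         grl_lambda=config.grl_lambda)
    return SubjectGnn(gconf, rng, eta_dim=prep.eta.shape[1])


def _objective(model: SubjectGnn, bundle, global_logits, local_logits,
               prep: PreparedCohort, train_idx, config: TrainConfig,
               include_local_ce: bool) -> L.LossBundle:
    labels = prep.labels
    if include_local_ce and local_logits is not None:
        cls_total, ce_g, ce_l = L.classification_loss(
            global_logits, local_logits, labels, train_idx, config.lambda_local)
        ce_l_val = float(ce_l.data)
    else:
        ce_g = L.cross_entropy(global_logits, labels, train_idx)
        cls_total, ce_l_val = ce_g, 0.0
    spec_loss = L.modality_specific_loss(bundle.specific, bundle.common)
    common_loss = L.modality_similarity_loss(bundle.common_per_channel)
    weights = {"cmd": config.cmd_weight, **(config.loss_weights or {})}
    if config.adversarial:
        site_logits = model.site_logits(bundle.fused)
        site_loss = L.site_adversarial_loss(site_logits, prep.sites)
        cmd = L.cmd_loss(bundle.fused, prep.sites, order=config.cmd_order)
        total = L.total_loss(cls_total, spec_loss, common_loss, site_loss, cmd,
                             weights=weights)
        site_val, cmd_val = float(site_loss.data), float(cmd.data)
    else:
        zero = Tensor(np.zeros(()))
        total = L.total_loss(cls_total, spec_loss, common_loss, zero, zero,
                             weights=weights)
        site_val = cmd_val = 0.0
    return L.LossBundle(total=total, cls_global=float(ce_g.data),
                        cls_local=ce_l_val, specific=float(spec_loss.data),
                        common=float(common_loss.data), site=site_val,
                        cmd=cmd_val, lambda_local=config.lambda_local)


def _check_finite(loss: Tensor, epoch: int, log: list) -> None:
    if not np.isfinite(loss.data):
        raise FloatingPointError(
            f"non-finite training loss at epoch {epoch}; last components: "
            f"{log[-1] if log else 'n/a'}")


def train_local_stage(prep: PreparedCohort, train_idx: np.ndarray,
                      config: TrainConfig, rng: np.random.Generator,
                      epochs: int | None = None) -> tuple[RoiGnn, list]:
    """Stage 1: the local ROI model on its classification loss alone."""
    lconf = LocalConfig(n_rois=prep.series.shape[1],
                        n_timepoints=prep.series.shape[2],
                        gru_hidden=config.gru_hidden,
                        gcn_widths=tuple(config.gcn_widths))
    model = RoiGnn(lconf, rng)
    opt = nn.Adam(model.parameters(), lr=config.lr,
                  halve_every=config.lr_halving_period)
    log = []
    for epoch in range(epochs or config.stage1_epochs):
        model.train()
        out = _local_forward(model, prep)
        loss = L.cross_entropy(out.local_logits, prep.labels, train_idx)
        _check_finite(loss, epoch, log)
        opt.zero_grad()
        loss.backward()
        opt.step()
        log.append({"epoch": epoch, "L_cls_local": float(loss.data)})
    return model, log


def _eval_local(model: RoiGnn, prep: PreparedCohort):
    model.eval()
    with nn.autodiff.no_grad():
        out = _local_forward(model, prep)
    model.train()
    return out


def train_two_stage(prep: PreparedCohort, train_idx: np.ndarray,
                    config: TrainConfig,
                    local_model: RoiGnn | None = None) -> FoldArtifact:
    """Two-stage regime on one train/test split (transductive)."""
    rng = np.random.default_rng(config.seed)
    if local_model is None:
        local_model, _ = train_local_stage(prep, train_idx, config, rng)
    local_out = _eval_local(local_model, prep)
    emb = local_out.graph_embedding.data

    struct = _harmonized_struct(prep, train_idx, config)
    x_f = np.asarray(functional_node_features(prep.fc, emb, config.feature_mode))
    graphs = _build_graphs(prep, x_f, struct, config)
    features = {"functional": x_f.astype(np.float32), "structural": struct,
                "demographic": prep.eta}
    channel_dims = {ch: features[ch].shape[1] for ch in features}
    model = _global_setup(prep, graphs, channel_dims, config, rng)
    laps_np = {ch: dense_laplacian(graphs[ch].weights)
               for ch in ("functional", "structural")}

    opt = nn.Adam(model.parameters(), lr=config.lr,
                  halve_every=config.lr_halving_period)
    log = []
    for epoch in range(config.max_epochs):
        laps = {ch: Tensor(laps_np[ch]) for ch in laps_np}
        laps["demographic"] = model.channel_laplacian(graphs["demographic"])
        bundle, logits = model(laps, features)
        lb = _objective(model, bundle, logits, None, prep, train_idx, config,
                        include_local_ce=False)
        _check_finite(lb.total, epoch, log)
        opt.zero_grad()
        lb.total.backward()
        opt.step()
        log.append({"epoch": epoch, **lb.as_dict()})

    probs = _predict(model, graphs, laps_np, features)
    nn.release_workspaces(local_model)
    return FoldArtifact(fold=-1, train_idx=train_idx,
                        test_idx=_complement(train_idx, len(prep.labels)),
                        local_model=local_model, global_model=model,
                        features=features, laplacians_np=laps_np,
                        graphs=graphs, probabilities=probs,
                        learned_adjacency=local_out.learned_adjacency.data.copy()
                        ), pd.DataFrame(log)


def train_end_to_end(prep: PreparedCohort, train_idx: np.ndarray,
                     config: TrainConfig) -> tuple[FoldArtifact, pd.DataFrame]:
    """Joint regime: one optimizer, full objective, gradients into the
    recurrent encoder and graph generator."""
    rng = np.random.default_rng(config.seed)
    lconf = LocalConfig(n_rois=prep.series.shape[1],
                        n_timepoints=prep.series.shape[2],
                        gru_hidden=config.gru_hidden,
                        gcn_widths=tuple(config.gcn_widths))
    local_model = RoiGnn(lconf, rng)

    struct = _harmonized_struct(prep, train_idx, config)
    init_out = _eval_local(local_model, prep)
    x_f0 = np.asarray(functional_node_features(
        prep.fc, init_out.graph_embedding.data, config.feature_mode))
    graphs = _build_graphs(prep, x_f0, struct, config)
    channel_dims = {"functional": x_f0.shape[1], "structural": struct.shape[1],
                    "demographic": prep.eta.shape[1]}
    model = _global_setup(prep, graphs, channel_dims, config, rng)
    laps_np = {ch: dense_laplacian(graphs[ch].weights)
               for ch in ("functional", "structural")}

    params = list(local_model.parameters()) + list(model.parameters())
    opt = nn.Adam(params, lr=config.lr, halve_every=config.lr_halving_period)
    log = []
    needs_emb = config.feature_mode in ("Emb", "Concat")
    for epoch in range(config.max_epochs):
        local_out = _local_forward(local_model, prep)
        if needs_emb:
            x_f = functional_node_features(prep.fc, local_out.graph_embedding,
                                           config.feature_mode)
        else:
            x_f = Tensor(x_f0)
        features = {"functional": x_f, "structural": struct,
                    "demographic": prep.eta}
        laps = {ch: Tensor(laps_np[ch]) for ch in laps_np}
        laps["demographic"] = model.channel_laplacian(graphs["demographic"])
        bundle, logits = model(laps, features)
        lb = _objective(model, bundle, logits, local_out.local_logits, prep,
                        train_idx, config, include_local_ce=True)
        _check_finite(lb.total, epoch, log)
        opt.zero_grad()
        lb.total.backward()
        opt.step()
        log.append({"epoch": epoch, **lb.as_dict()})

    local_out = _eval_local(local_model, prep)
    x_f = np.asarray(functional_node_features(
        prep.fc, local_out.graph_embedding.data, config.feature_mode))
    features = {"functional": x_f.astype(np.float32), "structural": struct,
                "demographic": prep.eta}
    probs = _predict(model, graphs, laps_np, features)
    nn.release_workspaces(local_model)
    return FoldArtifact(fold=-1, train_idx=train_idx,
                        test_idx=_complement(train_idx, len(prep.labels)),
                        local_model=local_model, global_model=model,
                        features=features, laplacians_np=laps_np,
                        graphs=graphs, probabilities=probs,
                        learned_adjacency=local_out.learned_adjacency.data.copy()
                        ), pd.DataFrame(log)


def _predict(model: SubjectGnn, graphs: dict, laps_np: dict,
             features: dict) -> np.ndarray:
    model.eval()
    with nn.autodiff.no_grad():
        laps = {ch: Tensor(laps_np[ch]) for ch in laps_np}
        laps["demographic"] = model.channel_laplacian(graphs["demographic"])
        _, logits = model(laps, features)
    model.train()
    return np.asarray(nn.softmax(logits, axis=-1).data[:, 1], dtype=float)


def _complement(idx: np.ndarray, n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    mask[idx] = False
    return np.flatnonzero(mask)


# -- cross-validation ----------------------------------------------------------


def _fit_split(prep, train_idx, config) -> tuple[FoldArtifact, pd.DataFrame]:
    if config.mode == "two_stage":
        return train_two_stage(prep, train_idx, config)
    return train_end_to_end(prep, train_idx, config)


def kfold_cv(bundle: CohortBundle, config: TrainConfig, folds: int = 10,
             keep_artifacts: bool = False) -> EvalReport | tuple:
    """Stratified (label x site) k-fold transductive cross-validation."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    prep = prepare_cohort(bundle, config)
    strata = prep.labels * bundle.spec.n_sites + prep.sites
    splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                               random_state=config.seed)
    artifacts, rows, logs = [], [], []
    for fold, (train_idx, test_idx) in enumerate(
            splitter.split(np.zeros(len(prep.labels)), strata)):
        if len(np.unique(prep.labels[train_idx])) < 2 \
                or len(np.unique(prep.labels[test_idx])) < 2:
            raise ValueError(f"fold {fold} lacks one of the classes")
        art, log = _fit_split(prep, train_idx, config)
        art = dataclasses.replace(art, fold=fold, test_idx=test_idx,
                                  train_idx=train_idx)
        artifacts.append(art)
        log["fold"] = fold
        logs.append(log)
        rows.append(pd.DataFrame({
            "subject": test_idx,
            "site": prep.sites[test_idx],
            "label": prep.labels[test_idx],
            "probability": art.probabilities[test_idx],
            "fold": fold,
        }))
    report = _assemble_report(pd.concat(rows, ignore_index=True),
                              pd.concat(logs, ignore_index=True), config)
    if keep_artifacts:
        return report, artifacts, prep
    return report


def loso_cv(bundle: CohortBundle, config: TrainConfig,
            keep_artifacts: bool = False) -> EvalReport | tuple:
    """Leave-one-site-out cross-validation: each site held out once."""
    prep = prepare_cohort(bundle, config)
    sites = np.unique(prep.sites)
    if sites.size < 2:
        raise ValueError("LOSO needs at least two sites")
    artifacts, rows, logs = [], [], []
    for fold, held in enumerate(sites):
        test_idx = np.flatnonzero(prep.sites == held)
        train_idx = np.flatnonzero(prep.sites != held)
        art, log = _fit_split(prep, train_idx, config)
        art = dataclasses.replace(art, fold=fold, test_idx=test_idx,
                                  train_idx=train_idx)
        artifacts.append(art)
        log["fold"] = fold
        logs.append(log)
        rows.append(pd.DataFrame({
            "subject": test_idx, "site": prep.sites[test_idx],
            "label": prep.labels[test_idx],
            "probability": art.probabilities[test_idx], "fold": fold,
        }))
    report = _assemble_report(pd.concat(rows, ignore_index=True),
                              pd.concat(logs, ignore_index=True), config)
    if keep_artifacts:
        return report, artifacts, prep
    return report


def _assemble_report(table: pd.DataFrame, loss_log: pd.DataFrame,
                     config: TrainConfig) -> EvalReport:
    per_fold = []
    for fold, grp in table.groupby("fold"):
        m = compute_metrics(grp["probability"].to_numpy(),
                            grp["label"].to_numpy())
        per_fold.append({"fold": fold, "n": len(grp), **m})
    per_fold = pd.DataFrame(per_fold)
    pooled = compute_metrics(table["probability"].to_numpy(),
                             table["label"].to_numpy())
    for key in ("ACC", "AUROC", "precision", "recall", "F1"):
        pooled[f"{key}_mean"] = float(per_fold[key].mean())
        pooled[f"{key}_sd"] = float(per_fold[key].std(ddof=1)) \
            if len(per_fold) > 1 else 0.0
    return EvalReport(table=table, per_fold=per_fold, pooled=pooled,
                      loss_log=loss_log, config=config)


# -- metrics -------------------------------------------------------------------


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> dict:
    """ACC, AUROC, precision, recall, F1 at the given probability threshold."""
    labels = np.asarray(labels)
    pred = (np.asarray(probabilities) >= threshold).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auroc = (skm.roc_auc_score(labels, probabilities)
                 if np.unique(labels).size > 1 else float("nan"))
        return {
            "ACC": float(skm.accuracy_score(labels, pred)),
            "AUROC": float(auroc),
            "precision": float(skm.precision_score(labels, pred,
                                                   zero_division=0)),
            "recall": float(skm.recall_score(labels, pred, zero_division=0)),
            "F1": float(skm.f1_score(labels, pred, zero_division=0)),
        }


def calibration_curve(probabilities: np.ndarray, labels: np.ndarray,
                      n_bins: int = 10) -> pd.DataFrame:
    """Equal-width probability bins with observed positive fractions."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if probabilities.min() < 0 or probabilities.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probabilities, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "mean_predicted": float(probabilities[mask].mean()) if mask.any() else np.nan,
            "observed_fraction": float(labels[mask].mean()) if mask.any() else np.nan,
            "count": int(mask.sum()),
        })
    out = pd.DataFrame(rows)
    assert out["count"].sum() == len(labels)
    return out


def subgroup_eval(report: EvalReport, subject_filter) -> EvalReport:
    """Recompute metrics on a subset of the probability table.

    ``subject_filter`` is a boolean mask over the table rows or a callable
    on the table returning one.
    """
    table = report.table
    mask = subject_filter(table) if callable(subject_filter) else np.asarray(subject_filter)
    sub = table[mask]
    if len(sub) == 0:
        raise ValueError("empty subgroup")
    per_fold = []
    for fold, grp in sub.groupby("fold"):
        per_fold.append({"fold": fold, "n": len(grp),
                         **compute_metrics(grp["probability"].to_numpy(),
                                           grp["label"].to_numpy())})
    pooled = compute_metrics(sub["probability"].to_numpy(),
                             sub["label"].to_numpy())
    return EvalReport(table=sub.reset_index(drop=True),
                      per_fold=pd.DataFrame(per_fold), pooled=pooled,
                      config=report.config)


def fused_embeddings(artifact: FoldArtifact) -> np.ndarray:
    """Eval-mode fused population embedding H for every subject."""
    model = artifact.global_model
    model.eval()
    with nn.autodiff.no_grad():
        laps = {ch: Tensor(artifact.laplacians_np[ch])
                for ch in artifact.laplacians_np}
        laps["demographic"] = model.channel_laplacian(
            artifact.graphs["demographic"])
        bundle, _ = model(laps, artifact.features)
    model.train()
    return np.asarray(bundle.fused.data, dtype=float)


def site_probe_accuracy(embeddings: np.ndarray, sites: np.ndarray,
                        seed: int = 0, test_fraction: float = 0.3) -> float:
    """Held-out accuracy of a fresh logistic-regression site probe.

    Measures how much site information survives in learned embeddings; used
    to compare adversarial vs non-adversarial training.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    x = np.asarray(embeddings, dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
    tr, te = train_test_split(np.arange(len(sites)), test_size=test_fraction,
                              stratify=sites, random_state=seed)
    probe = LogisticRegression(max_iter=2000, random_state=seed)
    probe.fit(x[tr], sites[tr])
    return float(probe.score(x[te], sites[te]))


def snowball_layer_silhouettes(bundle: CohortBundle,
                               config: TrainConfig) -> list[float]:
    """Per-layer silhouette (true labels) of the trained functional
    snowball block's hidden representations.

    A representation-quality probe for the anti-oversmoothing property of
    densely connected stacks: in a trained deep snowball, later layers
    cluster the classes more than early ones.  The probe trains on the
    classification loss alone so that the layer geometry reflects the
    architecture rather than the auxiliary independence/similarity/domain
    objectives (which deliberately reshape the embeddings for other goals).
    Returns one silhouette per hidden layer (1 .. snowball_layers).
    """
    from sklearn.metrics import silhouette_score

    cfg = dataclasses.replace(
        config, feature_mode="Corr", stage1_epochs=1,
        loss_weights={"specific": 0.0, "common": 0.0, "domain": 0.0})
    prep = prepare_cohort(bundle, cfg)
    art, _ = train_two_stage(prep, np.arange(len(prep.labels)), cfg)
    model = art.global_model
    model.eval()
    with nn.autodiff.no_grad():
        _, layers = model.ms_blocks["functional"](
            Tensor(art.laplacians_np["functional"]),
            Tensor(np.asarray(art.features["functional"], dtype=np.float32)),
            return_layers=True)
    # layers[0] is the input X; hidden layers follow
    return [float(silhouette_score(h.data, prep.labels))
            for h in layers[1:]]


def resampled_eval(report: EvalReport, case_control_ratio: float = 0.25,
                   n_boot: int = 100, seed: int = 0) -> pd.DataFrame:
    """Bootstrap evaluation on an unbalanced case:control ratio."""
    rng = np.random.default_rng(seed)
    table = report.table
    cases = table.index[table["label"] == 1].to_numpy()
    controls = table.index[table["label"] == 0].to_numpy()
    n_cases = max(1, int(round(len(controls) * case_control_ratio)))
    rows = []
    for b in range(n_boot):
        pick = np.concatenate([rng.choice(cases, size=n_cases, replace=True),
                               controls])
        sub = table.loc[pick]
        rows.append({"bootstrap": b,
                     **compute_metrics(sub["probability"].to_numpy(),
                                       sub["label"].to_numpy())})
    return pd.DataFrame(rows)
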