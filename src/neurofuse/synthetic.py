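"""Synthetic multi-site case/control cohort generator.

Every downstream stage of the package (functional-connectivity features,
harmonization, the local and global graph models, interpretation) is
exercised on cohorts produced here, with full ground-truth bookkeeping:

* group-differential ROI-ROI covariance — a set of *enhanced* and
  *diminished* edges whose covariance is shifted by ``edge_effect`` in cases;
* group mean shifts of ``struct_effect`` standardized units on a subset of
  named structural feature blocks ("characters");
* a case/control education difference of ``demo_effect`` standardized units;
* per-site batch effects in the ComBat location-scale generative form
  (additive per-feature shift, multiplicative per-feature scale) on the
  structural features, and a per-ROI additive signal-mean offset on the
  BOLD-like time series.

The generator does not attempt realistic hemodynamics or scanner physics:
time series are draws from a multivariate normal whose covariance carries
the planted group structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "CohortBundle",
    "default_cohort_spec",
    "generate_cohort",
    "planted_differential_matrix",
    "analytic_group_covariances",
    "save_bundle",
    "load_bundle",
]

# Planted edge sets used by the default study conditions (ROI index pairs).
_DEFAULT_ENHANCED = ((2, 5), (7, 12), (1, 20), (9, 14), (3, 28))
_DEFAULT_DIMINISHED = ((4, 11), (6, 19), (15, 22), (0, 13), (8, 25))


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort, including ground truth."""

    n_subjects: int
    n_rois: int = 32
    n_timepoints: int = 120
    n_sites: int = 3
    case_fraction: float = 0.5
    enhanced_edges: tuple = ()
    diminished_edges: tuple = ()
    edge_effect: float = 0.0
    n_struct_features: int = 60
    n_characters: int = 10
    informative_characters: tuple = ()
    struct_effect: float = 0.0
    site_shift_scale: float = 0.4
    site_scale_sd: float = 0.2
    demo_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie strictly in (0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_struct_features % self.n_characters:
            raise ValueError("n_struct_features must split evenly into characters")
        edges = [tuple(e) for e in self.enhanced_edges] + \
                [tuple(e) for e in self.diminished_edges]
        seen = set()
        for i, j in edges:
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"edge ({i}, {j}) is not a valid ROI pair")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"edge {key} listed twice across edge sets")
            seen.add(key)
        unknown = set(self.informative_characters) - set(self.character_names)
        if unknown:
            raise ValueError(f"unknown characters: {sorted(unknown)}")

    @property
    def character_names(self) -> list[str]:
        return [f"character_{i:02d}" for i in range(self.n_characters)]

    @property
    def character_width(self) -> int:
        return self.n_struct_features // self.n_characters

    def character_partition(self) -> dict[str, np.ndarray]:
        """Contiguous equal-width blocks of structural feature indices."""
        w = self.character_width
        return {name: np.arange(i * w, (i + 1) * w)
                for i, name in enumerate(self.character_names)}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_cohort_spec(n_subjects: int = 300, seed: int = 0, *,
                        edge_effect: float = 0.5, struct_effect: float = 0.8,
                        demo_effect: float = 0.5, site_shift_scale: float = 0.4,
                        site_scale_sd: float = 0.2) -> CohortSpec:
    """The default study conditions: 32 ROIs, 3 sites, five enhanced and five
    diminished edges, five informative structural characters."""
    return CohortSpec(
        n_subjects=n_subjects,
        enhanced_edges=_DEFAULT_ENHANCED,
        diminished_edges=_DEFAULT_DIMINISHED,
        edge_effect=edge_effect,
        informative_characters=("character_01", "character_03", "character_04",
                                "character_06", "character_08"),
        struct_effect=struct_effect,
        demo_effect=demo_effect,
        site_shift_scale=site_shift_scale,
        site_scale_sd=site_scale_sd,
        seed=seed,
    )


@dataclass
class CohortBundle:
    """Generated cohort: arrays plus demographics and the ground truth."""

    series: np.ndarray            # (n_subjects, n_rois, n_timepoints)
    struct_features: np.ndarray   # (n_subjects, n_struct_features)
    demographics: pd.DataFrame    # columns: age, sex, education, site
    labels: np.ndarray            # (n_subjects,) 0=control, 1=case
    spec: CohortSpec

    def __post_init__(self):
        n = len(self.labels)
        if not (self.series.shape[0] == self.struct_features.shape[0]
                == len(self.demographics) == n):
            raise ValueError("per-subject containers disagree on length")
        if self.demographics["site"].max() >= self.spec.n_sites:
            raise ValueError("site index out of range")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")

    @property
    def sites(self) -> np.ndarray:
        return self.demographics["site"].to_numpy()

    @property
    def roi_labels(self) -> list[str]:
        return [f"ROI_{i:02d}" for i in range(self.spec.n_rois)]


def _base_covariance(n_rois: int, rng: np.random.Generator,
                     rank: int | None = None) -> np.ndarray:
    """Random low-rank-plus-diagonal covariance, rescaled to unit diagonal."""
    rank = rank or max(2, n_rois // 4)
    w = rng.normal(size=(n_rois, rank)) / np.sqrt(rank)
    cov = w @ w.T + 0.8 * np.eye(n_rois)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _repair_pd(cov: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping at ``floor`` followed by re-symmetrization."""
    sym = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    repaired = (vecs * np.clip(vals, floor, None)) @ vecs.T
    return (repaired + repaired.T) / 2.0


def analytic_group_covariances(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """The exact control and case covariance used by :func:`generate_cohort`.

    Cases receive ``+edge_effect`` on enhanced pairs and ``-edge_effect`` on
    diminished pairs (symmetrically), followed by projection to the nearest
    positive-definite matrix.
    """
    rng = np.random.default_rng(spec.seed)
    cov_control = _base_covariance(spec.n_rois, rng)
    delta = planted_differential_matrix(spec)
    cov_case = _repair_pd(cov_control + delta)
    for name, cov in (("control", cov_control), ("case", cov_case)):
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError(
                f"{name} covariance not positive definite after repair; "
                f"offending edges: enhanced={spec.enhanced_edges}, "
                f"diminished={spec.diminished_edges}"
            )
    return cov_control, cov_case


def planted_differential_matrix(spec: CohortSpec) -> np.ndarray:
    """Signed ground-truth matrix: +effect at enhanced pairs, -effect at
    diminished pairs, zero elsewhere; symmetric with a zero diagonal."""
    mat = np.zeros((spec.n_rois, spec.n_rois))
    for i, j in spec.enhanced_edges:
        mat[i, j] = mat[j, i] = spec.edge_effect
    for i, j in spec.diminished_edges:
        mat[i, j] = mat[j, i] = -spec.edge_effect
    return mat


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Draw a full cohort reproducibly from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    cov_control = _base_covariance(spec.n_rois, rng)
    delta = planted_differential_matrix(spec)
    cov_case = _repair_pd(cov_control + delta)
    if np.linalg.eigvalsh(cov_case).min() <= 0:
        raise ValueError(
            "case covariance not positive definite after repair; offending "
            f"edges: enhanced={spec.enhanced_edges}, "
            f"diminished={spec.diminished_edges}"
        )

    n = spec.n_subjects
    n_cases = int(round(spec.case_fraction * n))
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[:n_cases]] = 1

    # Balanced random site assignment.
    sites = np.tile(np.arange(spec.n_sites), n // spec.n_sites + 1)[:n]
    sites = sites[rng.permutation(n)]

    chol = {0: np.linalg.cholesky(cov_control), 1: np.linalg.cholesky(cov_case)}
    series = np.empty((n, spec.n_rois, spec.n_timepoints))
    # Per-site additive signal-mean offset per ROI.
    roi_offsets = rng.normal(0.0, spec.site_shift_scale,
                             size=(spec.n_sites, spec.n_rois))
    for i in range(n):
        z = rng.standard_normal((spec.n_rois, spec.n_timepoints))
        series[i] = chol[labels[i]] @ z + roi_offsets[sites[i], :, None]

    # Structural features: baseline means, unit-ish noise, planted case
    # shifts on informative characters, then ComBat-form site effects.
    p = spec.n_struct_features
    feat_means = rng.normal(0.0, 1.0, size=p)
    x = feat_means + rng.normal(0.0, 1.0, size=(n, p))
    partition = spec.character_partition()
    case_rows = np.flatnonzero(labels == 1)
    for name in spec.informative_characters:
        cols = partition[name]
        x[np.ix_(case_rows, cols)] += spec.struct_effect
    gamma = rng.normal(0.0, spec.site_shift_scale, size=(spec.n_sites, p))
    log_delta = rng.normal(0.0, spec.site_scale_sd, size=(spec.n_sites, p))
    delta_scale = np.exp(log_delta)
    x = x * delta_scale[sites] + gamma[sites]

    age = np.clip(rng.normal(34.0, 11.0, size=n), 18.0, 70.0)
    sex = (rng.uniform(size=n) < 0.6).astype(np.int64)
    education = rng.normal(13.0, 3.0, size=n)
    education[labels == 1] -= spec.demo_effect * 3.0

    demo = pd.DataFrame({
        "age": age,
        "sex": sex,
        "education": education,
        "site": sites.astype(np.int64),
    })
    return CohortBundle(series=series, struct_features=x, demographics=demo,
                        labels=labels, spec=spec)


# -- persistence ---------------------------------------------------------------


def save_bundle(bundle: CohortBundle, path: str | Path) -> None:
    """Persist a bundle as ``<path>.npz`` + ``<path>.json`` + ``<path>.csv``."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"),
                        series=bundle.series,
                        struct_features=bundle.struct_features,
                        labels=bundle.labels)
    sidecar = {
        "spec": _jsonable(bundle.spec.to_dict()),
        "demographics": bundle.demographics.to_dict(orient="list"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    bundle.demographics.assign(label=bundle.labels).to_csv(
        path.with_suffix(".csv"), index=False)


def load_bundle(path: str | Path) -> CohortBundle:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_dict = sidecar["spec"]
    for key in ("enhanced_edges", "diminished_edges"):
        spec_dict[key] = tuple(tuple(e) for e in spec_dict[key])
    spec_dict["informative_characters"] = tuple(spec_dict["informative_characters"])
    spec = CohortSpec(**spec_dict)
    demo = pd.DataFrame(sidecar["demographics"])
    return CohortBundle(series=arrays["series"],
                        struct_features=arrays["struct_features"],
                        demographics=demo, labels=arrays["labels"], spec=spec)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
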