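"""Feature preparation: time-series alignment, standardization, Pearson
functional connectivity, and ComBat batch-effect harmonization.

Time-series signals are z-scored per ROI before entering any model; Fisher's
r-to-z transform is offered separately as an option on the correlation
matrix.  Harmonization follows the standard location-scale empirical-Bayes
formulation: per-feature site locations shrink toward a normal prior and
per-feature site scales toward an inverse-gamma prior, both moment-matched,
while covariates of interest (diagnosis, age, sex) are estimated by least
squares and preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "window_series",
    "standardize_series",
    "pearson_fc",
    "fisher_z",
    "HarmonizationModel",
    "fit_combat",
    "apply_combat",
]


def window_series(series: np.ndarray, width: int, step: int = 1, *,
                  mode: str = "align", subject: str | int | None = None):
    """Truncate an ROI x time matrix with a sliding window.

    ``mode='align'`` (default) returns the first full window, giving every
    subject an equal-length series.  ``mode='augment'`` returns the list of
    all full windows at stride ``step``.
    """
    n, t = series.shape
    if width > t:
        raise ValueError(
            f"window width {width} exceeds series length {t}"
            + (f" for subject {subject}" if subject is not None else "")
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    if mode == "align":
        return series[:, :width]
    if mode == "augment":
        return [series[:, s:s + width] for s in range(0, t - width + 1, step)]
    raise ValueError(f"unknown mode {mode!r}")


def standardize_series(series: np.ndarray) -> np.ndarray:
    """Z-score each ROI row to zero mean and unit standard deviation."""
    mu = series.mean(axis=-1, keepdims=True)
    sd = series.std(axis=-1, keepdims=True)
    flat = sd < 1e-10 * np.maximum(1.0, np.abs(mu))
    if flat.any():
        bad = np.argwhere(flat[..., 0]).ravel().tolist()
        raise ValueError(f"constant signal in ROI row(s) {bad}")
    return (series - mu) / sd


def pearson_fc(series: np.ndarray, *, to_z: bool = False) -> np.ndarray:
    """Pearson correlation matrix of ROI signals (rows).

    With ``to_z=True`` the off-diagonal entries are Fisher r-to-z
    transformed (artanh, correlations clipped at ``|r| <= 1 - 1e-7``).
    """
    n, t = series.shape
    if t < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    sd = series.std(axis=-1)
    flat = sd < 1e-10 * np.maximum(1.0, np.abs(series.mean(axis=-1)))
    if flat.any():
        raise ValueError(
            f"constant signal in ROI row(s) {np.nonzero(flat)[0].tolist()}")
    fc = np.corrcoef(series)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return fisher_z(fc) if to_z else fc


def fisher_z(corr: np.ndarray, clip: float = 1e-7) -> np.ndarray:
    """Fisher r-to-z transform with clipping; the diagonal maps with the rest."""
    return np.arctanh(np.clip(corr, -1.0 + clip, 1.0 - clip))


# -- ComBat harmonization ------------------------------------------------------


@dataclass
class HarmonizationModel:
    """Fitted location-scale harmonization parameters.

    ``gamma_star``/``delta_star`` hold the empirical-Bayes posterior site
    locations and scales per (site, feature), on the standardized scale.
    """

    site_ids: np.ndarray
    grand_mean: np.ndarray          # alpha-hat per feature
    beta: np.ndarray                # (n_covariates, p) covariate coefficients
    pooled_sd: np.ndarray           # per feature
    gamma_star: dict = field(default_factory=dict)
    delta_star: dict = field(default_factory=dict)
    identity: bool = False
    covariate_means: np.ndarray | None = None

    def __post_init__(self):
        for s, d in self.delta_star.items():
            if (d <= 0).any():
                raise ValueError(f"non-positive scale estimate for site {s}")


def _design(covariates: pd.DataFrame | np.ndarray | None, n_rows: int,
            means: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Centered covariate design matrix; missing entries (NaN) map to the
    training mean, i.e. they contribute no covariate adjustment."""
    if covariates is None:
        return np.zeros((n_rows, 0)), np.zeros(0)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if means is None:
        means = np.nanmean(arr, axis=0)
    arr = np.where(np.isnan(arr), means, arr)
    return arr - means, means


def fit_combat(features: np.ndarray, sites: np.ndarray,
               covariates: pd.DataFrame | np.ndarray | None = None,
               *, eb: bool = True, max_iter: int = 100,
               tol: float = 1e-4) -> HarmonizationModel:
    """Fit the location-scale harmonization model.

    Parameters
    ----------
    features : (n_subjects, p)
    sites : (n_subjects,) integer site index per subject
    covariates
        Biological covariates to preserve (e.g. diagnosis, age, sex).  They
        are centered; held-out subjects may later carry NaN entries, which
        are treated as the (training) prior mean.
    """
    x = np.asarray(features, dtype=float)
    sites = np.asarray(sites)
    if x.ndim != 2 or x.shape[0] != sites.shape[0]:
        raise ValueError("features and sites disagree on n_subjects")
    uniq, counts = np.unique(sites, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every site needs at least 2 subjects")

    n, p = x.shape
    design, cov_means = _design(covariates, n)

    if len(uniq) == 1:
        warnings.warn("single-site input: harmonization is the identity",
                      stacklevel=2)
        return HarmonizationModel(site_ids=uniq, grand_mean=np.zeros(p),
                                  beta=np.zeros((design.shape[1], p)),
                                  pooled_sd=np.ones(p), identity=True,
                                  covariate_means=cov_means)

    # Site indicator block, weighted so site effects average out over the
    # cohort; covariates enter centered.
    onehot = (sites[:, None] == uniq[None, :]).astype(float)
    frac = counts / n
    full = np.concatenate([onehot, design], axis=1) if design.size else onehot
    coef, *_ = np.linalg.lstsq(full, x, rcond=None)
    site_coef = coef[:len(uniq)]
    beta = coef[len(uniq):]
    grand_mean = frac @ site_coef

    fit = full @ coef
    resid = x - fit
    pooled_sd = np.sqrt((resid ** 2).mean(axis=0))
    pooled_sd[pooled_sd == 0] = 1.0

    stand = (x - grand_mean - design @ beta) / pooled_sd
    gamma_hat = {}
    delta2_hat = {}
    for s in uniq:
        zs = stand[sites == s]
        gamma_hat[s] = zs.mean(axis=0)
        delta2_hat[s] = zs.var(axis=0, ddof=1)

    gamma_star, delta_star = {}, {}
    if eb:
        for s in uniq:
            g, d2 = _eb_site(gamma_hat[s], delta2_hat[s],
                             int(counts[uniq == s][0]), max_iter, tol)
            gamma_star[s] = g
            delta_star[s] = np.sqrt(d2)
    else:
        for s in uniq:
            gamma_star[s] = gamma_hat[s]
            delta_star[s] = np.sqrt(np.clip(delta2_hat[s], 1e-12, None))

    return HarmonizationModel(site_ids=uniq, grand_mean=grand_mean, beta=beta,
                              pooled_sd=pooled_sd, gamma_star=gamma_star,
                              delta_star=delta_star, covariate_means=cov_means)


def _eb_site(g_hat: np.ndarray, d2_hat: np.ndarray, n_site: int,
             max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Parametric empirical-Bayes shrinkage for one site.

    Normal prior on locations and inverse-gamma prior on variances, both
    moment-matched across features, solved by the usual fixed-point
    iteration of the conditional posterior means.
    """
    g_bar = g_hat.mean()
    t2 = g_hat.var()
    d2 = np.clip(d2_hat, 1e-12, None)
    # Moment-matched inverse-gamma hyperparameters.
    v = d2.mean()
    s2 = d2.var()
    a_prior = (2 * s2 + v ** 2) / s2 if s2 > 0 else 100.0
    b_prior = (v * s2 + v ** 3) / s2 if s2 > 0 else v * 99.0

    g_star = g_hat.copy()
    d2_star = d2.copy()
    if t2 == 0:
        t2 = 1e-12
    for _ in range(max_iter):
        g_new = (n_site * t2 * g_hat + d2_star * g_bar) / (n_site * t2 + d2_star)
        sse = d2 * (n_site - 1) + n_site * (g_hat - g_new) ** 2
        d2_new = (0.5 * sse + b_prior) / (n_site / 2.0 + a_prior - 1.0)
        d2_new = np.clip(d2_new, 1e-12, None)
        change = max(np.abs(g_new - g_star).max(), np.abs(d2_new - d2_star).max())
        g_star, d2_star = g_new, d2_new
        if change < tol:
            break
    return g_star, d2_star


def apply_combat(model: HarmonizationModel, features: np.ndarray,
                 sites: np.ndarray,
                 covariates: pd.DataFrame | np.ndarray | None = None,
                 *, unseen: str = "identity") -> np.ndarray:
    """Harmonize ``features`` with a fitted model.

    Output: ``((x - site location - covariate fit) / site scale) * pooled sd
    + grand mean + covariate fit``.  Subjects from sites unseen at fit time
    pass through unchanged (``unseen='identity'``, with a warning).
    """
    x = np.asarray(features, dtype=float)
    sites = np.asarray(sites)
    if x.shape[0] != sites.shape[0]:
        raise ValueError("features and sites disagree on n_subjects")
    if model.identity:
        return x.copy()
    if x.shape[1] != model.grand_mean.shape[0]:
        raise ValueError("feature dimension differs from the fitted model")

    design, _ = _design(covariates, x.shape[0], model.covariate_means)
    cov_fit = design @ model.beta
    stand = (x - model.grand_mean - cov_fit) / model.pooled_sd
    out = np.empty_like(x)
    for s in np.unique(sites):
        mask = sites == s
        if s not in model.gamma_star:
            if unseen != "identity":
                raise ValueError(f"site {s} was not seen at fit time")
            warnings.warn(f"site {s} unseen at fit time; passing through",
                          stacklevel=2)
            out[mask] = x[mask]
            continue
        adj = (stand[mask] - model.gamma_star[s]) / model.delta_star[s]
        out[mask] = adj * model.pooled_sd + model.grand_mean + cov_fit[mask]
    return out
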