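"""Univariate GBLUP fitted independently per experiment, plus the kinship
regression for new genotypes and the constant-averaging strategies used for
new environments.

The model for one experiment is y = 1μ + g + e with g ~ N(0, σ²_g K) and
e ~ N(0, σ²_e I).  REML over the variance ratio φ = σ²_g/σ²_e is a smooth
one-dimensional problem after one eigendecomposition, solved by
golden-section search on log φ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .predict import PredictionResult, kinship_regression

LOG_RATIO_BOUNDS = (-10.0, 10.0)


@dataclass
class GblupFit:
    mu: float
    g_hat: np.ndarray
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float               # REML log-likelihood at the optimum
    ids: list[str] | None = None


def _reml_profile(theta: np.ndarray, y_rot: np.ndarray, n_resid: int):
    """Profiled REML log-likelihood pieces as a function of log variance ratio.

    ``theta`` are eigenvalues of S K S restricted to the residual space of X
    (zeros removed), ``y_rot`` the correspondingly rotated data.
    """
    def neg_ll(log_phi: float) -> float:
        phi = np.exp(log_phi)
        v = phi * theta + 1.0
        sigma2_e = float(np.sum(y_rot ** 2 / v) / n_resid)
        ll = -0.5 * (np.sum(np.log(v)) + n_resid * np.log(sigma2_e) + n_resid)
        return -ll
    return neg_ll


def reml_loglik(y: np.ndarray, kinship: np.ndarray, log_phi: float) -> float:
    """REML log-likelihood (up to an additive constant) at a given log
    variance ratio — independent evaluation used for grid-dominance checks."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    S = np.eye(n) - X @ X.T / n
    theta, U = np.linalg.eigh(S @ kinship @ S)
    keep = np.argsort(theta)[1:]                  # drop the projected-out dim
    theta = np.clip(theta[keep], 0.0, None)
    y_rot = U[:, keep].T @ y
    return -_reml_profile(theta, y_rot, n - 1)(log_phi)


def fit_gblup(y, kinship, ids=None) -> GblupFit:
    """REML GBLUP for one experiment.

    ``kinship`` is the K submatrix over the observed genotypes, aligned with
    ``y``.  Returns BLUPs from the mixed-model equations at the REML optimum.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    K = np.asarray(kinship, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship must align with y")
    if np.allclose(y, y[0]):
        warnings.warn("all phenotypes equal; returning zero genetic variance",
                      stacklevel=2)
        return GblupFit(float(y[0]), np.zeros(n), 0.0, 0.0, 0.0,
                        np.nan, list(ids) if ids is not None else None)

    X = np.ones((n, 1))
    S = np.eye(n) - X @ X.T / n
    theta, U = np.linalg.eigh(S @ K @ S)
    keep = np.argsort(theta)[1:]
    theta_k = np.clip(theta[keep], 0.0, None)
    y_rot = U[:, keep].T @ y
    neg_ll = _reml_profile(theta_k, y_rot, n - 1)
    res = minimize_scalar(neg_ll, bounds=LOG_RATIO_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    phi = float(np.exp(res.x))
    v = phi * theta_k + 1.0
    sigma2_e = float(np.sum(y_rot ** 2 / v) / (n - 1))
    sigma2_g = phi * sigma2_e

    # BLUPs at the optimum: V = σ²_g K + σ²_e I, GLS intercept, ĝ = σ²_g K V⁻¹ r
    s_all, Q = np.linalg.eigh((K + K.T) / 2.0)
    vfull = sigma2_g * np.clip(s_all, 0.0, None) + sigma2_e
    Vi_y = Q @ ((Q.T @ y) / vfull)
    Vi_1 = Q @ ((Q.T @ np.ones(n)) / vfull)
    mu = float(np.ones(n) @ Vi_y / (np.ones(n) @ Vi_1))
    r = y - mu
    g_hat = sigma2_g * (K @ (Q @ ((Q.T @ r) / vfull)))
    h2 = sigma2_g / (sigma2_g + sigma2_e) if sigma2_g + sigma2_e > 0 else 0.0
    return GblupFit(mu, g_hat, sigma2_g, sigma2_e, float(h2), float(-res.fun),
                    list(ids) if ids is not None else None)


def gblup_predict_new_geno(fit: GblupFit, k_no: np.ndarray,
                           k_oo: np.ndarray | None = None,
                           include_mu: bool = False) -> np.ndarray:
    """Genetic values of new genotypes: ``K_no K_oo⁻¹ ĝ``.

    ``k_no`` has one row per new genotype, columns aligned with the training
    genotypes of the fit.  When ``k_oo`` is None the training block is
    reconstructed as unnecessary — the caller must pass it; the solve uses an
    eigenvalue floor and warns when K_oo is near singular.  ``include_mu``
    adds the intercept for phenotype-scale output.
    """
    k_no = np.atleast_2d(np.asarray(k_no, dtype=float))
    if k_oo is None:
        raise TypeError("k_oo (training kinship block) is required")
    M = kinship_regression(k_no, k_oo)
    out = M @ fit.g_hat
    if include_mu:
        out = out + fit.mu
    return out


def gblup_new_env_strategy(per_experiment: dict[str, np.ndarray],
                           target_cols, grouping: dict[str, str] | None = None,
                           target_clusters=None, row_ids=None,
                           label: str = "GBLUP") -> PredictionResult:
    """Constant prediction for new environments from per-experiment GBLUPs.

    ``per_experiment`` maps training experiment id → per-genotype prediction
    vector (all aligned).  Under ``grouping=None`` (strategy ALL) every
    training experiment contributes; otherwise only experiments whose cluster
    matches the target's, with an ALL fallback (and warning) for empty
    clusters.
    """
    cols = list(per_experiment)
    if not cols:
        raise ValueError("no per-experiment fits supplied")
    mat = np.column_stack([per_experiment[c] for c in cols])
    if target_clusters is None:
        target_clusters = [None] * len(target_cols)
    out = np.empty((mat.shape[0], len(target_cols)))
    for j, cluster in enumerate(target_clusters):
        if cluster is None or grouping is None:
            members = list(range(len(cols)))
        else:
            members = [i for i, c in enumerate(cols) if grouping.get(c) == cluster]
            if not members:
                warnings.warn(f"cluster {cluster!r} empty; using ALL average",
                              stacklevel=2)
                members = list(range(len(cols)))
        out[:, j] = mat[:, members].mean(axis=1)
    ids = list(row_ids) if row_ids is not None else \
        [f"g{i}" for i in range(mat.shape[0])]
    return PredictionResult(out, np.zeros_like(out), "Gon", ids,
                            list(target_cols), label)
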