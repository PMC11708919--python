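"""Posterior prediction of genetic values for the four genotype/environment
target quadrants:

* Goo — old genotypes, old environments: per-draw ``FΛ + U_R``.
* Ano — new genotypes, old environments: per-draw
  ``(K_no K_oo⁻¹ U_F) Λ + K_no K_oo⁻¹ U_R`` (additive values only).
* Gon — old genotypes, new environments: per-draw ``F λ_nᵀ`` with the new
  environments' loading columns built from the EC regression coefficients,
  ``λ_n = Σ_l W_ln a_l``.  No residual-trait term: a new environment has no
  residual trait.
* Ann — new genotypes, new environments: Gon with F replaced by
  ``K_no K_oo⁻¹ U_F``, composed per draw so the draw-level covariance between
  U_F and the regression coefficients is preserved.

When a model's predictor side is the constant sentinel, new-environment
predictions instead average per-experiment predictions across the training
experiments of the target's cluster (:func:`constant_prediction`).

All summaries are posterior means over retained draws with draw-dispersion
standard deviations; every map here is linear per draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import INTERCEPT
from .modelspec import ModelSpec
from .sampler import PosteriorSamples

EIG_FLOOR = 1e-10


@dataclass
class PredictionResult:
    estimates: np.ndarray       # genotypes × experiments posterior means
    sd: np.ndarray              # same-shape posterior standard deviations
    target_kind: str            # Goo | Ano | Gon | Ann
    row_ids: list[str]
    col_ids: list[str]
    provenance: str = ""

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.estimates, index=self.row_ids,
                            columns=self.col_ids)

    def to_long(self):
        import pandas as pd
        df = self.to_frame().stack().rename("estimate").reset_index()
        df.columns = ["genotype", "experiment", "estimate"]
        df["sd"] = self.sd.ravel()
        df["target_kind"] = self.target_kind
        df["model_label"] = self.provenance
        return df


def _summarize(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return draws.mean(axis=0), draws.std(axis=0, ddof=0)


def predict_old_geno_old_env(post: PosteriorSamples,
                             provenance: str = "") -> PredictionResult:
    """Goo: total genetic values of the training genotypes in the training
    experiments."""
    if post.n_draws == 0:
        raise ValueError("empty posterior")
    draws = np.einsum("dnk,dkt->dnt", post.F, post.Lambda) + post.U_R
    est, sd = _summarize(draws)
    return PredictionResult(est, sd, "Goo", post.row_ids, post.col_ids, provenance)


def kinship_regression(k_no: np.ndarray, k_oo: np.ndarray) -> np.ndarray:
    """The matrix ``K_no K_oo⁻¹`` via eigendecomposition with a floor on the
    eigenvalues (singular K_oo triggers a warning, not a failure)."""
    s, Q = np.linalg.eigh((k_oo + k_oo.T) / 2.0)
    if s[0] < EIG_FLOOR:
        warnings.warn(f"K_oo near singular (min eigenvalue {s[0]:.2e}); "
                      f"flooring at {EIG_FLOOR}", stacklevel=2)
    s = np.maximum(s, EIG_FLOOR)
    return (k_no @ Q) / s[None, :] @ Q.T


def predict_new_geno(post: PosteriorSamples, k_no: np.ndarray,
                     k_oo: np.ndarray, new_ids=None,
                     provenance: str = "") -> PredictionResult:
    """Ano: additive genetic values of new genotypes in the training
    experiments, via kinship regression of U_F and U_R."""
    M = kinship_regression(np.atleast_2d(k_no), k_oo)
    draws = (np.einsum("dnk,dkt->dnt", np.einsum("mn,dnk->dmk", M, post.U_F),
                       post.Lambda)
             + np.einsum("mn,dnt->dmt", M, post.U_R))
    est, sd = _summarize(draws)
    ids = list(new_ids) if new_ids is not None else [f"new{i}" for i in range(M.shape[0])]
    return PredictionResult(est, sd, "Ano", ids, post.col_ids, provenance)


def new_env_loadings(post: PosteriorSamples, ec_new: dict[str, np.ndarray],
                     spec: ModelSpec) -> np.ndarray:
    """Per-draw loading columns λ_n for new environments (D × k × m).

    ``ec_new`` maps predictor term names to their design rows (m × p_l),
    already produced by ``ECTerm.rows_for`` (so categorical levels unseen in
    training are all-zero rows).  The intercept contributes always; prior
    terms not on the predictor side contribute zero.
    """
    use = [INTERCEPT] + [nm for nm in post.term_slices
                         if nm != INTERCEPT and nm in set(spec.predictor_terms)]
    m = None
    for nm in use:
        if nm in ec_new:
            m = np.atleast_2d(ec_new[nm]).shape[0]
            break
    if m is None:
        raise ValueError("ec_new provides no rows for any predictor term")
    D, k = post.A.shape[0], post.F.shape[2]
    lam = np.zeros((D, k, m))
    for nm in use:
        sl = post.term_slices[nm]
        if nm == INTERCEPT:
            rows = np.ones((m, 1))
        elif nm in ec_new:
            rows = np.atleast_2d(np.asarray(ec_new[nm], dtype=float))
        else:
            raise ValueError(f"ec_new missing rows for predictor term {nm!r}")
        # A block: D × p_l × k ; rows: m × p_l  →  D × k × m
        lam += np.einsum("mp,dpk->dkm", rows, post.A[:, sl, :])
    return lam


def predict_new_env(post: PosteriorSamples, ec_new: dict[str, np.ndarray],
                    spec: ModelSpec, k_no: np.ndarray | None = None,
                    k_oo: np.ndarray | None = None, new_env_ids=None,
                    new_geno_ids=None, provenance: str = "") -> PredictionResult:
    """Gon (or Ann when ``k_no`` is given): genetic values in environments
    never observed, from the EC-regression loading prediction."""
    lam = new_env_loadings(post, ec_new, spec)      # D × k × m
    if k_no is None:
        basis = post.F
        kind = "Gon"
        row_ids = post.row_ids
    else:
        M = kinship_regression(np.atleast_2d(k_no), k_oo)
        basis = np.einsum("mn,dnk->dmk", M, post.U_F)
        kind = "Ann"
        row_ids = list(new_geno_ids) if new_geno_ids is not None else \
            [f"new{i}" for i in range(M.shape[0])]
    draws = np.einsum("dnk,dkm->dnm", basis, lam)
    est, sd = _summarize(draws)
    m = lam.shape[2]
    col_ids = list(new_env_ids) if new_env_ids is not None else \
        [f"newenv{j}" for j in range(m)]
    return PredictionResult(est, sd, kind, row_ids, col_ids,
                            provenance or spec.label)


def constant_prediction(per_experiment: PredictionResult,
                        grouping: dict[str, str] | None = None,
                        target_cols=None,
                        target_clusters=None) -> PredictionResult:
    """Constant (experiment-average) prediction for new environments.

    ``grouping`` maps training experiment id → cluster label (None = one
    global cluster ALL).  Each target experiment receives, per genotype, the
    mean of estimates over the training experiments of its cluster; an empty
    cluster falls back to the all-experiment average with a warning.
    """
    est = per_experiment.estimates
    cols = per_experiment.col_ids
    overall = est.mean(axis=1)
    if target_cols is None:
        target_cols = ["ALL"]
        target_clusters = [None]
    if target_clusters is None:
        target_clusters = [None] * len(target_cols)
    out = np.empty((est.shape[0], len(target_cols)))
    sds = np.empty_like(out)
    for j, cluster in enumerate(target_clusters):
        if cluster is None or grouping is None:
            members = list(range(len(cols)))
        else:
            members = [i for i, c in enumerate(cols) if grouping.get(c) == cluster]
            if not members:
                warnings.warn(f"cluster {cluster!r} has no training experiments; "
                              "falling back to the all-experiment average",
                              stacklevel=2)
                members = list(range(len(cols)))
        out[:, j] = est[:, members].mean(axis=1)
        sds[:, j] = per_experiment.sd[:, members].mean(axis=1)
    return PredictionResult(out, sds, per_experiment.target_kind,
                            per_experiment.row_ids, list(target_cols),
                            per_experiment.provenance + "+constant")
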