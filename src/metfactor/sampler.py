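"""Gibbs sampler for the extended factor-analytic multivariate mixed model.

The model is a two-level hierarchy for an n × t trait matrix Y:

    level 1:  Y = X B + F Λ + U_R + E_R
    level 2:  f_k = u_Fk + e_Fk,   u_Fk ~ N(0, h²_Fk K),  e_Fk ~ N(0, (1−h²_Fk) I)
              (residual traits analogously, with free total variance σ²_Rj)

Each factor trait has total variance fixed at 1 (Λ absorbs scale); each
residual-trait column j partitions σ²_Rj into a kinship-structured additive
part and iid noise via a heritability h²_Rj.

The loading rows carry an environmental-covariate regression prior with
multiplicative-gamma shrinkage across factors:

    λ_k· = Σ_l W_l a_lk + ε_k
    a_lk ~ N(0, σ²_l / τ_k),  ε_kj ~ N(0, 1/(ψ_jk τ_k))
    ψ_jk ~ Ga(ν/2, ν/2),  τ_k = Π_{h≤k} δ_h,
    δ_1 ~ Ga(α1, β1),  δ_h ~ Ga(α2, β2) for h ≥ 2,  σ²_l ~ invGamma(a, b)

so higher-order factors are shrunk towards zero and, within a factor, the
loading row is pulled towards its EC regression — which is what permits
prediction in environments never observed.

Missing cells are handled by full data augmentation: they are redrawn from
the current conditional at every sweep, so all block updates see a complete
matrix.  Heritabilities are sampled on a discrete grid in the eigenbasis of
the (observed-genotype) kinship matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .data import INTERCEPT, ModelInputs, validate_inputs
from .modelspec import ModelSpec


class SamplerError(RuntimeError):
    pass


@dataclass
class SamplerConfig:
    """Tuning knobs for the Gibbs sampler.

    ``k_max`` is the working number of factors (the shrinkage prior turns the
    surplus off).  ``h2_grid_size`` is the number of equally spaced
    heritability grid points {0, 1/m, ..., (m-1)/m}.  The δ hyperparameters
    default to E[δ]>1 so prior precision increases with factor index.
    """

    k_max: int = 50
    n_iter: int = 5000
    burn_in: int = 2500
    thin: int = 5
    seed: int = 0
    h2_grid_size: int = 20
    nu: float = 3.0
    alpha1: float = 2.1
    beta1: float = 1.0
    alpha2: float = 3.1
    beta2: float = 1.0
    sigma_a: float = 3.0
    sigma_b: float = 1.0
    resid_a: float = 2.0
    resid_b: float = 1.0

    def __post_init__(self):
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.h2_grid_size < 2:
            raise ValueError("h2_grid_size must be >= 2")
        for nm in ("nu", "alpha1", "beta1", "alpha2", "beta2",
                   "sigma_a", "sigma_b", "resid_a", "resid_b"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class SamplerState:
    """All unknowns of one MCMC iteration. Shapes use n rows, t experiments,
    k factors, p fixed effects, P stacked EC coefficients."""

    B: np.ndarray           # p × t
    F: np.ndarray           # n × k
    U_F: np.ndarray         # n × k
    h2_F: np.ndarray        # k
    Lambda: np.ndarray      # k × t
    A: np.ndarray           # P × k (stacked over EC terms)
    sigma2_l: np.ndarray    # L (one shared variance per EC term)
    psi: np.ndarray         # k × t local precisions ψ_jk
    delta: np.ndarray       # k multiplicative-gamma increments
    tau: np.ndarray         # k cumulative precisions
    U_R: np.ndarray         # n × t
    h2_R: np.ndarray        # t
    sigma2_R: np.ndarray    # t total residual-trait variances
    Y: np.ndarray           # n × t current complete data (observed + imputed)

    @property
    def resid_var(self) -> np.ndarray:
        """Per-column iid noise variance σ²_eRj = σ²_Rj (1 − h²_Rj)."""
        return self.sigma2_R * (1.0 - self.h2_R)


@dataclass
class Precomputed:
    """Run-constant quantities: kinship eigenbasis and stacked EC design."""

    Q: np.ndarray           # n × n eigenvectors of K over observed genotypes
    s: np.ndarray           # eigenvalues (ascending)
    X: np.ndarray           # n × p fixed design
    XtX_inv: np.ndarray
    W: np.ndarray           # t × P stacked EC design (prior terms)
    term_slices: dict[str, slice]
    h2_grid: np.ndarray
    obs_mask: np.ndarray    # n × t


@dataclass
class PosteriorSamples:
    """Retained draws of the quantities the prediction equations need."""

    F: np.ndarray           # D × n × k
    U_F: np.ndarray
    Lambda: np.ndarray      # D × k × t
    A: np.ndarray           # D × P × k
    U_R: np.ndarray         # D × n × t
    B: np.ndarray           # D × p × t
    h2_F: np.ndarray        # D × k
    tau: np.ndarray         # D × k
    loglik: np.ndarray      # per-retained-draw observed-data log-likelihood
    config: SamplerConfig
    term_slices: dict[str, slice]
    row_ids: list[str]
    col_ids: list[str]

    @property
    def n_draws(self) -> int:
        return self.F.shape[0]

    def save(self, directory) -> None:
        """Persist as a directory of .npy arrays plus a JSON manifest."""
        import os
        os.makedirs(directory, exist_ok=True)
        for name in ("F", "U_F", "Lambda", "A", "U_R", "B", "h2_F", "tau",
                     "loglik"):
            np.save(os.path.join(directory, f"{name}.npy"), getattr(self, name))
        manifest = {
            "config": asdict(self.config),
            "term_slices": {k: [v.start, v.stop] for k, v in self.term_slices.items()},
            "row_ids": self.row_ids, "col_ids": self.col_ids,
            "n_draws": int(self.n_draws),
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        import os
        with open(os.path.join(directory, "manifest.json")) as fh:
            man = json.load(fh)
        arrays = {name: np.load(os.path.join(directory, f"{name}.npy"))
                  for name in ("F", "U_F", "Lambda", "A", "U_R", "B", "h2_F",
                               "tau", "loglik")}
        return cls(config=SamplerConfig(**man["config"]),
                   term_slices={k: slice(a, b) for k, (a, b)
                                in man["term_slices"].items()},
                   row_ids=man["row_ids"], col_ids=man["col_ids"], **arrays)


# ---------------------------------------------------------------------------
# setup

def _precompute(inputs: ModelInputs, config: SamplerConfig,
                spec: ModelSpec | None) -> Precomputed:
    tr = inputs.traits
    K_obs = inputs.kinship.matrix[np.ix_(inputs.genotype_incidence,
                                         inputs.genotype_incidence)]
    s, Q = np.linalg.eigh((K_obs + K_obs.T) / 2.0)
    if s[0] < -1e-8:
        raise SamplerError(f"kinship not PSD: smallest eigenvalue {s[0]:.3e}")
    s = np.clip(s, 0.0, None)
    X = inputs.fixed_design
    XtX_inv = np.linalg.inv(X.T @ X)
    names = None if spec is None else list(spec.prior_terms)
    W, slices = inputs.ec.stacked(names)
    m = config.h2_grid_size
    grid = np.arange(m) / m
    return Precomputed(Q, s, X, XtX_inv, W, slices, grid, tr.observed_mask.copy())


def initialize_state(inputs: ModelInputs, config: SamplerConfig,
                     spec: ModelSpec | None = None) -> SamplerState:
    """Deterministic-given-seed initialization.

    F and Λ come from a truncated SVD of the column-standardized,
    mean-imputed trait matrix; heritabilities start at (roughly) 0.5 on the
    grid; δ is drawn from its prior; unobserved cells start at column means.
    """
    tr = inputs.traits
    n, t = tr.n, tr.t
    k = config.k_max
    if k > min(n, t):
        raise SamplerError(f"k_max={k} exceeds min(n, t)={min(n, t)}")
    rng = np.random.default_rng(config.seed)
    pre = _precompute(inputs, config, spec)

    counts = tr.observed_mask.sum(axis=0)
    sums = np.where(tr.observed_mask, tr.values, 0.0).sum(axis=0)
    col_mean = np.divide(sums, counts, out=np.zeros(t), where=counts > 0)
    Y = np.where(tr.observed_mask, tr.values, col_mean[None, :])

    col_sd = Y.std(axis=0, ddof=0)
    col_sd = np.where(col_sd > 0, col_sd, 1.0)
    Ys = (Y - Y.mean(axis=0)) / col_sd
    U_svd, sv, Vt = np.linalg.svd(Ys, full_matrices=False)
    r = min(k, len(sv))
    F = np.zeros((n, k))
    Lam = np.zeros((k, t))
    F[:, :r] = U_svd[:, :r] * np.sqrt(n)
    Lam[:r] = (sv[:r, None] * Vt[:r]) / np.sqrt(n) * col_sd[None, :]

    p = pre.X.shape[1]
    B = pre.XtX_inv @ pre.X.T @ Y
    resid = Y - pre.X @ B - F @ Lam
    sigma2_R = np.maximum(resid.var(axis=0, ddof=0), 1e-6)

    P = pre.W.shape[1]
    delta = np.empty(k)
    delta[0] = rng.gamma(config.alpha1, 1.0 / config.beta1)
    if k > 1:
        delta[1:] = rng.gamma(config.alpha2, 1.0 / config.beta2, size=k - 1)
    grid_half = pre.h2_grid[np.argmin(np.abs(pre.h2_grid - 0.5))]
    return SamplerState(
        B=B, F=F, U_F=np.zeros((n, k)), h2_F=np.full(k, grid_half),
        Lambda=Lam, A=np.zeros((P, k)),
        sigma2_l=np.ones(len(pre.term_slices)),
        psi=np.ones((k, t)), delta=delta, tau=np.cumprod(delta),
        U_R=np.zeros((n, t)), h2_R=np.full(t, grid_half), sigma2_R=sigma2_R,
        Y=Y,
    )


# ---------------------------------------------------------------------------
# Gibbs blocks

def _sample_h2_column(y_tilde: np.ndarray, s: np.ndarray, grid: np.ndarray,
                      sigma2: float, rng) -> float:
    """Draw h² from its discrete-grid conditional for one column.

    ``y_tilde`` is the column rotated into the kinship eigenbasis and
    ``sigma2`` its (fixed) total variance; the genetic effect is
    marginalized, so marginally ỹ_i ~ N(0, σ²(h² s_i + 1 − h²)).
    """
    v = grid[:, None] * s[None, :] + (1.0 - grid[:, None])  # m × n
    logp = -0.5 * np.sum(np.log(v), axis=1) - 0.5 * (y_tilde ** 2 / sigma2) @ (1.0 / v.T)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    return float(rng.choice(grid, p=prob))


def _draw_u_column(y_tilde: np.ndarray, s: np.ndarray, h2: float,
                   sigma2: float, rng) -> np.ndarray:
    """Genetic effect (eigenbasis) given h², σ² and the rotated column."""
    g, e = h2 * s, (1.0 - h2)
    v = g + e
    mean = np.where(v > 0, g / v, 0.0) * y_tilde
    var = np.where(v > 0, sigma2 * g * e / v, 0.0)
    return mean + np.sqrt(var) * rng.standard_normal(len(s))


def sample_genetic_effects(state: SamplerState, inputs: ModelInputs,
                           pre: Precomputed, config: SamplerConfig, rng) -> None:
    """Heritabilities, genetic effects, fixed effects and residual-trait
    variances, all in the kinship eigenbasis.  Factor traits have total
    variance fixed at 1; residual traits carry conjugate invGamma σ²_Rj."""
    n, t = state.Y.shape
    Q, s, X = pre.Q, pre.s, pre.X
    grid = pre.h2_grid
    m = len(grid)
    v = grid[:, None] * s[None, :] + (1.0 - grid[:, None])   # m × n
    logdet = np.sum(np.log(v), axis=1)
    inv_v = 1.0 / v

    # --- factor traits (total variance fixed at 1)
    k_dim = state.F.shape[1]
    Ft = Q.T @ state.F                                       # n × k
    quad_F = inv_v @ Ft ** 2                                 # m × k
    logp = -0.5 * logdet[:, None] - 0.5 * quad_F
    logp -= logp.max(axis=0)
    prob = np.exp(logp)
    prob /= prob.sum(axis=0)
    Ut = np.empty_like(Ft)
    for k in range(k_dim):
        gi = rng.choice(m, p=prob[:, k])
        h2 = float(grid[gi])
        state.h2_F[k] = h2
        g = h2 * s
        vv = g + (1.0 - h2)
        mean = g / vv * Ft[:, k]
        var = g * (1.0 - h2) / vv
        Ut[:, k] = mean + np.sqrt(var) * rng.standard_normal(n)
    state.U_F[:] = Q @ Ut

    # --- residual traits
    R0 = state.Y - state.F @ state.Lambda   # still contains XB + U_R + E
    p = X.shape[1]
    d = state.resid_var
    # B columns (flat prior) given U_R; cov = σ²_eRj (XᵀX)⁻¹, independent per j
    b_mean = pre.XtX_inv @ (X.T @ (R0 - state.U_R))
    Lx = np.linalg.cholesky(pre.XtX_inv)
    state.B[:] = b_mean + (Lx @ rng.standard_normal((p, t))) * np.sqrt(d)[None, :]
    # (h², σ²_R) jointly with u marginalized (invGamma prior on σ²_R), then u
    Yt = Q.T @ (R0 - X @ state.B)                            # n × t
    a_post = config.resid_a + n / 2.0
    quad = inv_v @ Yt ** 2                                   # m × t
    logp = -0.5 * logdet[:, None] - a_post * np.log(config.resid_b + 0.5 * quad)
    logp -= logp.max(axis=0)
    prob = np.exp(logp)
    prob /= prob.sum(axis=0)
    Ut = np.empty_like(Yt)
    for j in range(t):
        gi = rng.choice(m, p=prob[:, j])
        h2 = float(grid[gi])
        sigma2 = 1.0 / rng.gamma(a_post, 1.0 / (config.resid_b + 0.5 * quad[gi, j]))
        state.h2_R[j] = h2
        state.sigma2_R[j] = sigma2
        g = h2 * s
        vv = g + (1.0 - h2)
        mean = g / vv * Yt[:, j]
        var = sigma2 * g * (1.0 - h2) / vv
        Ut[:, j] = mean + np.sqrt(var) * rng.standard_normal(n)
    state.U_R[:] = Q @ Ut


def sample_factor_scores(state: SamplerState, inputs: ModelInputs,
                         pre: Precomputed, config: SamplerConfig, rng) -> None:
    """Rows of F from their conditional normals.

    With complete (augmented) data every row shares the same k×k precision
    P = diag(1/(1−h²_F)) + Λ D⁻¹ Λᵀ, so one Cholesky serves all rows.
    """
    n, k = state.F.shape
    d = state.resid_var
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        bad = int(np.argmin(d))
        raise SamplerError(f"non-finite residual precision at experiment {bad}")
    prior_prec = 1.0 / (1.0 - state.h2_F)
    LamD = state.Lambda / d[None, :]
    P = np.diag(prior_prec) + LamD @ state.Lambda.T
    if np.any(~np.isfinite(P)):
        raise SamplerError("non-finite factor-score precision")
    R = state.Y - pre.X @ state.B - state.U_R
    M = state.U_F * prior_prec[None, :] + R @ LamD.T
    c, low = cho_factor(P, lower=True)
    mean = cho_solve((c, low), M.T).T
    z = rng.standard_normal((n, k))
    # draw: mean + L^{-T} z with P = L Lᵀ
    noise = solve_triangular(c, z.T, trans="T", lower=True).T
    state.F[:] = mean + noise


def sample_loadings(state: SamplerState, inputs: ModelInputs,
                    pre: Precomputed, config: SamplerConfig, rng) -> None:
    """Columns of Λ from conjugate normals given F, the adjusted data and the
    EC-regression prior mean with ψ⊙τ precisions."""
    k, t = state.Lambda.shape
    d = state.resid_var
    if np.any(d <= 0):
        raise SamplerError(f"zero residual variance at experiment {int(np.argmin(d))}")
    R = state.Y - pre.X @ state.B - state.U_R
    FtF = state.F.T @ state.F
    FtR = state.F.T @ R
    prior_mean = (pre.W @ state.A).T        # k × t
    for j in range(t):
        prec_prior = state.psi[:, j] * state.tau
        P = FtF / d[j] + np.diag(prec_prior)
        rhs = FtR[:, j] / d[j] + prec_prior * prior_mean[:, j]
        c, low = cho_factor(P, lower=True)
        mean = cho_solve((c, low), rhs)
        z = rng.standard_normal(k)
        state.Lambda[:, j] = mean + solve_triangular(c, z, trans="T", lower=True)


def _delta_update(delta: np.ndarray, c: np.ndarray, m_per_factor: int,
                  config: SamplerConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative-gamma increments given per-factor shrinkage loads c_k.

    ``c_k`` is Σ_j ψ_jk ε²_kj + Σ σ⁻²-scaled a² for factor k; each Gaussian
    element contributes τ_k^{1/2} to the likelihood, m_per_factor elements per
    factor. With no data (zero-sized c) the conditional is the prior.
    """
    K = len(delta)
    for h in range(K):
        tau = np.cumprod(delta)
        if h == 0:
            shape, rate = config.alpha1, config.beta1
        else:
            shape, rate = config.alpha2, config.beta2
        if K > h and len(c):
            shape = shape + 0.5 * m_per_factor * (K - h)
            tau_wo = tau[h:] / delta[h]
            rate = rate + 0.5 * np.sum(tau_wo * c[h:])
        delta[h] = rng.gamma(shape, 1.0 / rate)
    return delta, np.cumprod(delta)


def sample_loading_regression(state: SamplerState, inputs: ModelInputs,
                              pre: Precomputed, config: SamplerConfig, rng) -> None:
    """EC regression coefficients, per-term variances σ²_l, local precisions
    ψ and the multiplicative-gamma increments δ (hence τ)."""
    k, t = state.Lambda.shape
    W = pre.W
    P_dim = W.shape[1]
    coef_var = np.empty(P_dim)
    for li, (name, sl) in enumerate(pre.term_slices.items()):
        coef_var[sl] = state.sigma2_l[li]

    for kk in range(k):
        psi_k = state.psi[kk]
        WtPsi = W.T * psi_k[None, :]
        Pmat = WtPsi @ W + np.diag(1.0 / coef_var)
        rhs = WtPsi @ state.Lambda[kk]
        try:
            c, low = cho_factor(Pmat, lower=True)
        except np.linalg.LinAlgError:
            Pmat = Pmat + 1e-10 * np.eye(P_dim)
            try:
                c, low = cho_factor(Pmat, lower=True)
            except np.linalg.LinAlgError as e:  # pragma: no cover
                raise SamplerError(f"singular coefficient precision, factor {kk}") from e
        mean = cho_solve((c, low), rhs)
        z = rng.standard_normal(P_dim)
        state.A[:, kk] = mean + solve_triangular(c, z, trans="T", lower=True) \
            / np.sqrt(state.tau[kk])

    # per-term shared variances
    for li, (name, sl) in enumerate(pre.term_slices.items()):
        a_blk = state.A[sl, :]           # p_l × k
        ssq = np.sum(state.tau[None, :] * a_blk ** 2)
        shape = config.sigma_a + a_blk.size / 2.0
        rate = config.sigma_b + 0.5 * ssq
        state.sigma2_l[li] = 1.0 / rng.gamma(shape, 1.0 / rate)
        coef_var[sl] = state.sigma2_l[li]

    eps = state.Lambda - (W @ state.A).T     # k × t
    shape = (config.nu + 1.0) / 2.0
    rate = (config.nu + state.tau[:, None] * eps ** 2) / 2.0
    state.psi = rng.gamma(shape, 1.0 / rate)

    c_load = np.sum(state.psi * eps ** 2, axis=1) \
        + np.sum((state.A ** 2) / coef_var[:, None], axis=0)
    m_per_factor = t + P_dim
    state.delta, state.tau = _delta_update(state.delta, c_load, m_per_factor,
                                           config, rng)


def impute_missing_values(state: SamplerState, inputs: ModelInputs,
                          pre: Precomputed, config: SamplerConfig, rng) -> None:
    """Unobserved cells redrawn from N(linear predictor, σ²_eRj); observed
    cells are never touched."""
    miss = ~pre.obs_mask
    if not miss.any():
        return
    mean = pre.X @ state.B + state.F @ state.Lambda + state.U_R
    sd = np.sqrt(state.resid_var)[None, :]
    draw = mean + sd * rng.standard_normal(mean.shape)
    state.Y[miss] = draw[miss]


def observed_loglik(state: SamplerState, inputs: ModelInputs,
                    pre: Precomputed) -> float:
    """Observed-data log-likelihood at the current parameter values."""
    mean = pre.X @ state.B + state.F @ state.Lambda + state.U_R
    d = state.resid_var[None, :]
    obs = pre.obs_mask
    resid = inputs.traits.values - mean
    ll = -0.5 * (np.log(2 * np.pi * d) + resid ** 2 / d)
    return float(ll[obs].sum())


_BLOCKS = (
    ("genetic_effects", sample_genetic_effects),
    ("factor_scores", sample_factor_scores),
    ("loadings", sample_loadings),
    ("loading_regression", sample_loading_regression),
    ("imputation", impute_missing_values),
)


def run_chain(inputs: ModelInputs, config: SamplerConfig,
              spec: ModelSpec | None = None, progress: bool = False,
              log_every: int = 100) -> PosteriorSamples:
    """Run the Gibbs sampler and return post-burn-in thinned draws.

    ``spec`` restricts the EC terms entering the loading prior (its prior
    side); ``None`` uses every term in ``inputs.ec``.  Deterministic given
    ``config.seed``.
    """
    report = validate_inputs(inputs)
    if not report.ok:
        raise SamplerError(f"invalid inputs:\n{report}")
    pre = _precompute(inputs, config, spec)
    state = initialize_state(inputs, config, spec)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))

    D = config.n_retained
    n, t = state.Y.shape
    k, p, P = config.k_max, pre.X.shape[1], pre.W.shape[1]
    out = PosteriorSamples(
        F=np.empty((D, n, k)), U_F=np.empty((D, n, k)),
        Lambda=np.empty((D, k, t)), A=np.empty((D, P, k)),
        U_R=np.empty((D, n, t)), B=np.empty((D, p, t)),
        h2_F=np.empty((D, k)), tau=np.empty((D, k)), loglik=np.empty(D),
        config=config, term_slices=pre.term_slices,
        row_ids=list(inputs.traits.row_ids), col_ids=list(inputs.traits.col_ids))

    d_idx = 0
    for it in range(config.n_iter):
        for name, block in _BLOCKS:
            try:
                block(state, inputs, pre, config, rng)
            except SamplerError as e:
                raise SamplerError(f"iteration {it}, block {name}: {e}") from e
        if progress and (it + 1) % log_every == 0:
            print(f"iter {it + 1}/{config.n_iter} "
                  f"loglik={observed_loglik(state, inputs, pre):.2f}")
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                and d_idx < D:
            out.F[d_idx] = state.F
            out.U_F[d_idx] = state.U_F
            out.Lambda[d_idx] = state.Lambda
            out.A[d_idx] = state.A
            out.U_R[d_idx] = state.U_R
            out.B[d_idx] = state.B
            out.h2_F[d_idx] = state.h2_F
            out.tau[d_idx] = state.tau
            out.loglik[d_idx] = observed_loglik(state, inputs, pre)
            d_idx += 1
    return out
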