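"""Simulation generator for factor-structured multi-environment trials.

Emulates a MET in which genetic values across environments are driven by
latent factors: one constant factor (positive covariance everywhere), one
factor tied to a linear environmental gradient that is (partially) predictable
from environmental covariates, and additional factors unpredictable from any
EC.  Phenotypes are genetic values plus kinship-structured residual-trait
effects and noise, with per-column heritability ``h2`` and an overall factor
share of phenotypic variance calibrated by a single global residual rescaling.

Default sizes are n=500 lines × 500 environments (400 training, 100 test)
with 10 latent factors; the kinship matrix is ``K = ZZᵀ/100 + 0.5·I`` with a
random 500×50 ``Z``, giving 50 large and 450 small eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import (ECDesignSet, ECTerm, Kinship, ModelInputs, TraitMatrix,
                   quantitative_term)

EC_MODES = ("categorical", "univariate", "multivariate")


@dataclass
class SimConfig:
    n_lines: int = 500
    t_train: int = 400
    t_test: int = 100
    k_true: int = 10
    z_cols: int = 50
    h2: float = 0.8
    factor_share: float = 0.8
    main_effect_prop: float = 0.25
    unpredictable_prop: float = 0.25
    missing_prop: float = 0.0
    ec_mode: str = "categorical"
    n_groups: int = 10
    heldout_prop: float = 0.2  # lines treated as "new genotypes" by the runner
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.ec_mode not in EC_MODES:
            raise ValueError(f"ec_mode must be one of {EC_MODES}")
        for name in ("h2", "factor_share", "main_effect_prop",
                     "unpredictable_prop", "missing_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.main_effect_prop + self.unpredictable_prop > 1.0:
            raise ValueError("main_effect_prop + unpredictable_prop must be <= 1")

    @property
    def t_total(self) -> int:
        return self.t_train + self.t_test


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    Lambda: np.ndarray          # k_true × t
    F: np.ndarray               # n × k_true (genetic + nongenetic factor values)
    U_F: np.ndarray             # n × k_true genetic components of factors
    U_R: np.ndarray             # n × t residual-trait genetic effects (scaled)
    E_resid: np.ndarray         # n × t nongenetic residual (scaled)
    Y_full: np.ndarray          # n × t phenotypes before masking
    gradient: np.ndarray        # t, environmental gradient (row 2 of Lambda basis)
    groups: np.ndarray | None   # t, categorical mode group labels
    W: np.ndarray | None        # t × 10, multivariate mode EC matrix
    total_genetic: np.ndarray = field(init=False)
    additive_genetic: np.ndarray = field(init=False)

    def __post_init__(self):
        self.total_genetic = self.F @ self.Lambda + self.U_R
        self.additive_genetic = self.U_F @ self.Lambda + self.U_R

    def column_h2(self) -> tuple[np.ndarray, np.ndarray]:
        """Realized var(genetic)/var(total) for each column of F and of E."""
        h2_F = (self.U_F.var(axis=0, ddof=1)
                / self.F.var(axis=0, ddof=1))
        E_total = self.U_R + self.E_resid
        h2_E = (self.U_R.var(axis=0, ddof=1)
                / E_total.var(axis=0, ddof=1))
        return h2_F, h2_E

    def factor_variance_share(self) -> np.ndarray:
        """Per environment, var(FΛ column) / var(Y column)."""
        G = self.F @ self.Lambda
        return G.var(axis=0, ddof=1) / self.Y_full.var(axis=0, ddof=1)


def simulate_kinship(n: int, z_cols: int, rng) -> Kinship:
    """``K = ZZᵀ/100 + 0.5·I`` with iid standard-normal ``Z`` (n × z_cols)."""
    if not n > z_cols >= 1:
        raise ValueError("need n > z_cols >= 1")
    rng = np.random.default_rng(rng)
    Z = rng.standard_normal((n, z_cols))
    K = Z @ Z.T / 100.0 + 0.5 * np.eye(n)
    return Kinship(K, [f"L{i:04d}" for i in range(n)])


def simulate_environment_structure(mode: str, t_train: int, t_test: int, rng,
                                   n_groups: int = 10):
    """Environmental gradient plus the EC design exposed to the model.

    categorical — training environments fall in ``n_groups`` groups; half the
    test environments come from group 1, half from an unseen extra group;
    only group identities (one-hot over training groups) are exposed.
    univariate — per-environment standard-normal values, exposed directly.
    multivariate — a t×10 standard-normal matrix ``W`` is exposed; the
    gradient ~ MVN(0, WWᵀ/20 + 0.5·I) so ~50% of its variance is explainable
    from ``W``.

    Returns ``(gradient, ECDesignSet, groups_or_None, W_or_None)``.
    """
    if mode not in EC_MODES:
        raise ValueError(f"unknown ec_mode {mode!r}")
    rng = np.random.default_rng(rng)
    t = t_train + t_test
    if mode == "categorical":
        half = t_test // 2
        if t_test % 2:
            import warnings
            warnings.warn("t_test odd; test environments split as evenly as possible")
        grp_train = rng.permutation(np.arange(t_train) % n_groups + 1)
        groups = np.concatenate([grp_train,
                                 np.ones(half, dtype=int),
                                 np.full(t_test - half, n_groups + 1, dtype=int)])
        values = rng.standard_normal(n_groups + 1)  # one value per group
        gradient = values[groups - 1]
        levels = [f"g{g:02d}" for g in range(1, n_groups + 1)]  # training groups only
        design = np.zeros((t, n_groups))
        for j, g in enumerate(groups):
            if g <= n_groups:
                design[j, g - 1] = 1.0
        term = ECTerm("G", design, "categorical", levels=levels)
        ec = ECDesignSet.build(t, [term])
        return gradient, ec, groups, None
    if mode == "univariate":
        gradient = rng.standard_normal(t)
        ec = ECDesignSet.build(t, [quantitative_term("E", gradient)])
        return gradient, ec, None, None
    # multivariate
    W = rng.standard_normal((t, 10))
    coef = rng.standard_normal(10)
    gradient = W @ coef / np.sqrt(20.0) + np.sqrt(0.5) * rng.standard_normal(t)
    ec = ECDesignSet.build(t, [quantitative_term("W", W)])
    return gradient, ec, None, W


def _kinship_draws(chol_K: np.ndarray, m: int, rng) -> np.ndarray:
    """m columns of N(0, K) draws, shape n × m."""
    return chol_K @ rng.standard_normal((chol_K.shape[0], m))


def simulate_met(config: SimConfig) -> tuple[ModelInputs, SimTruth]:
    """Generate one simulated MET dataset under the factor-analytic model.

    Deterministic given ``config.seed``.  The returned ``ModelInputs`` covers
    all ``t_train + t_test`` environments with ``missing_prop`` of all cells
    masked; ``SimTruth`` keeps the complete phenotype matrix and every latent
    component.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, t, k = cfg.n_lines, cfg.t_total, cfg.k_true
    if k < 3:
        raise ValueError("k_true must be >= 3 (constant, gradient, unpredictable)")

    kin = simulate_kinship(n, cfg.z_cols, rng)
    gradient, ec, groups, W = simulate_environment_structure(
        cfg.ec_mode, cfg.t_train, cfg.t_test, rng, cfg.n_groups)

    # loading matrix: shares of total loading variance per environment
    grad_prop = 1.0 - cfg.main_effect_prop - cfg.unpredictable_prop
    Lam = np.zeros((k, t))
    Lam[0] = np.sqrt(cfg.main_effect_prop)
    g_std = gradient.std() if gradient.std() > 0 else 1.0
    Lam[1] = np.sqrt(grad_prop) * gradient / g_std
    n_unpred = k - 2
    U_rows = rng.standard_normal((n_unpred, t))
    U_rows /= np.sqrt((U_rows ** 2).mean(axis=1, keepdims=True))
    Lam[2:] = np.sqrt(cfg.unpredictable_prop / n_unpred) * U_rows

    chol_K = np.linalg.cholesky(kin.matrix)
    u_F = _kinship_draws(chol_K, k, rng)          # N(0, K) per factor
    e_F = rng.standard_normal((n, k))
    U_F = np.sqrt(cfg.h2) * u_F
    F = U_F + np.sqrt(1.0 - cfg.h2) * e_F

    u_R = _kinship_draws(chol_K, t, rng)
    e_R = rng.standard_normal((n, t))
    E0 = np.sqrt(cfg.h2) * u_R + np.sqrt(1.0 - cfg.h2) * e_R  # unit-variance env residual

    G = F @ Lam
    vG = G.var(axis=0, ddof=1)
    vE = E0.var(axis=0, ddof=1)

    def share(s):
        return np.mean(vG / (vG + s * s * vE)) - cfg.factor_share

    if cfg.factor_share >= 1.0:
        s_opt = 0.0
    else:
        s_opt = brentq(share, 1e-8, 1e4)
    U_R = s_opt * np.sqrt(cfg.h2) * u_R
    E_resid = s_opt * np.sqrt(1.0 - cfg.h2) * e_R
    Y_full = G + U_R + E_resid

    mask = np.ones(n * t, dtype=bool)
    n_missing = int(round(cfg.missing_prop * n * t))
    if n_missing:
        drop = rng.choice(n * t, size=n_missing, replace=False)
        mask[drop] = False
    mask = mask.reshape(n, t)
    Y = np.where(mask, Y_full, np.nan)

    col_ids = [f"env{j:04d}" for j in range(t)]
    meta = pd.DataFrame({
        "location": col_ids,
        "year": 2000,
        "state": [f"g{groups[j]:02d}" if groups is not None else "NA"
                  for j in range(t)],
        "tester": "T1",
        "role": ["train"] * cfg.t_train + ["test"] * cfg.t_test,
    }, index=col_ids)
    traits = TraitMatrix(Y, mask, list(kin.ids), col_ids, meta)
    inputs = ModelInputs(traits, kin, ec)
    truth = SimTruth(Lam, F, U_F, U_R, E_resid, Y_full, gradient, groups, W)
    return inputs, truth


# ---------------------------------------------------------------------------
# Scenario grid runner

SIM_GOALS = ("CV1", "CV2", "NewTrial", "NewState", "NewEnv",
             "NewGenoNewTrial", "NewGenoNewState", "NewGenoNewEnv")


def _goal_columns(goal: str, cfg: SimConfig, truth: SimTruth) -> np.ndarray | None:
    """Which environment columns a goal is evaluated on (None = infeasible)."""
    t_train, t_tot = cfg.t_train, cfg.t_total
    test_cols = np.arange(t_train, t_tot)
    if goal in ("CV1", "CV2"):
        return np.arange(t_train)
    if goal in ("NewTrial", "NewGenoNewTrial"):
        if cfg.ec_mode != "categorical":
            return None
        return test_cols[truth.groups[test_cols] == 1]
    if goal in ("NewState", "NewGenoNewState"):
        if cfg.ec_mode != "categorical":
            return None
        return test_cols[truth.groups[test_cols] == cfg.n_groups + 1]
    if goal in ("NewEnv", "NewGenoNewEnv"):
        if cfg.ec_mode == "categorical":
            return None
        return test_cols
    raise ValueError(f"unknown goal {goal!r}")


def run_sim_study(config: SimConfig, goals=SIM_GOALS, k_fit: int = 15,
                  sampler_config=None, n_replicates: int | None = None,
                  progress: bool = False) -> pd.DataFrame:
    """Fit the extended factor model and per-trial GBLUP on simulated METs and
    tabulate predictive abilities for the requested prediction goals.

    Per replicate, ``heldout_prop`` of lines are masked entirely during
    training and play the role of new genotypes.  Goals incompatible with the
    EC mode (e.g. NewState under a quantitative EC) are skipped.  Returns a
    tidy DataFrame (replicate, goal, model, ability, n_envs).
    """
    from .crossval import predictive_ability
    from .gblup import fit_gblup, gblup_predict_new_geno
    from .sampler import SamplerConfig, run_chain

    if sampler_config is None:
        sampler_config = SamplerConfig(k_max=k_fit, n_iter=600, burn_in=300,
                                       thin=3)
    reps = config.n_replicates if n_replicates is None else n_replicates
    rows = []
    for rep in range(reps):
        cfg = replace(config, seed=config.seed + rep)
        inputs, truth = simulate_met(cfg)
        rng = np.random.default_rng(cfg.seed + 900_000)
        n = cfg.n_lines
        n_held = int(round(cfg.heldout_prop * n))
        held = np.zeros(n, dtype=bool)
        held[rng.choice(n, size=n_held, replace=False)] = True

        train_cols = np.arange(cfg.t_train)
        train_inputs = inputs.subset_cols(train_cols)
        row_mask = np.repeat(~held[:, None], cfg.t_train, axis=1)
        train_inputs = train_inputs.with_traits(
            train_inputs.traits.with_mask(row_mask))
        scfg = replace(sampler_config, seed=cfg.seed + 1)

        post = run_chain(train_inputs, scfg, progress=progress)
        F_hat = post.F.mean(axis=0)
        UF_hat = post.U_F.mean(axis=0)
        Lam_hat = post.Lambda.mean(axis=0)
        UR_hat = post.U_R.mean(axis=0)
        # posterior-mean loading columns for every environment via EC regression
        Wfull, _ = inputs.ec.stacked()
        Lam_new = np.einsum("dpk,tp->dkt", post.A, Wfull).mean(axis=0)

        # per-trial GBLUP on observed training cells of non-held lines
        tr = train_inputs.traits
        K = inputs.kinship.matrix
        gblup_mat = np.full((n, cfg.t_train), np.nan)
        for j in range(cfg.t_train):
            obs = tr.observed_mask[:, j]
            if obs.sum() < 3:
                continue
            idx = np.flatnonzero(obs)
            k_oo = K[np.ix_(idx, idx)]
            fit = fit_gblup(tr.values[idx, j], k_oo)
            gblup_mat[idx, j] = fit.g_hat
            rest = np.flatnonzero(~obs)
            gblup_mat[rest, j] = gblup_predict_new_geno(
                fit, K[np.ix_(rest, idx)], k_oo)
        gblup_row_avg = np.nanmean(gblup_mat, axis=1)

        Yf = truth.Y_full
        for goal in goals:
            cols = _goal_columns(goal, cfg, truth)
            if cols is None or len(cols) == 0:
                continue
            new_geno = goal == "CV1" or goal.startswith("NewGeno")
            rows_eval = held if new_geno else ~held
            if goal == "CV1":
                mega = UF_hat @ Lam_hat + UR_hat
                gb = gblup_mat
            elif goal == "CV2":
                mega = F_hat @ Lam_hat + UR_hat
                gb = gblup_mat
            else:
                basis = UF_hat if new_geno else F_hat
                mega = basis @ Lam_new[:, cols]
                gb = np.tile(gblup_row_avg[:, None], (1, len(cols)))
            abilities_m, abilities_g = [], []
            for jj, col in enumerate(cols):
                if goal == "CV2":
                    cells = (~inputs.traits.observed_mask[:, col]) & rows_eval
                else:
                    cells = rows_eval
                if cells.sum() < 2:
                    continue
                y = Yf[cells, col]
                jm = col if goal in ("CV1", "CV2") else jj
                rm = predictive_ability(y, mega[cells, jm])
                rg = predictive_ability(y, gb[cells, jm])
                if np.isfinite(rm):
                    abilities_m.append(rm)
                if np.isfinite(rg):
                    abilities_g.append(rg)
            for model, vals in (("extended", abilities_m), ("gblup", abilities_g)):
                if vals:
                    rows.append({"replicate": rep, "goal": goal, "model": model,
                                 "ability": float(np.mean(vals)),
                                 "n_envs": len(vals)})
    return pd.DataFrame(rows)
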