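"""Meta-analytic summaries of per-experiment predictive abilities and
loading-matrix diagnostics.

Per-experiment correlations are pooled with a Hunter–Schmidt-type
random-effects meta-analysis: each correlation's sampling variance is
``(1 − r̄²)²/(n_i − 1)`` with ``r̄`` the sample-size-weighted mean, the
between-experiment variance is the HS estimator (floored at zero), and the
pooled mean uses inverse total-variance weights.  Paired model comparisons
meta-analyze per-experiment differences of two dependent correlations, with
the dependent-correlations covariance formula when the correlation between
the two prediction vectors is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MetaResult:
    mean: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    n_experiments: int
    p_value: float | None = None


def _hs_pool(y: np.ndarray, v: np.ndarray, n: np.ndarray) -> tuple[float, float, float]:
    """Hunter–Schmidt random-effects pooling: returns (mean, se, tau2).

    The pooled mean is the sample-size-weighted average; the between-study
    variance is the HS estimator with inverse-sampling-variance weights
    (floored at 0); the SE is the weighted ("sandwich") form under the fixed
    sample-size weights.
    """
    w = n.astype(float)
    mean = float(np.sum(w * y) / np.sum(w))
    wi = 1.0 / v
    yb = float(np.sum(wi * y) / np.sum(wi))
    tau2 = max(0.0, float(np.sum(wi * (y - yb) ** 2) / np.sum(wi)
                          - np.sum(wi * v) / np.sum(wi)))
    se = float(np.sqrt(np.sum(w ** 2 * (v + tau2))) / np.sum(w))
    return mean, se, tau2


def meta_mean_ability(table: pd.DataFrame, level: float = 0.95) -> MetaResult:
    """Pooled mean predictive ability across experiments.

    ``table`` needs columns ``ability`` and ``n_test`` (one row per
    experiment).  Undefined abilities (NaN) are dropped with a warning.
    """
    sub = table.dropna(subset=["ability"])
    if len(sub) < len(table):
        warnings.warn(f"dropped {len(table) - len(sub)} undefined abilities",
                      stacklevel=2)
    r = sub["ability"].to_numpy(dtype=float)
    n = sub["n_test"].to_numpy(dtype=float)
    if len(r) == 0:
        raise ValueError("no defined abilities to pool")
    if len(r) == 1:
        warnings.warn("single experiment: degenerate meta-analysis", stacklevel=2)
        return MetaResult(float(r[0]), 0.0, float(r[0]), float(r[0]), 0.0, 1)
    rbar = float(np.sum(n * r) / np.sum(n))
    v = (1.0 - rbar ** 2) ** 2 / (n - 1.0)
    mean, se, tau2 = _hs_pool(r, v, n)
    z = stats.norm.ppf(0.5 + level / 2)
    return MetaResult(mean, se, mean - z * se, mean + z * se, tau2, len(r))


def dependent_corr_diff_var(r_ya: float, r_yb: float, n: float,
                            r_ab: float | None = None) -> float:
    """Sampling variance of ``r_ya − r_yb`` on the same sample of size n.

    With ``r_ab`` (the correlation between the two prediction vectors) the
    dependent-correlations covariance is used; without it the correlations
    are treated as independent (conservative fallback).
    """
    va = (1.0 - r_ya ** 2) ** 2 / (n - 1.0)
    vb = (1.0 - r_yb ** 2) ** 2 / (n - 1.0)
    if r_ab is None:
        return va + vb
    cov = (r_ab * (1.0 - r_ya ** 2 - r_yb ** 2)
           - 0.5 * r_ya * r_yb * (1.0 - r_ya ** 2 - r_yb ** 2 - r_ab ** 2)) / (n - 1.0)
    v = va + vb - 2.0 * cov
    return max(v, 1e-12)


def meta_paired_difference(table_a: pd.DataFrame, table_b: pd.DataFrame,
                           r_ab: pd.Series | dict | None = None,
                           level: float = 0.95) -> MetaResult:
    """Random-effects meta-analysis of per-experiment ability differences
    (model a − model b), sample-size weighted, with a two-sided p-value for
    mean difference = 0.

    ``r_ab`` optionally supplies, per experiment id, the correlation between
    the two models' prediction vectors for the dependent-correlations SE.
    """
    a = table_a.set_index("experiment_id")
    b = table_b.set_index("experiment_id")
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise ValueError(f"experiment sets differ: only in a={only_a}, "
                         f"only in b={only_b}")
    exps = list(a.index)
    ra = a.loc[exps, "ability"].to_numpy(dtype=float)
    rb = b.loc[exps, "ability"].to_numpy(dtype=float)
    n = a.loc[exps, "n_test"].to_numpy(dtype=float)
    d = ra - rb
    v = np.empty_like(d)
    for i, e in enumerate(exps):
        rab = None
        if r_ab is not None:
            rab = dict(r_ab).get(e)
        v[i] = dependent_corr_diff_var(ra[i], rb[i], n[i], rab)
    if len(d) == 1:
        z0 = d[0] / np.sqrt(v[0])
        p = float(2 * stats.norm.sf(abs(z0)))
        return MetaResult(float(d[0]), float(np.sqrt(v[0])), np.nan, np.nan,
                          0.0, 1, p)
    mean, se, tau2 = _hs_pool(d, v, n)
    z = stats.norm.ppf(0.5 + level / 2)
    if np.all(d == 0.0):
        p = 1.0
    elif se == 0:
        p = 0.0
    else:
        p = float(2 * stats.norm.sf(abs(mean / se)))
    return MetaResult(mean, se, mean - z * se, mean + z * se, tau2, len(d), p)


def normal_ci(mean: float, s: float, n: float, level: float = 0.95):
    """``mean ± z·s/√n`` (z = 1.96 at the 95% level)."""
    if s < 0 or n < 1:
        raise ValueError("need s >= 0 and n >= 1")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * s / np.sqrt(n)
    return float(mean - half), float(mean + half)


def loading_ec_scan(lambda_mean: np.ndarray,
                    candidates: pd.DataFrame) -> pd.DataFrame:
    """Associate posterior-mean loading rows with per-experiment covariates.

    For each (factor, covariate) pair the loading row is regressed on the
    covariate (one-hot for non-numeric columns); the overall-F p-value is
    Bonferroni-adjusted across the k factors tested per covariate.  Constant
    loading rows or constant covariates get the p = 1 sentinel.
    """
    import statsmodels.api as sm

    lam = np.atleast_2d(np.asarray(lambda_mean, dtype=float))
    k, t = lam.shape
    if len(candidates) != t:
        raise ValueError("candidate table rows must align with experiments")
    rows = []
    for cov in candidates.columns:
        col = candidates[cov]
        if pd.api.types.is_numeric_dtype(col):
            X = col.to_numpy(dtype=float)[:, None]
        else:
            X = pd.get_dummies(col.astype(str), drop_first=True).to_numpy(dtype=float)
        for ki in range(k):
            y = lam[ki]
            degenerate = (np.std(y) == 0 or X.size == 0
                          or np.all(np.std(X, axis=0) == 0))
            if degenerate:
                p_raw = 1.0
                r2 = 0.0
            else:
                fit = sm.OLS(y, sm.add_constant(X)).fit()
                p_raw = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
                r2 = float(fit.rsquared)
            p_adj = min(1.0, p_raw * k)
            rows.append({"factor": ki, "covariate": cov, "p_raw": p_raw,
                         "p_adjusted": p_adj,
                         "neg_log10_p": float(-np.log10(max(p_adj, 1e-300))),
                         "r2": r2, "degenerate": bool(degenerate)})
    return pd.DataFrame(rows)


def factor_importance(post, share_threshold: float = 0.01) -> pd.DataFrame:
    """Per-factor squared-loading magnitudes from the posterior-mean Λ.

    Reports Σ_j λ²_kj per factor, its share of the total, the maximum
    per-experiment variance share λ²_kj / var(ŷ_j), and whether the factor
    clears the importance threshold (default 1% of trait variance in at
    least one experiment).
    """
    lam = post.Lambda.mean(axis=0)                 # k × t
    goo = np.einsum("dnk,dkt->dnt", post.F, post.Lambda) + post.U_R
    yhat = goo.mean(axis=0)
    var_y = yhat.var(axis=0, ddof=0)
    var_y = np.where(var_y > 0, var_y, np.nan)
    sq = lam ** 2
    total = sq.sum()
    share_exp = sq / var_y[None, :]
    max_share = np.nanmax(share_exp, axis=1)
    df = pd.DataFrame({
        "factor": np.arange(lam.shape[0]),
        "sum_sq_loading": sq.sum(axis=1),
        "share_of_total": sq.sum(axis=1) / total if total > 0 else 0.0,
        "max_experiment_share": max_share,
        "important": max_share > share_threshold,
    })
    df.attrs["n_important"] = int(df["important"].sum())
    return df
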