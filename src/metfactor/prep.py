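"""Plot-level MET data engineering: experiment splitting, outlier filtering,
per-experiment BLUEs, hybrid parent-genotype inference and the VanRaden
genomic relationship matrix.

An *experiment* is one tester family within one location-year trial; hybrids
are crosses of a candidate inbred (P1) onto a shared tester, so the trait
matrix assembled here has P1s as rows and location-year-tester experiments as
columns.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import Kinship, TraitMatrix, experiment_id

log = logging.getLogger(__name__)

PLOT_COLUMNS = ("trial", "tester", "hybrid", "P1", "replicate", "block", "value")


def split_experiments(plots: pd.DataFrame, min_hybrids: int = 50) -> dict:
    """Split plot data by (trial, tester) keeping partitions with at least
    ``min_hybrids`` distinct hybrid genotypes (counted as genotypes, not
    plots).  Returns {(trial, tester): sub-table}."""
    out = {}
    for key, sub in plots.groupby(["trial", "tester"], sort=True):
        n_hyb = sub["hybrid"].nunique()
        if n_hyb >= min_hybrids:
            out[key] = sub.reset_index(drop=True)
        else:
            log.info("dropping experiment %s: %d hybrids < %d", key, n_hyb,
                     min_hybrids)
    return out


def flag_outliers(values) -> np.ndarray:
    """Chauvenet-type criterion: flag value v when the expected count of
    equally extreme values under the fitted normal is below one, i.e.
    ``m · 2(1 − Φ(|v − mean|/sd)) < 1`` with sample mean/sd (ddof=1).

    The criterion depends on the sample size m: duplicating a dataset can
    newly flag a borderline point.  sd = 0 flags nothing.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros(len(v), dtype=bool)
    z = np.abs(v - v.mean()) / sd
    expected = len(v) * 2.0 * norm.sf(z)
    return expected < 1.0


def filter_outliers(experiments: dict) -> dict:
    """Two-level filtering: within-experiment points first, then whole
    experiments whose mean is an outlier among experiment means."""
    cleaned = {}
    for key, sub in experiments.items():
        mask = flag_outliers(sub["value"].to_numpy())
        if mask.any():
            log.info("experiment %s: removed %d outlying plots", key, mask.sum())
        cleaned[key] = sub.loc[~mask].reset_index(drop=True)
    keys = list(cleaned)
    if len(keys) >= 3:
        means = np.array([cleaned[k]["value"].mean() for k in keys])
        bad = flag_outliers(means)
        for k, flag in zip(keys, bad):
            if flag:
                log.info("experiment %s removed: outlying mean", k)
                del cleaned[k]
    return cleaned


def _marginal_means(X_h, X_r, y, Z=None, var_ratio=None):
    """GLS/OLS hybrid means averaged equally over replicate levels.

    X_h: hybrid one-hot (no intercept, full set); X_r: replicate one-hot
    dropped-first (may be empty); Z: random-block one-hot; var_ratio is
    σ²_block/σ²_e at the REML optimum (None = OLS).
    """
    n = len(y)
    X = np.hstack([X_h, X_r]) if X_r.size else X_h
    if Z is None or var_ratio is None:
        XtX = X.T @ X
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
    else:
        V = var_ratio * (Z @ Z.T) + np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX + 1e-10 * np.eye(X.shape[1]), X.T @ Vi @ y)
    h = X_h.shape[1]
    mu_h = beta[:h]
    if X_r.size:
        # equal-weight marginal over replicate levels (first level's effect is 0)
        mu_h = mu_h + beta[h:].sum() / (X_r.shape[1] + 1.0)
    return mu_h


def fit_blues(experiment: pd.DataFrame) -> pd.Series:
    """Per-hybrid BLUEs under the design-appropriate model.

    Model selection by design structure: ≥2 replicates & ≥2 blocks → hybrid +
    replicate fixed with block-in-replicate random; ≥2 replicates, single
    blocks → hybrid + replicate fixed; 1 replicate, ≥2 blocks → hybrid fixed
    with block random; else hybrid means.  The single random variance is
    estimated by REML (eigendecomposition of the block Gram matrix); BLUEs
    are marginal means averaging equally over replicate levels.
    """
    sub = experiment.dropna(subset=["value"]).copy()
    if sub.empty:
        raise ValueError("experiment has no data")
    y = sub["value"].to_numpy(dtype=float)
    hybrids = sorted(sub["hybrid"].astype(str).unique())
    X_h = pd.get_dummies(sub["hybrid"].astype(str))[hybrids].to_numpy(dtype=float)

    reps = sub["replicate"].astype(str)
    n_rep = reps.nunique()
    blocks_within = sub.groupby(reps.values)["block"].nunique()
    multi_block = (blocks_within > 1).any()

    X_r = np.empty((len(sub), 0))
    Z = None
    if n_rep >= 2:
        X_r = pd.get_dummies(reps, drop_first=True).to_numpy(dtype=float)
    if multi_block:
        if n_rep >= 2:
            rb = reps + ":" + sub["block"].astype(str)
        else:
            rb = sub["block"].astype(str)
        Z = pd.get_dummies(rb).to_numpy(dtype=float)

    var_ratio = None
    if Z is not None and Z.shape[1] >= 2:
        var_ratio = _reml_block_ratio(y, np.hstack([X_h, X_r]) if X_r.size else X_h, Z)
    mu = _marginal_means(X_h, X_r, y, Z, var_ratio)
    return pd.Series(mu, index=hybrids, name="blue")


def _reml_block_ratio(y, X, Z) -> float:
    """REML estimate of σ²_block/σ²_e for a single random term via 1-D search
    on the log ratio, using the residual projection of X."""
    from scipy.optimize import minimize_scalar
    n, p = X.shape
    Q, _ = np.linalg.qr(X, mode="complete")
    C = Q[:, np.linalg.matrix_rank(X):]          # basis of the residual space
    ZZ = Z @ Z.T
    Kc = C.T @ ZZ @ C
    theta, U = np.linalg.eigh((Kc + Kc.T) / 2)
    theta = np.clip(theta, 0.0, None)
    y_rot = U.T @ (C.T @ y)
    m = len(y_rot)
    if m == 0 or np.all(theta < 1e-12):
        return 0.0          # saturated fixed effects: no information on the ratio

    def neg_ll(log_phi):
        phi = np.exp(log_phi)
        v = phi * theta + 1.0
        s2 = np.sum(y_rot ** 2 / v) / m
        return 0.5 * (np.sum(np.log(v)) + m * np.log(max(s2, 1e-300)) + m)

    res = minimize_scalar(neg_ll, bounds=(-12, 12), method="bounded",
                          options={"xatol": 1e-8})
    return float(np.exp(res.x))


def assemble_trait_matrix(blues: dict, p1_of: dict, trial_meta: pd.DataFrame | None = None
                          ) -> TraitMatrix:
    """Reshape per-experiment BLUEs into the P1 × experiment trait matrix.

    ``blues`` maps (trial, tester) → per-hybrid BLUE Series; ``p1_of`` maps
    hybrid → P1.  A P1 crossed to two testers occupies one row and two
    columns; duplicate (P1, experiment) entries raise.
    """
    cells: dict[tuple[str, str], float] = {}
    col_meta_rows = {}
    dups = []
    for (trial, tester), series in blues.items():
        parts = str(trial).rsplit("_", 1)
        location, year = (parts[0], parts[1]) if len(parts) == 2 else (str(trial), "0")
        exp = experiment_id(location, year, tester)
        state = ""
        if trial_meta is not None and trial in trial_meta.index:
            state = str(trial_meta.loc[trial, "state"])
        col_meta_rows[exp] = {"location": location, "year": year,
                              "state": state, "tester": str(tester)}
        for hyb, val in series.items():
            p1 = p1_of.get(hyb)
            if p1 is None:
                raise KeyError(f"hybrid {hyb!r} has no P1 mapping")
            key = (str(p1), exp)
            if key in cells:
                dups.append(key)
            cells[key] = float(val)
    if dups:
        raise ValueError(f"duplicate (P1, experiment) BLUEs: {sorted(set(dups))[:5]}")
    rows = sorted({k[0] for k in cells})
    cols = list(col_meta_rows)
    mat = np.full((len(rows), len(cols)), np.nan)
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    for (p1, exp), val in cells.items():
        mat[ri[p1], ci[exp]] = val
    meta = pd.DataFrame(col_meta_rows).T.reindex(cols)
    return TraitMatrix.from_values(mat, rows, cols, meta)


# ---------------------------------------------------------------------------
# genotypes


def filter_sites(dosages: pd.DataFrame, maf_min: float = 0.05,
                 max_missing: float = 0.20) -> pd.DataFrame:
    """Keep sites with minor allele frequency > maf_min and missing rate
    < max_missing (dosages coded 0/1/2 with NaN missing)."""
    M = dosages.to_numpy(dtype=float)
    miss = np.mean(~np.isfinite(M), axis=0)
    p = np.nanmean(M, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = (maf > maf_min) & (miss < max_missing)
    return dosages.loc[:, dosages.columns[keep]]


def infer_parent_genotypes(hybrids: pd.DataFrame, tester_of: dict
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Infer P1 and tester dosages from hybrid dosages.

    Rules per hybrid per site: dosage 0 or 2 → both parents carry it;
    dosage 1 → the tester is 0 if any same-tester hybrid is 0 at the site
    (so P1 is 2), otherwise the tester is taken homozygous alternate (2) and
    P1 is 0; same-tester hybrids showing both 0 and 2 while the focal hybrid
    is 1 are irreconcilable → both parents missing there, logged.

    Hybrids whose tester is not shared with at least one other hybrid are
    dropped.  Returns (P1 matrix, tester matrix, conflict log table).
    """
    counts = pd.Series(tester_of).value_counts()
    keep = [h for h in hybrids.index if counts.get(tester_of[h], 0) >= 2]
    dropped = [h for h in hybrids.index if h not in set(keep)]
    for h in dropped:
        log.info("dropping hybrid %s: tester %s not replicated", h, tester_of[h])
    hyb = hybrids.loc[keep]
    M = hyb.to_numpy(dtype=float)
    testers = np.array([tester_of[h] for h in hyb.index])
    sites = list(hyb.columns)

    P1 = np.full_like(M, np.nan)
    tester_ids = sorted(set(testers))
    T = np.full((len(tester_ids), M.shape[1]), np.nan)
    conflicts = []
    for ti, tester in enumerate(tester_ids):
        rows = np.flatnonzero(testers == tester)
        sub = M[rows]
        has0 = np.any(sub == 0, axis=0)
        has2 = np.any(sub == 2, axis=0)
        has1 = np.any(sub == 1, axis=0)
        t_row = np.full(M.shape[1], np.nan)
        t_row[has0 & ~has2] = 0.0
        t_row[has2 & ~has0] = 2.0
        t_row[~has0 & ~has2 & has1] = 2.0          # inbred tester: alternate homozygote
        conflict = has0 & has2
        T[ti] = np.where(conflict, np.nan, t_row)
        for r in rows:
            h = M[r]
            homo = (h == 0) | (h == 2)
            P1[r, homo] = h[homo]
            het = h == 1
            P1[r, het & has0 & ~has2] = 2.0
            P1[r, het & ~has0] = 0.0               # tester 2 → P1 0
            bad = het & conflict
            P1[r, bad] = np.nan
            for j in np.flatnonzero(bad):
                conflicts.append({"hybrid": hyb.index[r], "tester": tester,
                                  "site": sites[j]})
    if conflicts:
        log.info("parent inference: %d irreconcilable hybrid-site calls",
                 len(conflicts))
    p1_df = pd.DataFrame(P1, index=hyb.index, columns=sites)
    t_df = pd.DataFrame(T, index=tester_ids, columns=sites)
    return p1_df, t_df, pd.DataFrame(conflicts)


def vanraden_grm(markers: pd.DataFrame | np.ndarray, ids=None) -> Kinship:
    """VanRaden additive GRM: ``G = (M − 2P)(M − 2P)ᵀ / (2 Σ p(1−p))``.

    Allele frequencies come from the supplied matrix; monomorphic sites are
    dropped and missing dosages mean-imputed per site before centering.
    """
    if isinstance(markers, pd.DataFrame):
        ids = [str(i) for i in markers.index]
        M = markers.to_numpy(dtype=float)
    else:
        M = np.asarray(markers, dtype=float)
        ids = list(ids) if ids is not None else [f"g{i}" for i in range(M.shape[0])]
    p = np.nanmean(M, axis=0) / 2.0  # per-site allele frequency
    keep = (p > 0) & (p < 1)
    M = M[:, keep]
    p = p[keep]
    if M.shape[1] == 0:
        raise ValueError("no polymorphic sites")
    M = np.where(np.isfinite(M), M, 2.0 * p[None, :])
    Mc = M - 2.0 * p[None, :]
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = Mc @ Mc.T / denom
    return Kinship(G, ids)
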