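"""Growth-stage weather environmental covariates.

Daily corn growing degree days (GDD, °F) drive a thermal-time partition of
each trial's season into 23 maize growth stages (VE, V1–V18, VT, R1, R2 and a
merged R3–R6).  Eleven daily weather variables plus GDD are averaged within
each stage, and season totals of accumulated GDD (AGDD) and accumulated
precipitation (APRE) are appended, giving (11+1)·23 + 2 = 278 EC features
per trial.

The conventional corn GDD is ((Tmax' + Tmin')/2) − 50 with Tmin floored at
50 °F and Tmax clipped to [50, 86] °F; ``divisor=1`` reproduces the
unhalved variant (Tmax' + Tmin' − 50), which roughly doubles AGDD and is
provided for comparison only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GDD_BASE_F = 50.0
GDD_CAP_F = 86.0
N_STAGES = 23

STAGE_NAMES = (["VE"] + [f"V{i}" for i in range(1, 19)] + ["VT", "R1", "R2",
                                                           "R3-R6"])

DEFAULT_WEATHER_VARIABLES = (
    "tmax", "tmin", "tmean", "precip", "humidity", "solar_radiation",
    "wind_speed", "dew_point", "vapor_pressure_deficit", "soil_temp",
    "evapotranspiration",
)


@dataclass
class StageTable:
    """23 ordered growth stages with strictly increasing AGDD entry
    thresholds.  The default thresholds are synthetic placeholders with a
    realistic shape (emergence near 115 GDD, ~84 GDD per leaf stage, grain
    fill after ~2000), not agronomic reference values."""

    names: list[str]
    thresholds: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if len(self.names) != N_STAGES or len(self.thresholds) != N_STAGES:
            raise ValueError(f"need exactly {N_STAGES} stages")
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")

    @classmethod
    def default(cls) -> "StageTable":
        thr = [0.0, 115.0]                           # VE, V1
        thr += [115.0 + 84.0 * i for i in range(1, 18)]   # V2..V18
        last = thr[-1]
        thr += [last + 120.0, last + 320.0, last + 520.0]  # VT, R1, R2
        # R3-R6 threshold: it is the 23rd entry
        return cls(list(STAGE_NAMES), np.array(thr[:22] + [thr[21] + 250.0]))

    @classmethod
    def from_csv(cls, path) -> "StageTable":
        df = pd.read_csv(path)
        return cls(list(df["stage"].astype(str)),
                   df["agdd_threshold"].to_numpy(dtype=float))


def compute_gdd_series(weather: pd.DataFrame, divisor: float = 2.0) -> pd.DataFrame:
    """Daily GDD and AGDD for one trial.

    ``weather`` needs columns ``date``, ``tmax``, ``tmin`` (°F) and is
    assumed restricted to [planting, harvest].  Days with tmax < tmin are
    skipped with a warning.  Returns the input plus ``gdd`` and ``agdd``.
    """
    w = weather.copy()
    if w["date"].duplicated().any():
        raise ValueError("duplicate dates in weather table")
    bad = w["tmax"] < w["tmin"]
    if bad.any():
        warnings.warn(f"skipping {int(bad.sum())} day(s) with tmax < tmin",
                      stacklevel=2)
        w = w.loc[~bad].reset_index(drop=True)
    tmin = np.clip(w["tmin"].to_numpy(dtype=float), GDD_BASE_F, None)
    tmax = np.clip(w["tmax"].to_numpy(dtype=float), GDD_BASE_F, GDD_CAP_F)
    w["gdd"] = (tmax + tmin) / divisor - GDD_BASE_F
    w["agdd"] = np.cumsum(w["gdd"].to_numpy())
    return w


def stage_partition(agdd, stages: StageTable) -> np.ndarray:
    """Per-day stage indices (0-based).  Day d is in stage s iff
    AGDD(d) ∈ [threshold_s, threshold_{s+1}); stages never entered stay
    empty and are flagged in the log."""
    agdd = np.asarray(agdd, dtype=float)
    if np.any(np.diff(agdd) < 0):
        raise ValueError("AGDD must be nondecreasing")
    idx = np.searchsorted(stages.thresholds, agdd, side="right") - 1
    idx = np.clip(idx, 0, N_STAGES - 1)
    reached = set(idx.tolist())
    missing = [stages.names[s] for s in range(N_STAGES) if s not in reached]
    if missing:
        log.info("season too short: stages never entered: %s", missing)
    return idx


def build_weather_ecs(weather: pd.DataFrame, stages: StageTable,
                      variables=DEFAULT_WEATHER_VARIABLES,
                      divisor: float = 2.0) -> pd.Series:
    """278-feature EC vector for one trial: per-stage means of the weather
    variables and GDD, plus season totals AGDD and APRE.

    Stages the season never reaches yield missing features (to be
    mean-imputed across trials downstream, with a log entry)."""
    if len(variables) != 11:
        raise ValueError("expected 11 weather variables")
    w = compute_gdd_series(weather, divisor=divisor)
    stage_idx = stage_partition(w["agdd"].to_numpy(), stages)
    feats = {}
    cols = list(variables) + ["gdd"]
    for s, name in enumerate(stages.names):
        in_stage = stage_idx == s
        for var in cols:
            key = f"{var}_{name}"
            feats[key] = float(w.loc[in_stage, var].mean()) if in_stage.any() \
                else np.nan
    feats["AGDD"] = float(w["agdd"].iloc[-1])
    feats["APRE"] = float(w["precip"].sum())
    out = pd.Series(feats)
    n_missing = int(out.isna().sum())
    if n_missing:
        log.info("trial EC vector: %d features from unreached stages missing",
                 n_missing)
    return out


def ec_eigenfeatures(matrix, n_components: int | None = None,
                     variance_target: float = 0.95) -> np.ndarray:
    """Scaled eigenvector features from a trials × variables table or a PSD
    trial similarity matrix.

    For a variables table: columns are standardized (all-missing columns are
    disallowed; missing entries mean-imputed), and the eigenvectors of the
    trial × trial covariance are scaled by the square roots of their
    eigenvalues (equivalently the SVD scores).  For a symmetric PSD matrix:
    its eigenvectors are scaled likewise.  ``n_components=None`` keeps the
    smallest number of components explaining ``variance_target`` of the
    variance, capped at trials − 1.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    symmetric = X.shape[0] == X.shape[1] and np.allclose(X, X.T, atol=1e-10)
    if symmetric:
        s, Q = np.linalg.eigh((X + X.T) / 2)
        if s[0] < -1e-8:
            symmetric = False                  # not PSD: treat as a table
    if symmetric:
        order = np.argsort(s)[::-1]
        s, Q = np.clip(s[order], 0, None), Q[:, order]
        feats = Q * np.sqrt(s)[None, :]
        evals = s
    else:
        if np.all(~np.isfinite(X), axis=0).any():
            raise ValueError("all-missing column; impute or drop it first")
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isfinite(X), X, col_mean[None, :])
        X = X - X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
        U, sv, _ = np.linalg.svd(X, full_matrices=False)
        feats = U * sv[None, :]
        evals = sv ** 2
    if n_components is None:
        total = evals.sum()
        if total <= 0:
            n_components = 1
        else:
            frac = np.cumsum(evals) / total
            n_components = int(np.searchsorted(frac, variance_target) + 1)
        n_components = min(n_components, max(n - 1, 1))
    return feats[:, :n_components]
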