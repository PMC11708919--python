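"""Cross-validation scenario construction and the model × scenario harness.

Six scenarios are supported, mirroring standard MET prediction questions:

* ``CV1`` — new genotypes: one genotype 5-fold partition shared by every
  experiment; a fold's genotypes are test everywhere simultaneously.
* ``CV2`` — sparse testing: same partition, but fold order permuted
  independently per experiment, so each genotype is unobserved in ~1/5 of
  experiments while observed in the rest.
* ``NewTrial`` / ``NewState`` / ``NewTester`` / ``NewGenoNewYear`` — new
  environments: built on top of each of the five CV2 training sets by holding
  out whole trials, states (those with enough experiments), tester-defined
  experiment sets, or two-year blocks.  ``NewGenoNewYear`` additionally drops
  from the test set any genotype observed in training, so both the genotypes
  and the environments are new.

Per-experiment predictive ability is the Pearson correlation between observed
phenotypes and predicted genetic values over the test cells, averaged across
a scenario's assignments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ModelInputs
from .modelspec import ModelSpec

SCENARIOS = ("CV1", "CV2", "NewTrial", "NewState", "NewTester", "NewGenoNewYear")
NEW_ENV_SCENARIOS = ("NewTrial", "NewState", "NewTester", "NewGenoNewYear")
N_FOLDS = 5
MIN_STATE_EXPERIMENTS = 9
UNDEFINED_ABILITY = np.nan


class ScenarioInfeasible(ValueError):
    pass


@dataclass
class Assignment:
    """One train/test split at cell resolution."""

    train_mask: np.ndarray          # n × t bool: cells available for training
    test_cells: np.ndarray          # n × t bool: cells scored
    new_env_cols: np.ndarray        # column indices wholly excluded from training
    new_geno_rows: np.ndarray       # row indices with zero training observations
    label: str = ""


@dataclass
class FoldPlan:
    scenario: str
    assignments: list[Assignment]
    seed: int

    def to_json(self, path, col_ids=None) -> None:
        payload = {"scenario": self.scenario, "seed": self.seed,
                   "assignments": []}
        for a in self.assignments:
            payload["assignments"].append({
                "label": a.label,
                "new_env_cols": ([col_ids[j] for j in a.new_env_cols]
                                 if col_ids is not None else
                                 [int(j) for j in a.new_env_cols]),
                "n_train_cells": int(a.train_mask.sum()),
                "n_test_cells": int(a.test_cells.sum()),
            })
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _genotype_folds(n: int, rng) -> np.ndarray:
    """Seeded shuffle into N_FOLDS groups whose sizes differ by at most 1."""
    labels = np.arange(n) % N_FOLDS
    return labels[rng.permutation(n)]


def _cv2_labels(n: int, t: int, rng) -> np.ndarray:
    """n × t fold labels: the CV1 partition with fold order independently
    permuted per experiment."""
    base = _genotype_folds(n, rng)
    lab = np.empty((n, t), dtype=int)
    for j in range(t):
        perm = rng.permutation(N_FOLDS)
        lab[:, j] = perm[base]
    return lab, base


def _year_blocks(years: np.ndarray) -> list[np.ndarray]:
    """Consecutive two-year windows from the minimum year (partial last)."""
    y0 = int(np.min(years))
    blocks = []
    y = y0
    while y <= int(np.max(years)):
        cols = np.flatnonzero((years >= y) & (years <= y + 1))
        if len(cols):
            blocks.append(cols)
        y += 2
    return blocks


def make_folds(inputs: ModelInputs, scenario: str, seed: int = 0) -> FoldPlan:
    """Construct the fold plan of a scenario; deterministic given ``seed``."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    tr = inputs.traits
    n, t = tr.n, tr.t
    obs = tr.observed_mask
    rng = np.random.default_rng(seed)
    lab, base = _cv2_labels(n, t, rng)

    if scenario == "CV1":
        assignments = []
        for f in range(N_FOLDS):
            test_rows = base == f
            train = obs & ~test_rows[:, None]
            test = obs & test_rows[:, None]
            assignments.append(Assignment(train, test, np.array([], dtype=int),
                                          np.flatnonzero(test_rows), f"CV1-f{f}"))
        return FoldPlan(scenario, assignments, seed)

    if scenario == "CV2":
        assignments = []
        for f in range(N_FOLDS):
            test = obs & (lab == f)
            train = obs & (lab != f)
            assignments.append(Assignment(train, test, np.array([], dtype=int),
                                          np.array([], dtype=int), f"CV2-f{f}"))
        return FoldPlan(scenario, assignments, seed)

    # new-environment scenarios: built on each of the five CV2 training sets
    meta = tr.col_meta
    if scenario == "NewTrial":
        trials = meta["location"].astype(str) + "_" + meta["year"].astype(str)
        uniq = sorted(trials.unique())
        order = rng.permutation(len(uniq))
        groups = [[uniq[i] for i in order[g::N_FOLDS]] for g in range(N_FOLDS)]
        col_sets = [np.flatnonzero(trials.isin(g).to_numpy()) for g in groups]
        labels = [f"trialfold{g}" for g in range(N_FOLDS)]
    elif scenario == "NewState":
        states = meta["state"].astype(str)
        counts = states.value_counts()
        big = sorted(counts[counts >= MIN_STATE_EXPERIMENTS].index)
        if not big:
            raise ScenarioInfeasible(
                f"no state with >= {MIN_STATE_EXPERIMENTS} experiments")
        col_sets = [np.flatnonzero((states == s).to_numpy()) for s in big]
        labels = [f"state:{s}" for s in big]
    elif scenario == "NewTester":
        testers = meta["tester"].astype(str)
        uniq = sorted(testers.unique())
        if len(uniq) < 2:
            raise ScenarioInfeasible("need at least 2 testers")
        col_sets = [np.flatnonzero((testers == s).to_numpy()) for s in uniq]
        labels = [f"tester:{s}" for s in uniq]
    else:  # NewGenoNewYear
        years = meta["year"].astype(int).to_numpy()
        blocks = _year_blocks(years)
        if len(blocks) < 2:
            raise ScenarioInfeasible("need at least 2 two-year blocks")
        col_sets = [np.asarray(b) for b in blocks]
        labels = [f"years:{years[b].min()}-{years[b].max()}" for b in blocks]

    assignments = []
    for f in range(N_FOLDS):
        cv2_train = obs & (lab != f)
        cv2_test = obs & (lab == f)
        for cols, lbl in zip(col_sets, labels):
            in_cols = np.zeros(t, dtype=bool)
            in_cols[cols] = True
            train = cv2_train & ~in_cols[None, :]
            test = cv2_test & in_cols[None, :]
            new_rows = np.array([], dtype=int)
            if scenario == "NewGenoNewYear":
                trained_rows = train.any(axis=1)
                test = test & ~trained_rows[:, None]
                new_rows = np.flatnonzero(~trained_rows)
            assignments.append(Assignment(train, test, cols, new_rows,
                                          f"CV2-f{f}/{lbl}"))
    return FoldPlan(scenario, assignments, seed)


def predictive_ability(y, g_hat) -> float:
    """Pearson correlation of observed values with predictions; NaN sentinel
    when either side has zero variance or fewer than 2 pairs."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g_hat, dtype=float)
    keep = np.isfinite(y) & np.isfinite(g)
    y, g = y[keep], g[keep]
    if len(y) < 2 or np.std(y) == 0 or np.std(g) == 0:
        return UNDEFINED_ABILITY
    return float(np.corrcoef(y, g)[0, 1])


# ---------------------------------------------------------------------------
# models the harness can run


class MegaLMMModel:
    """Extended factor model wrapper: fit the chain on the training cells and
    predict every cell, routing new-environment columns through the EC
    loading regression (or constant prediction for ``::O`` specs)."""

    def __init__(self, spec, sampler_config, constant_grouping_col: str | None = None):
        self.spec = spec
        self.config = sampler_config
        self.constant_grouping_col = constant_grouping_col
        self.label = spec.label if isinstance(spec, ModelSpec) else str(spec)

    def fit_predict(self, inputs: ModelInputs, assignment: Assignment):
        from .modelspec import parse_model_spec
        from .predict import (constant_prediction, new_env_loadings,
                              predict_old_geno_old_env)
        from .sampler import run_chain

        spec = self.spec
        if not isinstance(spec, ModelSpec):
            spec = parse_model_spec(spec, inputs.ec.names)
        t = inputs.traits.t
        train_cols = np.setdiff1d(np.arange(t), assignment.new_env_cols)
        sub = inputs.subset_cols(train_cols)
        sub = sub.with_traits(sub.traits.with_mask(assignment.train_mask[:, train_cols]))
        post = run_chain(sub, self.config, spec)

        total = (np.einsum("dnk,dkt->dnt", post.F, post.Lambda) + post.U_R).mean(0)
        additive = (np.einsum("dnk,dkt->dnt", post.U_F, post.Lambda)
                    + post.U_R).mean(0)
        est_total = np.full((inputs.traits.n, t), np.nan)
        est_add = np.full_like(est_total, np.nan)
        est_total[:, train_cols] = total
        est_add[:, train_cols] = additive

        cols_new = assignment.new_env_cols
        if len(cols_new):
            if spec.uses_constant:
                goo = predict_old_geno_old_env(post, self.label)
                grouping, clusters = self._grouping(inputs, train_cols, cols_new)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cp = constant_prediction(
                        goo, grouping,
                        target_cols=[inputs.traits.col_ids[j] for j in cols_new],
                        target_clusters=clusters)
                est_total[:, cols_new] = cp.estimates
                ga = constant_prediction(
                    PredictionResult_like(additive, post),
                    grouping,
                    target_cols=[inputs.traits.col_ids[j] for j in cols_new],
                    target_clusters=clusters)
                est_add[:, cols_new] = ga.estimates
            else:
                ec_new = {}
                for nm in spec.predictor_terms:
                    term = inputs.ec.term(nm)
                    ec_new[nm] = term.design[cols_new]
                lam = new_env_loadings(post, ec_new, spec)   # D × k × m
                est_total[:, cols_new] = np.einsum(
                    "dnk,dkm->dnm", post.F, lam).mean(0)
                est_add[:, cols_new] = np.einsum(
                    "dnk,dkm->dnm", post.U_F, lam).mean(0)
        return est_total, est_add

    def _grouping(self, inputs, train_cols, cols_new):
        if self.constant_grouping_col is None:
            return None, [None] * len(cols_new)
        meta = inputs.traits.col_meta[self.constant_grouping_col].astype(str)
        grouping = {inputs.traits.col_ids[j]: meta.iloc[j] for j in train_cols}
        clusters = [meta.iloc[j] for j in cols_new]
        return grouping, clusters


def PredictionResult_like(estimates, post):
    from .predict import PredictionResult
    return PredictionResult(estimates, np.zeros_like(estimates), "Goo",
                            post.row_ids, post.col_ids)


class GblupModel:
    """Per-experiment univariate GBLUP with kinship regression for unobserved
    genotypes and a constant averaging strategy for new environments.

    ``strategy`` is ``"ALL"`` or a metadata column name (``"state"``,
    ``"tester"``) defining the averaging cluster.
    """

    def __init__(self, strategy: str = "ALL"):
        self.strategy = strategy
        self.label = f"GBLUP_{strategy}"

    def fit_predict(self, inputs: ModelInputs, assignment: Assignment):
        from .gblup import fit_gblup, gblup_predict_new_geno

        tr = inputs.traits
        n, t = tr.n, tr.t
        K = inputs.kinship.matrix[np.ix_(inputs.genotype_incidence,
                                         inputs.genotype_incidence)]
        est = np.full((n, t), np.nan)
        train_cols = np.setdiff1d(np.arange(t), assignment.new_env_cols)
        for j in train_cols:
            obs = assignment.train_mask[:, j]
            if obs.sum() < 3:
                continue
            idx = np.flatnonzero(obs)
            k_oo = K[np.ix_(idx, idx)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_gblup(tr.values[idx, j], k_oo)
            est[idx, j] = fit.g_hat
            rest = np.flatnonzero(~obs)
            if len(rest):
                est[rest, j] = gblup_predict_new_geno(fit, K[np.ix_(rest, idx)],
                                                      k_oo)
        cols_new = assignment.new_env_cols
        if len(cols_new):
            have = [j for j in train_cols if np.isfinite(est[:, j]).all()]
            meta = tr.col_meta
            for j in cols_new:
                members = have
                if self.strategy != "ALL":
                    cl = str(meta[self.strategy].iloc[j])
                    members = [i for i in have
                               if str(meta[self.strategy].iloc[i]) == cl] or have
                est[:, j] = est[:, members].mean(axis=1)
        return est, est


class OracleModel:
    """Injects a fixed prediction matrix; harness sanity checks."""

    def __init__(self, estimates: np.ndarray, label: str = "oracle"):
        self.estimates = estimates
        self.label = label

    def fit_predict(self, inputs, assignment):
        return self.estimates, self.estimates


def run_scenario(inputs: ModelInputs, models: list, plan: FoldPlan,
                 y_eval: np.ndarray | None = None) -> pd.DataFrame:
    """Evaluate each model on every assignment of a fold plan.

    Returns an AbilityTable: one row per model × experiment with the ability
    averaged over the assignments in which the experiment had test cells.
    ``y_eval`` overrides the evaluation phenotypes (defaults to the observed
    trait values; a simulation can pass the complete matrix).
    """
    tr = inputs.traits
    Y = tr.values if y_eval is None else np.asarray(y_eval, dtype=float)
    records = []
    for model in models:
        per_exp: dict[str, list] = {}
        per_exp_n: dict[str, list] = {}
        for a in plan.assignments:
            if (a.train_mask & a.test_cells).any():
                raise AssertionError("train and test cells overlap")
            est_total, est_add = model.fit_predict(inputs, a)
            use_add = plan.scenario == "CV1" or (
                plan.scenario == "NewGenoNewYear")
            est = est_add if use_add else est_total
            for j in range(tr.t):
                cells = a.test_cells[:, j]
                m = int(cells.sum())
                if m < 2:
                    continue
                r = predictive_ability(Y[cells, j], est[cells, j])
                if np.isfinite(r):
                    per_exp.setdefault(tr.col_ids[j], []).append(r)
                    per_exp_n.setdefault(tr.col_ids[j], []).append(m)
        for exp, vals in per_exp.items():
            records.append({
                "model_label": model.label, "scenario": plan.scenario,
                "experiment_id": exp, "ability": float(np.mean(vals)),
                "n_test": int(round(np.mean(per_exp_n[exp]))),
                "fold_count": len(vals),
            })
    return pd.DataFrame(records)


def select_best_strategy(table: pd.DataFrame, candidates: list[str],
                         n_terms: dict[str, int] | None = None) -> str:
    """Candidate with the highest meta-analytic mean ability; ties broken by
    fewer predictor terms, then label order."""
    from .evalstats import meta_mean_ability

    if not candidates:
        raise ValueError("no candidates")
    scored = []
    for label in candidates:
        sub = table[table["model_label"] == label]
        if sub.empty:
            raise ValueError(f"candidate {label!r} absent from the table")
        if len(sub) == 1:
            mean = float(sub["ability"].iloc[0])
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mean = meta_mean_ability(sub).mean
        nt = (n_terms or {}).get(label, label.count("+") + 1)
        scored.append((-round(mean, 12), nt, label))
    scored.sort()
    return scored[0][2]
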