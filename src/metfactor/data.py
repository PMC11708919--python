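"""Core data containers for multi-environment-trial (MET) genomic prediction.

The central objects are:

* :class:`TraitMatrix` — an ``n × t`` matrix of adjusted phenotypes (BLUEs),
  rows indexed by genotype, columns by *experiment* (one tester family within
  one location-year trial), with an explicit observation mask.
* :class:`Kinship` — a symmetric PSD genomic relationship matrix.
* :class:`ECDesignSet` — named environmental-covariate (EC) terms, each a
  ``t × p_l`` design matrix over experiments (intercept term first).
* :class:`ModelInputs` — the bundle handed to the sampler and baselines.

Missing phenotypes are ``NaN`` in memory and the literal string ``NA`` on
disk; the mask, not a sentinel value, is authoritative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

INTERCEPT = "intercept"

META_COLUMNS = ("location", "year", "state", "tester")


def experiment_id(location: str, year, tester: str) -> str:
    """Display id for an experiment: ``<location>_<year>_<tester>``."""
    return f"{location}_{year}_{tester}"


@dataclass
class TraitMatrix:
    """Genotype × experiment phenotype matrix with missingness mask.

    ``values`` holds NaN at unobserved cells; ``observed_mask`` is False
    there.  ``col_meta`` is a DataFrame indexed by ``col_ids`` with columns
    ``location, year, state, tester`` (extra columns are allowed).
    """

    values: np.ndarray
    observed_mask: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    col_meta: pd.DataFrame

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask shapes differ")
        n, t = self.values.shape
        if len(self.row_ids) != n or len(self.col_ids) != t:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.row_ids)) != n:
            raise ValueError("row_ids not unique")
        if len(set(self.col_ids)) != t:
            raise ValueError("col_ids not unique")
        # NaN cells must be masked out
        self.observed_mask = self.observed_mask & np.isfinite(self.values)
        self.col_meta = self.col_meta.reindex(self.col_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_values(cls, values, row_ids, col_ids, col_meta=None) -> "TraitMatrix":
        values = np.asarray(values, dtype=float)
        mask = np.isfinite(values)
        if col_meta is None:
            col_meta = pd.DataFrame(index=list(col_ids),
                                    columns=list(META_COLUMNS), dtype=object)
        return cls(values, mask, list(row_ids), list(col_ids), col_meta)

    @classmethod
    def from_csv(cls, values_path, meta_path=None) -> "TraitMatrix":
        df = pd.read_csv(values_path, index_col=0, na_values=["NA"])
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, index_col=0)
        return cls.from_values(df.to_numpy(dtype=float),
                               [str(i) for i in df.index],
                               [str(c) for c in df.columns], meta)

    def to_csv(self, values_path, meta_path=None) -> None:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)
        df.to_csv(values_path, na_rep="NA")
        if meta_path is not None:
            self.col_meta.to_csv(meta_path)

    def subset_cols(self, cols: np.ndarray) -> "TraitMatrix":
        """New TraitMatrix restricted to the given column indices."""
        cols = np.asarray(cols)
        return TraitMatrix(self.values[:, cols], self.observed_mask[:, cols],
                           list(self.row_ids), [self.col_ids[j] for j in cols],
                           self.col_meta.iloc[cols])

    def with_mask(self, mask: np.ndarray) -> "TraitMatrix":
        """Copy with observation restricted to ``mask & observed_mask``."""
        mask = np.asarray(mask, dtype=bool) & self.observed_mask
        values = np.where(mask, self.values, np.nan)
        return TraitMatrix(values, mask, list(self.row_ids),
                           list(self.col_ids), self.col_meta.copy())


@dataclass
class Kinship:
    """Symmetric PSD genomic relationship matrix over genotype ids."""

    matrix: np.ndarray
    ids: list[str]
    SYM_TOL: float = field(default=1e-8, repr=False)
    PSD_TOL: float = field(default=-1e-8, repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        q = self.matrix.shape[0]
        if self.matrix.shape != (q, q):
            raise ValueError("kinship must be square")
        if len(self.ids) != q or len(set(self.ids)) != q:
            raise ValueError("kinship ids must be unique and match the matrix")

    @property
    def q(self) -> int:
        return self.matrix.shape[0]

    def is_symmetric(self) -> bool:
        return bool(np.max(np.abs(self.matrix - self.matrix.T)) <= self.SYM_TOL)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh((self.matrix + self.matrix.T) / 2.0)[0])

    def index_of(self, ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.ids)}
        try:
            return np.array([pos[g] for g in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"genotype id {e.args[0]!r} not in kinship") from None

    def submatrix(self, ids) -> np.ndarray:
        idx = self.index_of(ids)
        return self.matrix[np.ix_(idx, idx)]

    def cross(self, new_ids, old_ids) -> np.ndarray:
        """K_no block: rows = new genotypes, columns = old (training)."""
        ri, ci = self.index_of(new_ids), self.index_of(old_ids)
        return self.matrix[np.ix_(ri, ci)]

    @classmethod
    def from_csv(cls, path) -> "Kinship":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path)


@dataclass
class ECTerm:
    """One named EC term: a ``t × p`` design matrix over experiments.

    Categorical terms are full one-hot over training levels (the shared
    per-term prior variance absorbs the redundancy); quantitative terms are
    centered/scaled at build time and the transform is stored so the same
    scaling applies to new environments.
    """

    name: str
    design: np.ndarray
    kind: str  # 'intercept' | 'categorical' | 'quantitative'
    levels: list[str] | None = None
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self):
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))

    @property
    def p(self) -> int:
        return self.design.shape[1]

    def rows_for(self, new_values) -> np.ndarray:
        """Design rows for new environments.

        ``new_values``: categorical — sequence of level labels (unseen levels
        map to an all-zero row with a warning); quantitative — array of raw
        covariate values, transformed with the stored training scaling;
        intercept — only a row count is needed.
        """
        if self.kind == "intercept":
            m = len(new_values) if hasattr(new_values, "__len__") else int(new_values)
            return np.ones((m, 1))
        if self.kind == "categorical":
            rows = np.zeros((len(new_values), self.p))
            lookup = {lv: i for i, lv in enumerate(self.levels)}
            for i, lv in enumerate(new_values):
                j = lookup.get(lv)
                if j is None:
                    warnings.warn(
                        f"EC term {self.name!r}: level {lv!r} unseen in "
                        "training; contributes zero", stacklevel=2)
                else:
                    rows[i, j] = 1.0
            return rows
        vals = np.atleast_2d(np.asarray(new_values, dtype=float))
        if vals.shape[1] != self.p and vals.shape[0] == self.p:
            vals = vals.T
        return (vals - self.center) / self.scale


def categorical_term(name: str, labels) -> ECTerm:
    labels = [str(x) for x in labels]
    levels = sorted(set(labels))
    design = np.zeros((len(labels), len(levels)))
    pos = {lv: j for j, lv in enumerate(levels)}
    for i, lv in enumerate(labels):
        design[i, pos[lv]] = 1.0
    return ECTerm(name, design, "categorical", levels=levels)


def quantitative_term(name: str, values) -> ECTerm:
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    center = vals.mean(axis=0)
    scale = vals.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return ECTerm(name, (vals - center) / scale, "quantitative",
                  center=center, scale=scale)


@dataclass
class ECDesignSet:
    """Ordered EC terms; the first term is always the all-ones intercept."""

    terms: list[ECTerm]

    def __post_init__(self):
        if not self.terms or self.terms[0].kind != "intercept":
            t = self.terms[0].design.shape[0] if self.terms else 0
            self.terms = [ECTerm(INTERCEPT, np.ones((t, 1)), "intercept")] + list(self.terms)
        names = [tm.name for tm in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("EC term names must be unique")
        t = self.terms[0].design.shape[0]
        for tm in self.terms:
            if tm.design.shape[0] != t:
                raise ValueError(f"EC term {tm.name!r} has wrong row count")

    @classmethod
    def build(cls, t: int, terms: list[ECTerm] | None = None) -> "ECDesignSet":
        return cls([ECTerm(INTERCEPT, np.ones((t, 1)), "intercept")] + list(terms or []))

    @property
    def t(self) -> int:
        return self.terms[0].design.shape[0]

    @property
    def names(self) -> list[str]:
        return [tm.name for tm in self.terms]

    def term(self, name: str) -> ECTerm:
        for tm in self.terms:
            if tm.name == name:
                return tm
        raise KeyError(f"unknown EC term {name!r}")

    def stacked(self, names=None) -> tuple[np.ndarray, dict[str, slice]]:
        """Horizontally stacked design ``t × P`` with per-term column slices.

        ``names=None`` stacks every term (intercept first).
        """
        use = self.names if names is None else [INTERCEPT] + [
            n for n in self.names if n != INTERCEPT and n in set(names)]
        mats, slices, off = [], {}, 0
        for n in use:
            tm = self.term(n)
            mats.append(tm.design)
            slices[n] = slice(off, off + tm.p)
            off += tm.p
        return np.hstack(mats), slices

    def subset(self, cols: np.ndarray) -> "ECDesignSet":
        """Row-subset (training environments); transforms are retained."""
        cols = np.asarray(cols)
        out = []
        for tm in self.terms:
            out.append(ECTerm(tm.name, tm.design[cols], tm.kind,
                              levels=tm.levels, center=tm.center, scale=tm.scale))
        return ECDesignSet(out)


@dataclass
class ModelInputs:
    """Everything the sampler and baselines consume."""

    traits: TraitMatrix
    kinship: Kinship
    ec: ECDesignSet
    fixed_design: np.ndarray | None = None
    genotype_incidence: np.ndarray | None = None  # row -> kinship index

    def __post_init__(self):
        n = self.traits.n
        if self.fixed_design is None:
            self.fixed_design = np.ones((n, 1))
        self.fixed_design = np.atleast_2d(np.asarray(self.fixed_design, dtype=float))
        if self.genotype_incidence is None:
            self.genotype_incidence = self.kinship.index_of(self.traits.row_ids)
        self.genotype_incidence = np.asarray(self.genotype_incidence, dtype=int)

    def with_traits(self, traits: TraitMatrix) -> "ModelInputs":
        return replace(self, traits=traits)

    def subset_cols(self, cols: np.ndarray) -> "ModelInputs":
        return ModelInputs(self.traits.subset_cols(cols), self.kinship,
                           self.ec.subset(cols), self.fixed_design,
                           self.genotype_incidence)


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"ERROR: {s}" for s in self.issues]
        lines += [f"WARNING: {s}" for s in self.warnings]
        return "\n".join(lines) or "OK"


def validate_inputs(inputs: ModelInputs) -> ValidationReport:
    """Report-only consistency checks; never mutates its argument."""
    rep = ValidationReport()
    tr, K = inputs.traits, inputs.kinship
    known = set(K.ids)
    missing = [g for g in tr.row_ids if g not in known]
    if missing:
        rep.issues.append(f"kinship missing genotype ids: {missing[:5]}"
                          + ("..." if len(missing) > 5 else ""))
    if not K.is_symmetric():
        rep.issues.append("kinship not symmetric within 1e-8")
    else:
        lam = K.min_eigenvalue()
        if lam < K.PSD_TOL:
            rep.issues.append(f"kinship not PSD: min eigenvalue {lam:.3e}")
    empty = np.flatnonzero(~inputs.traits.observed_mask.any(axis=0))
    for j in empty:
        rep.warnings.append(f"experiment {tr.col_ids[j]!r} has zero observed cells")
    X = inputs.fixed_design
    if np.linalg.matrix_rank(X) < X.shape[1]:
        rep.issues.append("fixed_design is rank deficient")
    if inputs.ec.t != tr.t:
        rep.issues.append(f"EC design rows ({inputs.ec.t}) != experiments ({tr.t})")
    if len(np.unique(inputs.genotype_incidence)) != tr.n:
        rep.issues.append("genotype_incidence maps two rows to one kinship id")
    return rep
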