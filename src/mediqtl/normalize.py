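"""Covariate correction and rank-based inverse-normal transformation.

Both the enzyme-activity phenotype and every expression probe are first
residualized on age and sex by ordinary least squares and then mapped to
standard-normal quantiles through their ranks ("quantile normalization" in
the quantitative-trait sense).  The rank offset is (r - 0.5)/n by default,
with the Blom offset (r - 3/8)/(n + 1/4) available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .io import ExpressionMatrix, PhenotypeTable

log = logging.getLogger(__name__)


@dataclass
class AdjustedVector:
    """A per-sample vector after covariate removal (and possibly normalization)."""

    sample_ids: list[str]
    values: np.ndarray
    covariates_removed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise ValueError("values must have one entry per sample")


def encode_sex(sex) -> np.ndarray:
    """Map any two-level sex labelling onto 0/1 (NaN preserved)."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "fiub":
        out = arr.astype(float)
        levels = np.unique(out[~np.isnan(out)])
    else:
        out = np.full(arr.shape, np.nan)
        mask = np.array([str(v).strip() not in ("", "NA", "nan", ".") for v in arr])
        labels = sorted({str(v).strip() for v in arr[mask]})
        if len(labels) > 2:
            raise ValueError(f"sex must be two-level, got {labels}")
        for code, lab in enumerate(labels):
            out[mask & (arr.astype(str) == lab)] = float(code)
        levels = np.unique(out[~np.isnan(out)])
    if len(levels) > 2:
        raise ValueError(f"sex must be two-level, got levels {levels}")
    if len(levels) == 2:  # map the two levels onto exactly 0 and 1
        out = np.where(np.isnan(out), np.nan, (out == levels[1]).astype(float))
    return out


def _design(age: np.ndarray, sex: np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    """Intercept + age + sex design; constant covariate columns are dropped."""
    n = len(age)
    cols = [np.ones(n)]
    names: list[str] = []
    for name, v in (("age", age), ("sex", sex)):
        finite = v[~np.isnan(v)]
        if finite.size and np.ptp(finite) > 0:
            cols.append(v)
            names.append(name)
        else:
            log.warning("covariate %r is constant; dropped from the design", name)
    return np.column_stack(cols), tuple(names)


def covariate_adjust(y, age, sex, sample_ids: list[str] | None = None) -> AdjustedVector:
    """Residualize ``y`` on intercept + age + sex by least squares.

    Samples with a missing response or covariate are dropped (and logged);
    at least 4 complete cases are required.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = encode_sex(sex)
    if not (len(y) == len(age) == len(sex)):
        raise ValueError("y, age and sex must have equal lengths")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(len(y))]
    X, names = _design(age, sex)
    complete = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    n_used = int(complete.sum())
    if n_used < 4:
        raise ValueError(f"need >= 4 complete cases for covariate adjustment, have {n_used}")
    if n_used < len(y):
        log.info("covariate adjustment dropped %d incomplete samples", len(y) - n_used)
    Xc, yc = X[complete], y[complete]
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    return AdjustedVector(
        sample_ids=[s for s, ok in zip(sample_ids, complete) if ok],
        values=resid,
        covariates_removed=names,
    )


def adjust_matrix(values: np.ndarray, age, sex) -> np.ndarray:
    """Residualize every column of a samples x features matrix on age + sex.

    Missing entries stay missing; columns with missing entries are fitted on
    their complete cases.  Returns a matrix of the same shape.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sexv = encode_sex(sex)
    X, _ = _design(age, sexv)
    rows_ok = ~np.isnan(X).any(axis=1)
    out = np.full_like(values, np.nan)
    nan_cols = np.isnan(values[rows_ok]).any(axis=0)
    if (~nan_cols).any():
        cols = np.flatnonzero(~nan_cols)
        Xc = X[rows_ok]
        B, *_ = np.linalg.lstsq(Xc, values[np.ix_(rows_ok, cols)], rcond=None)
        out[np.ix_(rows_ok, cols)] = values[np.ix_(rows_ok, cols)] - Xc @ B
    for j in np.flatnonzero(nan_cols):
        ok = rows_ok & ~np.isnan(values[:, j])
        if ok.sum() < X.shape[1] + 1:
            continue
        beta, *_ = np.linalg.lstsq(X[ok], values[ok, j], rcond=None)
        out[ok, j] = values[ok, j] - X[ok] @ beta
    return out


def inverse_normal_transform(v, offset: str = "half") -> np.ndarray:
    """Rank-based inverse-normal transform; ties get average ranks, NaN stays NaN.

    ``offset='half'`` maps rank r of n to the standard-normal quantile at
    (r - 0.5)/n; ``offset='blom'`` uses (r - 3/8)/(n + 1/4).
    """
    v = np.asarray(v, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need >= 2 non-missing values to normalize")
    vals = v[ok]
    if np.ptp(vals) == 0:
        raise ValueError("cannot rank-normalize a constant vector")
    r = rankdata(vals, method="average")
    if offset == "half":
        q = (r - 0.5) / n
    elif offset == "blom":
        q = (r - 0.375) / (n + 0.25)
    else:
        raise ValueError(f"unknown offset {offset!r}")
    out[ok] = norm.ppf(q)
    return out


def preprocess_phenotype(p: PhenotypeTable, offset: str = "half") -> AdjustedVector:
    """Age/sex-correct then rank-normalize the trait, in that order."""
    adj = covariate_adjust(p.trait, p.age, p.sex, sample_ids=p.sample_ids)
    return AdjustedVector(
        sample_ids=adj.sample_ids,
        values=inverse_normal_transform(adj.values, offset=offset),
        covariates_removed=adj.covariates_removed,
    )


def preprocess_expression(e: ExpressionMatrix, p: PhenotypeTable,
                          offset: str = "half") -> ExpressionMatrix:
    """Age/sex-correct then rank-normalize every probe; sample order must match ``p``."""
    if e.sample_ids != p.sample_ids:
        raise ValueError("expression and phenotype samples must be aligned first")
    adj = adjust_matrix(e.values, p.age, p.sex)
    out = np.full_like(adj, np.nan)
    for j in range(adj.shape[1]):
        out[:, j] = inverse_normal_transform(adj[:, j], offset=offset)
    from dataclasses import replace

    return replace(e, values=out)
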