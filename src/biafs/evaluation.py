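"""OLS evaluation of a selected feature set against a body-composition target.

Mirrors the standard regression model summary: multiple correlation R,
R², adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), and the standard error of the
estimate SEE = sqrt(RSS / (n−p−1)), plus held-out per-subject relative
errors |ŷ − y| / |y| on a deterministic file-order train/test split
(first ``n_train`` rows train, remainder test).

The three body-fat prediction equations printed by the source study
(BFM1–BFM3) ship as fixtures for :func:`apply_printed_model`; their
coefficients are applied to raw feature values as given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataio import SampleTable

log = logging.getLogger("biafs")

_RANK_TOL = 1e-8


def split_train_test(table: SampleTable, n_train: int = 80) -> tuple[SampleTable, SampleTable]:
    """Deterministic split in file order: first ``n_train`` rows train,
    the remainder test."""
    if table.n_samples <= n_train:
        raise ValueError(f"need more than n_train={n_train} rows, have {table.n_samples}")
    return table.head(n_train), table.tail(table.n_samples - n_train)


@dataclass
class LinearModel:
    """Fitted OLS model with the usual summary statistics."""

    intercept: float
    coefficients: dict[str, float]
    r: float
    r_squared: float
    adj_r_squared: float
    see: float
    n: int
    p: int

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        names = list(self.coefficients)
        if isinstance(X, pd.DataFrame):
            missing = [c for c in names if c not in X.columns]
            if missing:
                raise KeyError(f"missing predictor column(s): {missing}")
            M = X[names].to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            if M.shape[1] != len(names):
                raise ValueError("column count does not match fitted predictors")
        beta = np.array([self.coefficients[c] for c in names])
        return self.intercept + M @ beta

    def summary_row(self) -> dict[str, float]:
        return {"R": self.r, "R2": self.r_squared,
                "adj_R2": self.adj_r_squared, "SEE": self.see}


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    """Unit-scale copy so the rank test is insensitive to column units
    (raw columns span ~1e-3 ohm^-1 reciprocals to ~1e5 ohm^2 products)."""
    sd = M.std(axis=0)
    sd[sd <= 0] = 1.0
    return M / sd


def _design_rank(M: np.ndarray) -> int:
    S = _standardize_columns(M)
    smax = np.linalg.svd(S, compute_uv=False)[0] if S.size else 0.0
    return int(np.linalg.matrix_rank(S, tol=_RANK_TOL * max(1.0, smax)))


def _minimal_dependent_set(M: np.ndarray, names: list[str]) -> list[str]:
    """A small set of mutually dependent columns, for the rank error."""
    S = _standardize_columns(M)
    basis: list[int] = []
    for j in range(S.shape[1]):
        cand = basis + [j]
        if _design_rank(S[:, cand]) == len(cand):
            basis.append(j)
            continue
        coef, *_ = np.linalg.lstsq(S[:, basis], S[:, j], rcond=None)
        involved = [names[b] for b, c in zip(basis, coef) if abs(c) > 1e-6]
        return involved + [names[j]]
    return []


def fit_ols(X: pd.DataFrame | np.ndarray, y: np.ndarray,
            feature_names: list[str] | None = None) -> LinearModel:
    """Least-squares fit with intercept; errors on rank-deficient designs.

    ``X`` is n×p (DataFrame column names become coefficient names).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        names = feature_names or [f"x{j + 1}" for j in range(M.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n, p = M.shape
    if y.size != n:
        raise ValueError("X and y lengths differ")
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    design = np.column_stack([np.ones(n), M])
    if _design_rank(design) < p + 1:
        dep = _minimal_dependent_set(design, ["(constant)"] + names)
        raise ValueError(f"design matrix is rank deficient; dependent columns: {dep}")

    fit = sm.OLS(y, design).fit()
    r2 = float(fit.rsquared)
    see = float(np.sqrt(fit.ssr / (n - p - 1)))
    return LinearModel(
        intercept=float(fit.params[0]),
        coefficients={nm: float(b) for nm, b in zip(names, fit.params[1:])},
        r=float(np.sqrt(max(r2, 0.0))),
        r_squared=r2,
        adj_r_squared=float(1 - (1 - r2) * (n - 1) / (n - p - 1)),
        see=see,
        n=n,
        p=p,
    )


@dataclass
class RelativeErrorSummary:
    """Held-out relative errors; entries with zero actual value are
    flagged and excluded from the max/mean."""

    errors: np.ndarray           # nan where the actual value was zero
    max: float
    mean: float
    n_excluded: int


def relative_errors(model: LinearModel, X_test, y_test) -> RelativeErrorSummary:
    """Per-subject |ŷ − y| / |y| for a fitted model on held-out data."""
    y = np.asarray(y_test, dtype=float).ravel()
    pred = model.predict(X_test)
    nonzero = y != 0
    errs = np.full(y.shape, np.nan)
    errs[nonzero] = np.abs(pred[nonzero] - y[nonzero]) / np.abs(y[nonzero])
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        log.warning("excluded %d zero-valued actual(s) from relative error", n_excluded)
    valid = errs[nonzero]
    return RelativeErrorSummary(errors=errs,
                                max=float(valid.max()) if valid.size else float("nan"),
                                mean=float(valid.mean()) if valid.size else float("nan"),
                                n_excluded=n_excluded)


@dataclass(frozen=True)
class PrintedModel:
    """A published body-fat prediction equation (raw-feature coefficients)."""

    name: str
    coefficients: dict[str, float]
    intercept: float

    def apply(self, row) -> float:
        missing = [c for c in self.coefficients if c not in row]
        if missing:
            raise KeyError(f"{self.name}: missing feature value(s): {missing}")
        return self.intercept + sum(b * float(row[c]) for c, b in self.coefficients.items())


# The study's three printed BFM equations.  The sex indicator printed as
# "S" is this package's feature "G"; BFM3 has no constant term.
PRINTED_BFM_MODELS: dict[str, PrintedModel] = {
    "BFM1": PrintedModel("BFM1", {
        "W": 0.041, "G": 0.126, "A": 0.523, "R3": -0.212,
        "1/R1": 0.171, "1/R2": 0.126, "1/R3": 0.179,
        "R4^2": 1.132, "R4R5": 0.13, "R5^2": 0.127,
    }, intercept=-8.56),
    "BFM2": PrintedModel("BFM2", {
        "W": 0.313, "G": -0.044, "1/R3": -0.125, "1/R1": 0.108,
        "R4^2": 0.016, "R2^2": -0.01, "R5^2": 0.071,
        "R4R5": 0.072, "R5": -0.526,
    }, intercept=5.674),
    "BFM3": PrintedModel("BFM3", {
        "A": 0.464, "H": -0.15, "W": 0.122, "R5": -0.143,
        "R1R2": 0.129, "R2R3": 0.122, "R4R5": -0.134,
        "1/R5": 0.145, "R2^2": 0.129, "R5^2": -0.141,
    }, intercept=0.0),
}


def apply_printed_model(model: str | PrintedModel, row) -> float:
    """Evaluate a printed prediction equation on one row of feature values.

    ``row`` is any mapping from feature name to value (a dict or a pandas
    Series over expanded-feature columns).
    """
    if isinstance(model, str):
        try:
            model = PRINTED_BFM_MODELS[model]
        except KeyError:
            raise KeyError(f"unknown printed model {model!r}; "
                           f"available: {sorted(PRINTED_BFM_MODELS)}") from None
    return model.apply(row)
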