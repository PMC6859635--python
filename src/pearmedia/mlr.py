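"""Multiple linear regression baseline (main effects, ordinary least squares)."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factors import FACTOR_NAMES


@dataclass(frozen=True)
class MLRModel:
    """Intercept + one coefficient per input column."""

    response: str
    intercept: float
    coefficients: dict[str, float]
    quadratic: bool = False

    def predict(self, X: pd.DataFrame | dict) -> np.ndarray:
        cols = _expand(_frame(X, list(self.coefficients) if not self.quadratic
                              else None), self.quadratic)
        out = np.full(len(cols), self.intercept)
        for name, coef in self.coefficients.items():
            out = out + coef * cols[name].to_numpy(float)
        return out

    def coefficient_table(self) -> pd.DataFrame:
        rows = [{"term": "intercept", "coefficient": self.intercept}]
        rows += [{"term": k, "coefficient": v} for k, v in self.coefficients.items()]
        return pd.DataFrame(rows)


def _frame(X, cols=None) -> pd.DataFrame:
    df = pd.DataFrame(X)
    if cols is not None:
        base = [c for c in cols if "*" not in c and ":" not in c]
        missing = [c for c in base if c not in df]
        if missing:
            raise KeyError(f"missing input columns {missing}")
    return df


def _expand(df: pd.DataFrame, quadratic: bool) -> pd.DataFrame:
    cols = [c for c in FACTOR_NAMES if c in df.columns]
    if not cols:
        cols = [c for c in df.columns if df[c].dtype.kind in "fi"]
    out = df[cols].astype(float).copy()
    if quadratic:
        for i, a in enumerate(cols):
            for b in cols[i:]:
                out[f"{a}*{b}"] = out[a] * out[b]
    return out


def _collinear_columns(M: np.ndarray, names: list[str], tol: float = 1e-8) -> list[str]:
    """Columns linearly dependent on their predecessors (incremental rank)."""
    bad, rank_so_far = [], 0
    for j in range(M.shape[1]):
        r = np.linalg.matrix_rank(M[:, : j + 1], tol=tol * max(1.0, np.abs(M).max()))
        if r == rank_so_far:
            bad.append(names[j])
        rank_so_far = r
    return bad


def fit_mlr(train: pd.DataFrame, response: str, quadratic: bool = False) -> MLRModel:
    """Ordinary-least-squares fit of ``response`` on the factor columns.

    Raises on rank deficiency, naming the collinear columns.
    """
    X = _expand(_frame(train), quadratic)
    names = list(X.columns)
    y = _frame(train)[response].to_numpy(float)
    if len(X) <= X.shape[1]:
        raise ValueError("need more records than parameters")
    M = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        bad = _collinear_columns(M, ["intercept", *names])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    return MLRModel(
        response=response,
        intercept=float(beta[0]),
        coefficients=dict(zip(names, map(float, beta[1:]))),
        quadratic=quadratic,
    )
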