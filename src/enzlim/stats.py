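"""Univariate statistical layer: Pearson, OLS, quadratic fits, stepwise.

Thin, contract-enforcing wrappers around scipy/statsmodels plus a
bidirectional AIC stepwise search.  Significance is two-sided at α = 0.05
throughout, with no multiple-testing correction (the screens are
exploratory; see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stoichiometry import ValidationError

__all__ = [
    "CorrelationResult",
    "RegressionFit",
    "QuadraticFit",
    "QuadShape",
    "StepwiseResult",
    "pearson",
    "ols",
    "quadratic_fit",
    "stepwise",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary: coefficient table plus fit statistics.

    ``params``/``bse``/``tvalues``/``pvalues`` are indexed by term name
    (``const`` for the intercept).
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    adj_r_squared: float
    n: int
    df_resid: int
    aic: float


class QuadShape(str, Enum):
    HUMP = "HUMP"
    U = "U"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass(frozen=True)
class QuadraticFit:
    """Fit of y = a + b·x + c·x² with a hump/U label.

    The shape is HUMP only when the curvature c is negative, significant at
    0.05, and the vertex −b/(2c) lies inside the observed x range (and
    symmetrically U for positive curvature): a maximum outside the data is
    just a monotone trend.
    """

    fit: RegressionFit
    a: float
    b: float
    c: float
    vertex_x: float | None
    shape: QuadShape


@dataclass(frozen=True)
class StepwiseResult:
    selected: tuple[str, ...]
    fit: RegressionFit
    trace: tuple[tuple[int, str, str, float], ...]  # (step, action, term, AIC)


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the exact t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"x and y must be equal-length vectors, got "
                              f"{x.shape} and {y.shape}")
    n = x.size
    if n < 3:
        raise ValidationError(f"Pearson correlation needs n ≥ 3, got n={n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation is undefined for a constant vector")
    from scipy import stats as sps

    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def _as_design(X) -> pd.DataFrame:
    if isinstance(X, pd.Series):
        X = X.to_frame()
    elif not isinstance(X, pd.DataFrame):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        X = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
    return X.astype(float)


def ols(y, X, add_intercept: bool = True) -> RegressionFit:
    """Ordinary least squares with classical (homoskedastic) inference.

    ``X`` may be a DataFrame, Series, or array; an intercept column is added
    by default.  Raises a singular-design error listing the collinear
    columns when the design is rank deficient.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    n, k = X.shape
    if y.shape != (n,):
        raise ValidationError(f"y has length {len(y)}, design has {n} rows")
    if n <= k:
        raise ValidationError(f"need n > number of coefficients ({k}), got n={n}")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        suspects = [
            c for c in X.columns
            if c != "const"
            and np.linalg.matrix_rank(X.drop(columns=c).to_numpy())
            == np.linalg.matrix_rank(X.to_numpy())
        ]
        raise ValidationError(
            f"singular design matrix; collinear column(s): {suspects or list(X.columns)}"
        )
    res = sm.OLS(y, X).fit()
    return RegressionFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        n=n,
        df_resid=int(res.df_resid),
        aic=float(res.aic),
    )


def quadratic_fit(y, x, alpha: float = 0.05) -> QuadraticFit:
    """Fit y on [1, x, x²] and label the curve HUMP, U or NONE."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValidationError(f"quadratic fit needs n ≥ 4, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; quadratic fit is undefined")
    X = pd.DataFrame({"x": x, "x2": x**2})
    fit = ols(y, X, add_intercept=True)
    a = float(fit.params["const"])
    b = float(fit.params["x"])
    c = float(fit.params["x2"])
    p_c = float(fit.pvalues["x2"])
    vertex = -b / (2 * c) if c != 0 else None
    shape = QuadShape.NONE
    if c != 0 and p_c < alpha and vertex is not None:
        if x.min() <= vertex <= x.max():
            shape = QuadShape.HUMP if c < 0 else QuadShape.U
    return QuadraticFit(fit=fit, a=a, b=b, c=c, vertex_x=vertex, shape=shape)


def stepwise(
    y,
    candidates: pd.DataFrame,
    direction: str = "both",
    criterion: str = "aic",
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> StepwiseResult:
    """Bidirectional stepwise predictor screening from the intercept-only model.

    With ``criterion="aic"`` (default), at each step every single-term
    addition and removal is scored and the move with the largest AIC decrease
    is taken; the search stops when no move lowers the AIC.  Ties are broken
    by predictor name order, so the search is deterministic.

    ``criterion="pvalue"`` instead enters the most significant candidate with
    p < ``alpha_enter`` and removes the least significant selected term with
    p > ``alpha_remove``.

    ``direction`` may be ``"both"``, ``"forward"`` or ``"backward"``
    (backward starts from the full model and only removes).
    """
    if direction not in ("both", "forward", "backward"):
        raise ValidationError(f"unknown direction {direction!r}")
    if criterion not in ("aic", "pvalue"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    y = np.asarray(y, dtype=float)
    candidates = _as_design(candidates)
    names = sorted(candidates.columns)
    for c in names:
        if np.ptp(candidates[c].to_numpy()) == 0:
            raise ValidationError(f"candidate {c!r} is constant")

    selected: list[str] = names.copy() if direction == "backward" else []
    can_add = direction in ("both", "forward")
    can_remove = direction in ("both", "backward")

    def fit_terms(terms: list[str]) -> RegressionFit:
        if terms:
            return ols(y, candidates[terms], add_intercept=True)
        X0 = pd.DataFrame(index=range(len(y)))
        return ols(y, X0, add_intercept=True)

    current = fit_terms(selected)
    trace: list[tuple[int, str, str, float]] = [(0, "start", "", current.aic)]
    step = 0
    if criterion == "aic":
        while True:
            if current.r_squared > 1 - 1e-12 and selected:
                break  # numerically perfect fit; AIC differences are noise
            step += 1
            moves: list[tuple[float, str, str]] = []
            if can_add:
                for name in names:
                    if name not in selected:
                        try:
                            cand_fit = fit_terms(sorted(selected + [name]))
                        except ValidationError:
                            continue  # too few df or singular; move infeasible
                        moves.append((cand_fit.aic, "add", name))
            if can_remove:
                for name in selected:
                    cand_fit = fit_terms([t for t in selected if t != name])
                    moves.append((cand_fit.aic, "remove", name))
            if not moves:
                break
            moves.sort(key=lambda m: (m[0], m[1], m[2]))
            best_aic, action, name = moves[0]
            if best_aic >= current.aic - 1e-10:
                break
            if action == "add":
                selected = sorted(selected + [name])
            else:
                selected = [t for t in selected if t != name]
            current = fit_terms(selected)
            trace.append((step, action, name, current.aic))
    else:
        while True:
            step += 1
            changed = False
            if can_add:
                best: tuple[float, str] | None = None
                for name in names:
                    if name in selected:
                        continue
                    try:
                        cand_fit = fit_terms(sorted(selected + [name]))
                    except ValidationError:
                        continue
                    p = float(cand_fit.pvalues[name])
                    if p < alpha_enter and (best is None or p < best[0]):
                        best = (p, name)
                if best is not None:
                    selected = sorted(selected + [best[1]])
                    current = fit_terms(selected)
                    trace.append((step, "add", best[1], current.aic))
                    changed = True
            if can_remove and selected:
                ps = {t: float(current.pvalues[t]) for t in selected}
                worst = max(sorted(ps), key=lambda t: ps[t])
                if ps[worst] > alpha_remove:
                    selected = [t for t in selected if t != worst]
                    current = fit_terms(selected)
                    trace.append((step, "remove", worst, current.aic))
                    changed = True
            if not changed:
                break
    return StepwiseResult(
        selected=tuple(selected), fit=current, trace=tuple(trace)
    )
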