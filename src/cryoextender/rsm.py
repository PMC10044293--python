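"""Response-surface least squares, fit-order summary, and Type III ANOVA.

Works on experiment tables in physical units. The model matrix is built
from a :class:`~cryoextender.design.ModelSpec` evaluated at the raw
concentrations (intercept, mains, two-way interactions, squares). Type III
(partial) sums of squares come from full-vs-term-deleted model
comparisons, the natural reading of "partial" for continuous covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelSpec, Term, expand_model_matrix


@dataclass
class ModelFit:
    model: ModelSpec
    coefficients: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    r2: float
    df_residual: int
    mse_residual: float
    aliased: list[Term]
    response: str


def _model_matrix(table: pd.DataFrame, model: ModelSpec) -> np.ndarray:
    points = table[list(model.factors)].to_numpy(dtype=float)
    return expand_model_matrix(points, model)


def _aliased_terms(X: np.ndarray, model: ModelSpec) -> list[Term]:
    """Terms whose columns are linearly dependent on earlier ones."""
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    _, _, piv = qr(X, pivoting=True, mode="economic")
    dependent = sorted(piv[rank:])
    return [model.terms[j] for j in dependent]


def fit_ols(table: pd.DataFrame, model: ModelSpec, response: str) -> ModelFit:
    """Least-squares fit of the model to one response column.

    Rank-deficient matrices are fitted with the pseudo-inverse and the
    aliased terms flagged on the returned fit.
    """
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    X = _model_matrix(table, model)
    n, p = X.shape
    y = table[response].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rank = np.linalg.matrix_rank(X)
    df_resid = n - rank
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return ModelFit(
        model=model,
        coefficients=beta,
        residuals=resid,
        fitted=fitted,
        r2=r2,
        df_residual=df_resid,
        mse_residual=sse / df_resid if df_resid > 0 else np.nan,
        aliased=_aliased_terms(X, model),
        response=response,
    )


class ResponseSurfaceOLS:
    """sklearn-style wrapper: fit a polynomial response surface by OLS.

    Parameters
    ----------
    model : ModelSpec
        Terms to fit, in physical units.
    response : str
        Response column name ("tm" or "pm").
    """

    def __init__(self, model: ModelSpec, response: str = "tm"):
        self.model = model
        self.response = response

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "response": self.response}

    def set_params(self, **params) -> "ResponseSurfaceOLS":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, table: pd.DataFrame, y=None) -> "ResponseSurfaceOLS":
        fit = fit_ols(table, self.model, self.response)
        self.coef_ = fit.coefficients
        self.residuals_ = fit.residuals
        self.r2_ = fit.r2
        self.df_residual_ = fit.df_residual
        self.mse_residual_ = fit.mse_residual
        self.aliased_ = fit.aliased
        self.fit_ = fit
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return _model_matrix(table, self.model) @ self.coef_


def _order_models(factors: list[str]) -> dict[str, ModelSpec]:
    """Nested linear < quadratic < cubic term hierarchies."""
    lin: list[Term] = [("intercept",)] + [("main", f) for f in factors]
    quad = lin + [("interaction", f, g) for f, g in combinations(factors, 2)] + [
        ("quadratic", f) for f in factors
    ]
    # cubic adds pure cubes and all degree-3 mixed monomials, encoded as
    # generic exponent terms via repeated interaction naming is not
    # expressible in ModelSpec; cubic columns are built separately.
    return {
        "linear": ModelSpec(tuple(factors), tuple(lin)),
        "quadratic": ModelSpec(tuple(factors), tuple(quad)),
    }


def _cubic_columns(table: pd.DataFrame, factors: list[str]) -> np.ndarray:
    """Degree-3 monomial columns (x^3, x^2 y, x y z) beyond the quadratic."""
    P = table[list(factors)].to_numpy(dtype=float)
    cols = [P[:, i] ** 3 for i in range(len(factors))]
    for i in range(len(factors)):
        for j in range(len(factors)):
            if i != j:
                cols.append(P[:, i] ** 2 * P[:, j])
    for i, j, k in combinations(range(len(factors)), 3):
        cols.append(P[:, i] * P[:, j] * P[:, k])
    return np.column_stack(cols)


def sequential_fit_summary(
    table: pd.DataFrame,
    response: str,
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Sequential model-order summary (linear, quadratic, cubic).

    Each order is tested against the previous one with the
    extra-sum-of-squares F test; an order whose added columns are not
    estimable at the available run count is flagged aliased (no p-value).
    """
    if factors is None:
        factors = [c for c in table.columns if c not in ("run_id", "replicate", "bull_id", "tm", "pm")]
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    specs = _order_models(list(factors))

    X_lin = _model_matrix(table, specs["linear"])
    X_quad = _model_matrix(table, specs["quadratic"])
    X_cubic = np.column_stack([X_quad, _cubic_columns(table, list(factors))])
    rows = []
    prev_sse, prev_rank = float(((y - y.mean()) ** 2).sum()), 1
    for order, X in (("linear", X_lin), ("quadratic", X_quad), ("cubic", X_cubic)):
        rank = np.linalg.matrix_rank(X)
        aliased = rank < X.shape[1] or n - rank <= 0
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        df_extra = rank - prev_rank
        df_resid = n - rank
        if aliased or df_extra <= 0 or df_resid <= 0 or sse <= 0:
            p = np.nan
        else:
            F = ((prev_sse - sse) / df_extra) / (sse / df_resid)
            p = float(stats.f.sf(F, df_extra, df_resid))
        rows.append(
            {"order": order, "sequential_p": p, "r2": r2, "aliased": bool(aliased)}
        )
        prev_sse, prev_rank = sse, rank
    return pd.DataFrame(rows)


def type3_anova(table: pd.DataFrame, model: ModelSpec, response: str) -> pd.DataFrame:
    """Type III (partial) ANOVA by full-vs-reduced model comparison.

    SS(term) = SSE(model without term) - SSE(full model); F against the
    full model's residual mean square. Aliased terms are excluded with a
    warning column rather than an error.
    """
    full = fit_ols(table, model, response)
    if full.df_residual <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    sse_full = float(full.residuals @ full.residuals)
    mse = full.mse_residual
    rows = []
    for term in model.terms:
        if term == ("intercept",):
            continue
        if term in full.aliased:
            rows.append({"term": term, "df": 0, "mean_square": np.nan,
                         "f_value": np.nan, "p_value": np.nan, "aliased": True})
            continue
        reduced_terms = tuple(t for t in model.terms if t != term)
        reduced = ModelSpec(model.factors, reduced_terms)
        red_fit = fit_ols(table, reduced, response)
        ss = float(red_fit.residuals @ red_fit.residuals) - sse_full
        ss = max(ss, 0.0)
        df = 1
        F = (ss / df) / mse
        rows.append(
            {
                "term": term,
                "df": df,
                "mean_square": ss / df,
                "f_value": F,
                "p_value": float(stats.f.sf(F, df, full.df_residual)),
                "aliased": False,
            }
        )
    rows.append(
        {
            "term": ("residual",),
            "df": full.df_residual,
            "mean_square": mse,
            "f_value": np.nan,
            "p_value": np.nan,
            "aliased": False,
        }
    )
    return pd.DataFrame(rows)
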