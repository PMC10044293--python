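"""NIPALS partial least squares regression (PLS2) with validation metrics.

Both motility responses are modelled jointly against the 12 component
concentrations. X and Y are autoscaled (centered, unit variance); NIPALS
extracts components t_a = X w_a maximizing covariance with the responses,
deflating X (and Y) after each component. The rotated weights
W* = W (P'W)^{-1} give scores directly from the original (scaled) X, and
the regression coefficients B = W* C' are back-transformed to original
units so the fitted model reads as a plain linear prediction equation

    y_hat = intercept + sum_j B_j * concentration_j.

Validation metrics: R^2, RMSE, MAPE (% of measured), and RPD = SD/RMSE,
the ratio of the measured values' standard deviation to the model RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ValidationMetrics:
    r2: float
    rmse: float
    mape: float
    rpd: float
    n: int
    n_mape_excluded: int = 0


class NIPALSPLS:
    """PLS regression via NIPALS, sklearn-estimator style.

    Parameters
    ----------
    n_components : int
        Number of latent components A.
    max_iter : int
        NIPALS iteration cap per component.
    tol : float
        Convergence threshold on the relative change of the score vector.

    Attributes (after fit)
    ----------------------
    W_ : (p, A) X-weights; P_ : (p, A) X-loadings; C_ : (m, A) Y-loadings;
    T_ : (n, A) scores; W_star_ : (p, A) rotated weights;
    coef_ : (p, m) regression coefficients in original units;
    intercept_ : (m,) intercepts in original units;
    x_mean_, x_std_, y_mean_, y_std_ : autoscaling parameters.
    """

    def __init__(self, n_components: int = 3, max_iter: int = 1000, tol: float = 1e-10):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "max_iter": self.max_iter,
            "tol": self.tol,
        }

    def set_params(self, **params) -> "NIPALSPLS":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, Y) -> "NIPALSPLS":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        n, p = X.shape
        m = Y.shape[1]
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = X.std(axis=0, ddof=1)
        self.y_mean_ = Y.mean(axis=0)
        self.y_std_ = Y.std(axis=0, ddof=1)
        zero = np.where(self.x_std_ == 0)[0]
        if zero.size:
            raise ValueError(f"zero-variance X column(s) at index {zero.tolist()}")
        if (self.y_std_ == 0).any():
            raise ValueError("zero-variance response column")
        Xc = (X - self.x_mean_) / self.x_std_
        Yc = (Y - self.y_mean_) / self.y_std_
        rank = np.linalg.matrix_rank(Xc)
        A = self.n_components
        if A > rank:
            raise ValueError(f"n_components={A} exceeds rank(X)={rank}")

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        C = np.zeros((m, A))
        T = np.zeros((n, A))
        Xd, Yd = Xc.copy(), Yc.copy()
        for a in range(A):
            # seed u with the dominant singular direction of the
            # cross-covariance: the NIPALS fixed point, so the iteration
            # converges immediately even for near-degenerate components
            if m == 1:
                u = Yd[:, 0].copy()
            else:
                _, _, V0t = np.linalg.svd(Xd.T @ Yd, full_matrices=False)
                u = Yd @ V0t[0]
                if not u.any():
                    u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
            t_old = None
            for _it in range(self.max_iter):
                w = Xd.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    raise RuntimeError(
                        f"response residual vanished at component {a + 1}"
                    )
                w /= nw
                t = Xd @ w
                c = Yd.T @ t / (t @ t)
                if m == 1:
                    break
                u = Yd @ c / (c @ c)
                if t_old is not None and np.linalg.norm(t - t_old) <= self.tol * np.linalg.norm(t):
                    break
                t_old = t
            else:
                raise RuntimeError(
                    f"NIPALS did not converge for component {a + 1} "
                    f"after {self.max_iter} iterations"
                )
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            pa = Xd.T @ t / (t @ t)
            Xd = Xd - np.outer(t, pa)
            Yd = Yd - np.outer(t, c)
            W[:, a], P[:, a], C[:, a], T[:, a] = w, pa, c, t

        self.W_, self.P_, self.C_, self.T_ = W, P, C, T
        self.W_star_ = W @ np.linalg.inv(P.T @ W)
        B_scaled = self.W_star_ @ C.T  # p x m, scaled space
        self.coef_ = B_scaled * (self.y_std_[None, :] / self.x_std_[:, None])
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_
        self.n_features_in_ = p
        self.n_targets_ = m
        return self

    def transform(self, X) -> np.ndarray:
        """Scores of new rows: T = X_scaled W*."""
        X = np.asarray(X, dtype=float)
        return ((X - self.x_mean_) / self.x_std_) @ self.W_star_

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("wrong number of feature columns")
        return self.intercept_ + X @ self.coef_


def fit_nipals(
    calibration: pd.DataFrame,
    x_columns: list[str],
    y_columns: list[str],
    n_components: int = 3,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> NIPALSPLS:
    """Fit :class:`NIPALSPLS` on named columns of an experiment table."""
    for c in x_columns + y_columns:
        if c not in calibration.columns:
            raise ValueError(f"column {c!r} not in calibration table")
    model = NIPALSPLS(n_components=n_components, max_iter=max_iter, tol=tol)
    return model.fit(calibration[x_columns].to_numpy(float),
                     calibration[y_columns].to_numpy(float))


def predict_from_equation(
    intercept: float, coefficients: dict[str, float], rows: pd.DataFrame
) -> np.ndarray:
    """Evaluate a linear prediction equation at concentration rows.

    Pure arithmetic — no refitting: y_hat = intercept + sum coef_j * conc_j.
    """
    missing = [c for c in coefficients if c not in rows.columns]
    if missing:
        raise ValueError(f"rows are missing component column(s) {missing}")
    y = np.full(len(rows), float(intercept))
    for name, coef in coefficients.items():
        y += coef * rows[name].to_numpy(dtype=float)
    return y


def metrics(
    measured, predicted, printed_variant: bool = False
) -> ValidationMetrics:
    """R^2, RMSE, MAPE and RPD between measured and predicted vectors.

    MAPE is computed over rows with measured != 0 (motility can be
    exactly 0); the count of excluded rows is reported. With
    ``printed_variant=True`` the R^2 denominator is sum((A_i - P_i)^2)
    with A the measured mean — a nonstandard form kept available for
    comparison; the default is the standard total sum of squares.
    """
    M = np.asarray(measured, dtype=float)
    P = np.asarray(predicted, dtype=float)
    if M.shape != P.shape or M.size == 0:
        raise ValueError("measured and predicted must be equal-length, non-empty")
    sse = float(((M - P) ** 2).sum())
    if printed_variant:
        denom = float(((M.mean() - P) ** 2).sum())
    else:
        denom = float(((M - M.mean()) ** 2).sum())
    if denom == 0:
        raise ValueError("R^2 undefined: measured vector is constant")
    r2 = 1.0 - sse / denom
    rmse = float(np.sqrt(sse / M.size))
    nz = M != 0
    mape = (
        float(100.0 * np.mean(np.abs((M[nz] - P[nz]) / M[nz]))) if nz.any() else np.nan
    )
    sd = float(np.std(M, ddof=1))
    rpd = sd / rmse if rmse > 0 else np.inf
    return ValidationMetrics(
        r2=r2, rmse=rmse, mape=mape, rpd=rpd, n=int(M.size),
        n_mape_excluded=int((~nz).sum()),
    )


def jackknife_cv(
    calibration: pd.DataFrame,
    x_columns: list[str],
    y_columns: list[str],
    groups: str | np.ndarray = "bull_id",
    max_components: int = 6,
) -> tuple[pd.DataFrame, int]:
    """Leave-one-group-out predictive R^2 (Q^2) per component count.

    Groups default to bulls: each bull's rows are held out together, the
    model refitted, and the held-out rows predicted. Q^2(A) = 1 -
    PRESS(A)/TSS, averaged over responses. The recommended A is the
    smallest one within 1% of the maximum Q^2.
    """
    if isinstance(groups, str):
        g = calibration[groups].to_numpy()
    else:
        g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("cross-validation needs at least two groups")
    X = calibration[x_columns].to_numpy(float)
    Y = calibration[y_columns].to_numpy(float)
    max_components = min(max_components, np.linalg.matrix_rank(X - X.mean(axis=0)))
    press = np.zeros((max_components, Y.shape[1]))
    for lab in labels:
        hold = g == lab
        Xt, Yt = X[~hold], Y[~hold]
        for A in range(1, max_components + 1):
            m = NIPALSPLS(n_components=A).fit(Xt, Yt)
            press[A - 1] += ((Y[hold] - m.predict(X[hold])) ** 2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    q2 = 1.0 - press / tss[None, :]
    q2_mean = q2.mean(axis=1)
    best = float(q2_mean.max())
    threshold = best - 0.01 * abs(best)
    recommended = int(np.argmax(q2_mean >= threshold)) + 1
    out = pd.DataFrame(
        {"n_components": np.arange(1, max_components + 1), "q2": q2_mean}
    )
    for j, col in enumerate(y_columns):
        out[f"q2_{col}"] = q2[:, j]
    return out, recommended


def jackknife_coefficients(
    calibration: pd.DataFrame,
    x_columns: list[str],
    y_columns: list[str],
    groups: str | np.ndarray = "bull_id",
    n_components: int = 3,
    conf_level: float = 0.95,
) -> dict[str, np.ndarray]:
    """Delete-one-group jackknife SEs and CIs for the coefficients.

    SE^2 = (g-1)/g * sum_i (B_(i) - B_bar)^2 over the g leave-one-out
    estimates; intervals use the t distribution with g-1 df.
    """
    if isinstance(groups, str):
        g = calibration[groups].to_numpy()
    else:
        g = np.asarray(groups)
    labels = pd.unique(g)
    ng = len(labels)
    if ng < 2:
        raise ValueError("jackknife needs at least two groups")
    X = calibration[x_columns].to_numpy(float)
    Y = calibration[y_columns].to_numpy(float)
    full = NIPALSPLS(n_components=n_components).fit(X, Y)
    reps = np.empty((ng,) + full.coef_.shape)
    for i, lab in enumerate(labels):
        keep = g != lab
        reps[i] = NIPALSPLS(n_components=n_components).fit(X[keep], Y[keep]).coef_
    mean = reps.mean(axis=0)
    se = np.sqrt((ng - 1) / ng * ((reps - mean) ** 2).sum(axis=0))
    tq = stats.t.ppf(0.5 + conf_level / 2, df=ng - 1)
    return {
        "coef": full.coef_,
        "se": se,
        "lower": full.coef_ - tq * se,
        "upper": full.coef_ + tq * se,
        "n_groups": ng,
    }


def loading_map(model: NIPALSPLS) -> tuple[np.ndarray, np.ndarray]:
    """(w*_1, w*_2) per predictor and (c_1, c_2) per response, for plotting."""
    if model.W_star_.shape[1] < 2:
        raise ValueError("loading map needs at least 2 components")
    return model.W_star_[:, :2].copy(), model.C_[:, :2].copy()
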