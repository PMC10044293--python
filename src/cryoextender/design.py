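"""I-optimal experimental design by coordinate exchange.

An I-optimal design minimizes the average (integrated) variance of the
fitted model's predictions over the design region. For a model matrix
X and the moments matrix M of the model terms under the uniform measure
on the coded cube [-1, 1]^k, the criterion is

    I(X) = trace[(X'X)^{-1} M],

with M computed in closed form (odd moments vanish; E[x^2] = 1/3,
E[x^4] = 1/5, E[x^2 y^2] = 1/9). The coordinate-exchange search sweeps
every (run, factor) coordinate, replacing it by the candidate level that
most decreases I(X); rank-one updates of (X'X)^{-1} make each candidate
evaluation O(p^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .components import ComponentSpec

Term = tuple  # ("intercept",) | ("main", f) | ("interaction", f, g) | ("quadratic", f)


@dataclass(frozen=True)
class ModelSpec:
    """Ordered factor list plus the polynomial terms of the model."""

    factors: tuple[str, ...]
    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("model terms must be unique")
        for term in self.terms:
            kind = term[0]
            if kind == "interaction":
                _, f, g = term
                if f == g:
                    raise ValueError("interaction factors must differ")
            if kind in ("main", "quadratic", "interaction"):
                for f in term[1:]:
                    if f not in self.factors:
                        raise ValueError(f"term references unknown factor {f!r}")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def exponents(self) -> np.ndarray:
        """Per-term exponent vectors over the factors (terms x k)."""
        idx = {f: j for j, f in enumerate(self.factors)}
        E = np.zeros((len(self.terms), len(self.factors)), dtype=int)
        for i, term in enumerate(self.terms):
            if term[0] == "main":
                E[i, idx[term[1]]] = 1
            elif term[0] == "quadratic":
                E[i, idx[term[1]]] = 2
            elif term[0] == "interaction":
                E[i, idx[term[1]]] += 1
                E[i, idx[term[2]]] += 1
            elif term[0] != "intercept":
                raise ValueError(f"unknown term kind {term[0]!r}")
        return E


def linear_model(factors: list[str]) -> ModelSpec:
    terms: list[Term] = [("intercept",)] + [("main", f) for f in factors]
    return ModelSpec(tuple(factors), tuple(terms))


def quadratic_model(factors: list[str]) -> ModelSpec:
    """Full quadratic: intercept, mains, all two-way interactions, squares.

    For k factors this has 1 + k + k(k-1)/2 + k terms (91 for k = 12).
    """
    terms: list[Term] = [("intercept",)]
    terms += [("main", f) for f in factors]
    terms += [("interaction", f, g) for f, g in combinations(factors, 2)]
    terms += [("quadratic", f) for f in factors]
    return ModelSpec(tuple(factors), tuple(terms))


@dataclass
class DesignMatrix:
    """Coded design points with the model they were optimized for."""

    points: np.ndarray  # n_runs x k, entries in [-1, 1]
    model: ModelSpec
    criterion_value: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != len(self.model.factors):
            raise ValueError("points shape does not match model factors")
        if (np.abs(self.points) > 1 + 1e-12).any():
            raise ValueError("coded entries must lie in [-1, 1]")


def expand_model_matrix(points: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Evaluate every model term at every point (n x p model matrix)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != len(model.factors):
        raise ValueError(
            f"points have {points.shape[1] if points.ndim == 2 else '?'} columns, "
            f"model has {len(model.factors)} factors"
        )
    E = model.exponents()
    # column j = prod_f points[:, f] ** E[j, f]; 0**0 == 1 covers the intercept
    return np.prod(points[:, None, :] ** E[None, :, :], axis=2)


def moments_matrix(model: ModelSpec) -> np.ndarray:
    """Exact moments matrix under the uniform measure on [-1, 1]^k.

    M[a, b] = E[term_a * term_b] = prod_f E[x^(e_a + e_b)] with
    E[x^e] = 0 for odd e and 1/(e+1) for even e.
    """
    E = model.exponents()
    p = model.n_terms
    M = np.empty((p, p))
    for a in range(p):
        for b in range(a, p):
            e = E[a] + E[b]
            if (e % 2).any():
                val = 0.0
            else:
                val = float(np.prod(1.0 / (e + 1.0)))
            M[a, b] = M[b, a] = val
    return M


def i_criterion(design: DesignMatrix) -> float:
    """Average prediction variance trace[(X'X)^{-1} M]; lower is better."""
    X = expand_model_matrix(design.points, design.model)
    M = moments_matrix(design.model)
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    if rank < design.model.n_terms:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        names = [design.model.terms[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"singular information matrix; deficient terms: {names}"
        )
    return float(np.trace(np.linalg.solve(XtX, M)))


class _ExchangeState:
    """Incremental I-criterion bookkeeping for coordinate exchange.

    Maintains A = (X'X)^{-1} and t = trace(A M). Replacing row u by row v
    is a rank-one update followed by a rank-one downdate, each of which
    changes the trace by a closed-form amount computable from matvecs.
    """

    def __init__(self, X: np.ndarray, M: np.ndarray):
        self.M = M
        self.X = X.copy()
        self.ok = self._refactor()

    def _refactor(self) -> bool:
        XtX = self.X.T @ self.X
        try:
            np.linalg.cholesky(XtX)
            self.A = np.linalg.solve(XtX, np.eye(XtX.shape[0]))
        except np.linalg.LinAlgError:
            return False
        self.A = 0.5 * (self.A + self.A.T)
        self.trace = float(np.sum(self.A * self.M))
        return True

    def try_replace(self, u: np.ndarray, v: np.ndarray) -> float | None:
        """Criterion after replacing model-matrix row u by v, or None if singular."""
        A, M = self.A, self.M
        q = A @ v
        a = 1.0 + v @ q
        if a <= 1e-12:
            return None
        t1 = self.trace - (q @ M @ q) / a
        p = A @ u
        r = p - q * (v @ p) / a          # A1 u
        d = 1.0 - (u @ p - (v @ p) ** 2 / a)  # 1 - u' A1 u
        if d <= 1e-12:
            return None
        return t1 + (r @ M @ r) / d

    def replace(self, i: int, v: np.ndarray) -> None:
        """Commit the replacement of row i by v."""
        u = self.X[i].copy()
        A, M = self.A, self.M
        q = A @ v
        a = 1.0 + v @ q
        A1 = A - np.outer(q, q) / a
        r = A1 @ u
        d = 1.0 - u @ r
        self.A = A1 + np.outer(r, r) / d
        self.A = 0.5 * (self.A + self.A.T)
        self.X[i] = v
        self.trace = float(np.sum(self.A * self.M))


DEFAULT_LEVELS = (-1.0, -0.5, 0.0, 0.5, 1.0)


def coordinate_exchange(
    n_runs: int,
    model: ModelSpec,
    n_starts: int = 10,
    candidate_levels: tuple[float, ...] = DEFAULT_LEVELS,
    tol: float = 1e-9,
    seed: int | None = None,
    max_sweeps: int = 50,
    refine: bool = False,
) -> DesignMatrix:
    """Construct an I-optimal design by multi-start coordinate exchange.

    From each random start (points drawn from the candidate grid),
    repeatedly sweeps every (run, factor) coordinate and accepts the
    candidate level that lowers the criterion; stops when a full sweep
    improves by less than `tol`. With ``refine=True`` a golden-section
    line search over [-1, 1] polishes each winning coordinate. Returns the
    best design over starts; the criterion is non-increasing across
    accepted exchanges.
    """
    k = len(model.factors)
    p = model.n_terms
    if n_runs < p:
        raise ValueError(f"n_runs={n_runs} is below the {p} model terms")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    M = moments_matrix(model)
    levels = np.asarray(candidate_levels, dtype=float)

    best_points, best_crit = None, np.inf
    for _ in range(n_starts):
        # draw non-singular starting designs
        for _attempt in range(100):
            pts = rng.choice(levels, size=(n_runs, k))
            X = expand_model_matrix(pts, model)
            state = _ExchangeState(X, M)
            if state.ok:
                break
        else:
            continue
        for _sweep in range(max_sweeps):
            start_trace = state.trace
            for i in range(n_runs):
                for f in range(k):
                    u = state.X[i].copy()
                    point = pts[i].copy()
                    current = state.trace

                    def row_at(level: float) -> np.ndarray:
                        point[f] = level
                        return expand_model_matrix(point[None, :], model)[0]

                    best_level, best_val = pts[i, f], current
                    for level in levels:
                        if level == pts[i, f]:
                            continue
                        val = state.try_replace(u, row_at(level))
                        if val is not None and val < best_val - 1e-15:
                            best_level, best_val = level, val
                    if refine:
                        from scipy.optimize import minimize_scalar

                        res = minimize_scalar(
                            lambda lv: (
                                state.try_replace(u, row_at(lv)) or np.inf
                            ),
                            bounds=(-1.0, 1.0),
                            method="bounded",
                            options={"xatol": 1e-6},
                        )
                        if res.fun < best_val - 1e-15:
                            best_level, best_val = float(res.x), float(res.fun)
                    if best_val < current - 1e-15:
                        pts[i, f] = best_level
                        state.replace(i, row_at(best_level))
            state._refactor()  # guard against drift
            if start_trace - state.trace < tol:
                break
        if state.trace < best_crit:
            best_points, best_crit = pts.copy(), state.trace

    if best_points is None:
        raise np.linalg.LinAlgError("no non-singular starting design found")
    return DesignMatrix(points=best_points, model=model, criterion_value=best_crit)


def decode(
    design: DesignMatrix,
    specs: list[ComponentSpec],
    n_replicates: int = 4,
) -> pd.DataFrame:
    """Map coded points to physical concentrations and expand replicates.

    Coded x in [-1, 1] maps affinely onto [low, high]; each run is
    duplicated `n_replicates` times with a replicate index.
    """
    if len(specs) != len(design.model.factors):
        raise ValueError(
            f"{len(specs)} component specs for {len(design.model.factors)} factors"
        )
    lows = np.array([s.low for s in specs])
    highs = np.array([s.high for s in specs])
    phys = lows + (design.points + 1.0) / 2.0 * (highs - lows)
    rows = []
    for run in range(design.points.shape[0]):
        for rep in range(1, n_replicates + 1):
            row = {"run_id": run + 1, "replicate": rep}
            row.update({s.name: phys[run, j] for j, s in enumerate(specs)})
            rows.append(row)
    return pd.DataFrame(rows)
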