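"""PLS path modeling (PLS-PM) with reflective blocks.

Manifest variables are grouped into blocks, each measuring one latent
variable (mode A / reflective). Latent scores are estimated by the
classical alternating algorithm: an outer approximation (scores as
weighted sums of their block's manifests) and an inner approximation
(scores as combinations of connected latents under the centroid,
factorial or path scheme) are iterated until the outer weights
stabilize. Afterwards:

* loadings: correlations between manifests and their latent, signs
  oriented so each block's loading sum is positive;
* path coefficients: OLS of every endogenous latent on its predecessors;
* Dillon-Goldstein's rho per block (composite reliability; a block is
  judged unidimensional when rho > 0.70);
* goodness of fit: sqrt(mean communality of multi-manifest blocks x
  mean R^2 of endogenous blocks).
"""

from __future__ import annotations

from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BlockSpec:
    name: str
    manifest_variables: tuple[str, ...]
    mode: str = "reflective"

    def __post_init__(self) -> None:
        if len(self.manifest_variables) < 1:
            raise ValueError(f"block {self.name!r} needs >= 1 manifest variable")
        if self.mode != "reflective":
            raise ValueError("only reflective (mode A) blocks are supported")


def default_blocks() -> list[BlockSpec]:
    """Five-block measurement model for the extender study."""
    return [
        BlockSpec("basic_compound", ("water", "tris", "fructose")),
        BlockSpec("extracellular_protectant", ("egg_yolk", "milk")),
        BlockSpec("cpa_osmoregulator", ("glycerol", "ethylene_glycol", "trehalose", "clc")),
        BlockSpec("antioxidant_class", ("glutathione", "melatonin", "ngf")),
        BlockSpec("motility", ("tm", "pm")),
    ]


def default_path_matrix(blocks: list[BlockSpec]) -> pd.DataFrame:
    """Default structural model (entry [i, j] = 1: block j predicts block i).

    Basic compound and extracellular protectant are exogenous;
    CPA/osmoregulator <- basic compound + extracellular protectant;
    antioxidant class <- extracellular protectant + CPA/osmoregulator;
    motility <- all four. Configuration, not dogma.
    """
    names = [b.name for b in blocks]
    P = pd.DataFrame(0, index=names, columns=names, dtype=int)
    edges = [
        ("cpa_osmoregulator", "basic_compound"),
        ("cpa_osmoregulator", "extracellular_protectant"),
        ("antioxidant_class", "extracellular_protectant"),
        ("antioxidant_class", "cpa_osmoregulator"),
        ("motility", "basic_compound"),
        ("motility", "extracellular_protectant"),
        ("motility", "cpa_osmoregulator"),
        ("motility", "antioxidant_class"),
    ]
    for target, source in edges:
        if target in P.index and source in P.columns:
            P.loc[target, source] = 1
    return P


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant manifest column")
    return (X - X.mean(axis=0)) / sd


def dg_rho(block_data: np.ndarray | pd.DataFrame) -> float:
    """Dillon-Goldstein's rho (composite reliability) of a reflective block.

    rho = (sum lambda_i)^2 / [(sum lambda_i)^2 + sum (1 - lambda_i^2)]
    with lambda_i the correlation of each standardized manifest with the
    block's first principal component, signs aligned so sum lambda_i >= 0.
    Single-variable blocks return 1 by convention.
    """
    X = np.asarray(block_data, dtype=float)
    if X.ndim == 1 or X.shape[1] == 1:
        return 1.0
    Z = _standardize(X)
    n = Z.shape[0]
    U, S, Vt = np.linalg.svd(Z / np.sqrt(n - 1), full_matrices=False)
    pc1 = Z @ Vt[0]
    lam = np.array([np.corrcoef(Z[:, j], pc1)[0, 1] for j in range(Z.shape[1])])
    if lam.sum() < 0:
        lam = -lam
    s = lam.sum()
    return float(s**2 / (s**2 + np.sum(1.0 - lam**2)))


class PLSPathModel:
    """sklearn-style PLS path model estimator.

    Parameters
    ----------
    blocks : list of BlockSpec
    path_matrix : DataFrame
        Square 0/1 matrix over block names; [i, j] = 1 means block j is a
        predictor of block i. Must be acyclic.
    scheme : {"centroid", "factorial", "path"}
        Inner weighting scheme.
    tol, max_iter : convergence controls on the outer weights.

    Attributes (after fit)
    ----------------------
    latent_scores_ : DataFrame (n x blocks), unit variance.
    outer_weights_, loadings_ : per manifest variable.
    dg_rho_ : per block. path_coefficients_ : DataFrame (endogenous x
    predecessors). r2_ : per endogenous block. communality_ : per block.
    gof_ : scalar goodness of fit.
    """

    def __init__(
        self,
        blocks: list[BlockSpec] | None = None,
        path_matrix: pd.DataFrame | None = None,
        scheme: str = "centroid",
        tol: float = 1e-9,
        max_iter: int = 500,
    ):
        self.blocks = blocks
        self.path_matrix = path_matrix
        self.scheme = scheme
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "blocks": self.blocks,
            "path_matrix": self.path_matrix,
            "scheme": self.scheme,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "PLSPathModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _validate(self, table: pd.DataFrame):
        blocks = self.blocks if self.blocks is not None else default_blocks()
        P = (
            self.path_matrix
            if self.path_matrix is not None
            else default_path_matrix(blocks)
        )
        names = [b.name for b in blocks]
        if list(P.index) != names or list(P.columns) != names:
            P = P.reindex(index=names, columns=names, fill_value=0)
        if self.scheme not in ("centroid", "factorial", "path"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        ts = TopologicalSorter(
            {i: [j for j in names if P.loc[i, j]] for i in names}
        )
        try:
            ts.prepare()
        except CycleError as e:
            raise ValueError(f"path matrix is cyclic: {e}") from None
        seen: set[str] = set()
        for b in blocks:
            dup = seen & set(b.manifest_variables)
            if dup:
                raise ValueError(f"manifests in multiple blocks: {sorted(dup)}")
            seen |= set(b.manifest_variables)
            for v in b.manifest_variables:
                if v not in table.columns:
                    raise ValueError(f"block {b.name!r}: missing column {v!r}")
        return blocks, P

    def fit(self, table: pd.DataFrame, y=None) -> "PLSPathModel":
        blocks, P = self._validate(table)
        names = [b.name for b in blocks]
        n = len(table)
        X = {
            b.name: _standardize(table[list(b.manifest_variables)].to_numpy(float))
            for b in blocks
        }
        adj = (P.to_numpy() + P.to_numpy().T) > 0  # connectivity, symmetric
        w = {b.name: np.ones(len(b.manifest_variables)) for b in blocks}

        def scores(weights):
            Y = np.column_stack([X[nm] @ weights[nm] for nm in names])
            return Y / Y.std(axis=0, ddof=1)

        Y = scores(w)
        for _it in range(self.max_iter):
            R = np.corrcoef(Y, rowvar=False)
            if len(names) == 1:
                R = np.array([[1.0]])
            Z = np.zeros_like(Y)
            for i, nm in enumerate(names):
                neigh = np.nonzero(adj[i])[0]
                if len(neigh) == 0:
                    Z[:, i] = Y[:, i]
                    continue
                if self.scheme == "centroid":
                    e = np.sign(R[i, neigh])
                elif self.scheme == "factorial":
                    e = R[i, neigh]
                else:  # path scheme
                    preds = [j for j in neigh if P.iloc[i, j] == 1]
                    succ = [j for j in neigh if P.iloc[j, i] == 1]
                    e = np.zeros(len(neigh))
                    if preds:
                        coef, *_ = np.linalg.lstsq(Y[:, preds], Y[:, i], rcond=None)
                        for jj, j in enumerate(preds):
                            e[list(neigh).index(j)] = coef[jj]
                    for j in succ:
                        e[list(neigh).index(j)] = R[i, j]
                Z[:, i] = Y[:, neigh] @ e
            new_w = {}
            for i, b in enumerate(blocks):
                zi = Z[:, i]
                wi = X[b.name].T @ zi / n  # mode A
                new_w[b.name] = wi
            Ynew = scores(new_w)
            delta = max(
                np.max(np.abs(_unit(new_w[nm]) - _unit(w[nm]))) for nm in names
            )
            w, Y = new_w, Ynew
            if delta < self.tol:
                break
        else:
            raise RuntimeError(
                f"PLS-PM did not converge in {self.max_iter} iterations"
            )

        # sign convention: per-block loading sum positive
        loadings = {}
        for i, b in enumerate(blocks):
            lam = np.array(
                [np.corrcoef(X[b.name][:, j], Y[:, i])[0, 1]
                 for j in range(X[b.name].shape[1])]
            )
            if lam.sum() < 0:
                Y[:, i] = -Y[:, i]
                w[b.name] = -w[b.name]
                lam = -lam
            loadings[b.name] = lam

        self.latent_scores_ = pd.DataFrame(Y, columns=names, index=table.index)
        self.outer_weights_ = {
            b.name: dict(zip(b.manifest_variables, _unit(w[b.name])))
            for b in blocks
        }
        self.loadings_ = {
            b.name: dict(zip(b.manifest_variables, loadings[b.name]))
            for b in blocks
        }
        self.dg_rho_ = {
            b.name: dg_rho(table[list(b.manifest_variables)]) for b in blocks
        }
        self.unidimensional_ = {k: v > 0.70 for k, v in self.dg_rho_.items()}

        paths = pd.DataFrame(np.nan, index=names, columns=names)
        r2 = {}
        for i, nm in enumerate(names):
            preds = [j for j, pn in enumerate(names) if P.loc[nm, pn] == 1]
            if not preds:
                continue
            Xp = Y[:, preds]
            coef, *_ = np.linalg.lstsq(Xp, Y[:, i], rcond=None)
            fitted = Xp @ coef
            r2[nm] = float(1.0 - ((Y[:, i] - fitted) ** 2).sum() / ((Y[:, i]) ** 2).sum())
            for jj, j in enumerate(preds):
                paths.loc[nm, names[j]] = coef[jj]
        self.path_coefficients_ = paths
        self.r2_ = r2
        self.communality_ = {
            b.name: float(np.mean(loadings[b.name] ** 2)) for b in blocks
        }
        multi = [b.name for b in blocks if len(b.manifest_variables) > 1]
        mean_comm = float(np.mean([self.communality_[nm] for nm in multi])) if multi else 1.0
        mean_r2 = float(np.mean(list(r2.values()))) if r2 else 0.0
        self.gof_ = float(np.sqrt(mean_comm * mean_r2))
        self.block_names_ = names
        return self


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def fit_plspm(
    table: pd.DataFrame,
    blocks: list[BlockSpec] | None = None,
    path_matrix: pd.DataFrame | None = None,
    scheme: str = "centroid",
    tol: float = 1e-9,
    max_iter: int = 500,
) -> PLSPathModel:
    return PLSPathModel(
        blocks=blocks, path_matrix=path_matrix, scheme=scheme, tol=tol,
        max_iter=max_iter,
    ).fit(table)


def endogenous_summary(model: PLSPathModel) -> pd.DataFrame:
    """Endogenous blocks ordered by R^2 (descending), with the
    conventional R^2 > 0.2 reporting flag."""
    rows = [
        {"block": nm, "r2": r, "r2_above_0.2": r > 0.2}
        for nm, r in model.r2_.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("r2", ascending=False)
        .reset_index(drop=True)
    )
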