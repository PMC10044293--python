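"""Multiple factor analysis (MFA) over named variable groups.

MFA balances several groups of variables in one global PCA: each active
group's standardized columns are weighted by 1/sqrt(lambda1), the inverse
square root of the group's leading PCA eigenvalue, so that every group's
first partial axis carries unit inertia and no single group dominates the
global dimensions. A supplementary categorical column (here: bulls) is
projected afterwards as barycenters of its rows and does not influence
the axes.

Default grouping of the 14 study variables:
basic compound {water, tris, fructose}; extracellular protectant
{egg_yolk, milk}; CPA {glycerol, ethylene_glycol}; osmoregulator
{trehalose, clc}; antioxidant class {glutathione, melatonin, ngf};
motility {tm, pm}. Membership is configuration, not ground truth — the
merged "CPA and osmoregulator" variant used for path modeling is equally
valid here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VariableGroup:
    name: str
    variables: tuple[str, ...]
    role: str = "active"  # "active" | "supplementary_categorical"

    def __post_init__(self) -> None:
        if self.role not in ("active", "supplementary_categorical"):
            raise ValueError(f"unknown group role {self.role!r}")
        if self.role == "active" and len(self.variables) < 1:
            raise ValueError(f"active group {self.name!r} needs >= 1 variable")


def default_groups() -> list[VariableGroup]:
    return [
        VariableGroup("basic_compound", ("water", "tris", "fructose")),
        VariableGroup("extracellular_protectant", ("egg_yolk", "milk")),
        VariableGroup("cpa", ("glycerol", "ethylene_glycol")),
        VariableGroup("osmoregulator", ("trehalose", "clc")),
        VariableGroup("antioxidant_class", ("glutathione", "melatonin", "ngf")),
        VariableGroup("motility", ("tm", "pm")),
        VariableGroup("bulls", ("bull_id",), role="supplementary_categorical"),
    ]


class MFA:
    """sklearn-style MFA transformer.

    Parameters
    ----------
    groups : list of VariableGroup
        Active groups define the analysis; at most one supplementary
        categorical group is projected afterwards.
    n_dims : int
        Number of global dimensions to retain.

    Attributes (after fit)
    ----------------------
    eigenvalues_ : global PCA eigenvalues (non-increasing).
    group_weights_ : {group: 1/lambda1}.
    variable_coordinates_ : DataFrame (variables x dims), correlation of
        each standardized variable with each global dimension.
    group_contributions_ : DataFrame (groups x dims), % of dimension
        inertia carried by each active group (columns sum to 100).
    row_coordinates_ : (n x dims) global row scores.
    supplementary_coordinates_ : DataFrame (levels x dims) or None.
    """

    def __init__(self, groups: list[VariableGroup], n_dims: int = 5):
        self.groups = groups
        self.n_dims = n_dims

    def get_params(self, deep: bool = True) -> dict:
        return {"groups": self.groups, "n_dims": self.n_dims}

    def set_params(self, **params) -> "MFA":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, table: pd.DataFrame, y=None) -> "MFA":
        active = [g for g in self.groups if g.role == "active"]
        supp = [g for g in self.groups if g.role == "supplementary_categorical"]
        if len(active) < 1:
            raise ValueError("need at least one active group")
        if len(active) == 1:
            import warnings

            warnings.warn("single active group: MFA degenerates to a PCA of that group")
        seen: set[str] = set()
        for g in active:
            dup = seen & set(g.variables)
            if dup:
                raise ValueError(f"variables in multiple groups: {sorted(dup)}")
            seen |= set(g.variables)
            for v in g.variables:
                if v not in table.columns:
                    raise ValueError(f"group {g.name!r} references missing column {v!r}")

        n = len(table)
        blocks, weights, var_names, var_group = [], {}, [], []
        for g in active:
            Xg = table[list(g.variables)].to_numpy(float)
            mean = Xg.mean(axis=0)
            sd = Xg.std(axis=0, ddof=0)
            if (sd == 0).any():
                bad = [v for v, s in zip(g.variables, sd) if s == 0]
                raise ValueError(f"constant column(s) {bad} in group {g.name!r}")
            Zg = (Xg - mean) / sd
            lam1 = np.linalg.svd(Zg / np.sqrt(n), compute_uv=False)[0] ** 2
            weights[g.name] = 1.0 / lam1
            blocks.append(Zg / np.sqrt(lam1))
            var_names += list(g.variables)
            var_group += [g.name] * len(g.variables)

        Z = np.hstack(blocks)
        U, S, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
        eig = S**2
        dims = min(self.n_dims, (eig > 1e-12).sum())
        self.eigenvalues_ = eig
        self.group_weights_ = weights
        self.row_coordinates_ = np.sqrt(n) * U[:, :dims] * S[:dims]
        V = Vt.T[:, :dims]

        # variable coordinate = corr(standardized var, dimension)
        Zstd = np.hstack(
            [b * np.sqrt(lam) for b, lam in zip(blocks, [1.0 / weights[g.name] for g in active])]
        )
        F = self.row_coordinates_
        coords = np.empty((Z.shape[1], dims))
        for j in range(Z.shape[1]):
            for d in range(dims):
                coords[j, d] = np.corrcoef(Zstd[:, j], F[:, d])[0, 1]
        self.variable_coordinates_ = pd.DataFrame(
            coords, index=var_names, columns=[f"dim{d+1}" for d in range(dims)]
        )

        contrib = 100.0 * V**2  # columns of V are unit vectors
        cdf = pd.DataFrame(
            contrib, index=var_names, columns=[f"dim{d+1}" for d in range(dims)]
        )
        cdf["group"] = var_group
        self.variable_contributions_ = cdf.drop(columns="group")
        self.group_contributions_ = cdf.groupby("group", sort=False).sum()

        self.total_inertia_ = float(eig.sum())
        self.var_names_ = var_names

        self.supplementary_coordinates_ = None
        if supp:
            col = supp[0].variables[0]
            self.supplementary_coordinates_ = self.project_supplementary(table, col)
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Row coordinates of fitted data (fit-transform semantics)."""
        return self.row_coordinates_

    def project_supplementary(self, table: pd.DataFrame, column: str) -> pd.DataFrame:
        """Barycenter of each categorical level in global row space."""
        if column not in table.columns:
            raise ValueError(f"unknown column {column!r}")
        F = pd.DataFrame(
            self.row_coordinates_,
            columns=[f"dim{d+1}" for d in range(self.row_coordinates_.shape[1])],
        )
        F[column] = table[column].to_numpy()
        return F.groupby(column, sort=True).mean()


def fit_mfa(
    table: pd.DataFrame, groups: list[VariableGroup], n_dims: int = 5
) -> MFA:
    return MFA(groups=groups, n_dims=n_dims).fit(table)


def group_contributions(result: MFA) -> pd.DataFrame:
    """Active-group contributions (%) per dimension; columns sum to 100."""
    return result.group_contributions_


def supplementary_projection(result: MFA, table: pd.DataFrame, column: str) -> pd.DataFrame:
    """Project a categorical column's levels as barycenters of their rows."""
    return result.project_supplementary(table, column)
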