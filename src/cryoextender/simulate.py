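"""Synthetic experiment-table generator.

Emulates the statistical structure of the extender study so every
downstream stage (ANOVA, PLS, clustering, Monte Carlo, MFA, PLS-PM) can be
exercised without the original measurements: 122 design runs x 4
replicates = 488 media over the 12 published component ranges, a
linear-in-concentration ground-truth response surface anchored on the
published prediction-equation coefficients, additive per-bull intercept
shifts for 43 bulls in 4 cohorts, and Gaussian residual noise whose SD is
the square root of the published residual mean square.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .components import COMPONENT_ORDER, ComponentSpec, default_component_specs

logger = logging.getLogger(__name__)

RESPONSES = ("tm", "pm")


@dataclass
class TrueModel:
    """Ground-truth response surface for one motility response.

    response = intercept + sum(main_coefs * conc)
             + sum(interaction_coefs * conc_i * conc_j)
             + bull_effect + N(0, noise_sd), clipped to [0, 100].
    """

    intercept: float
    main_coefs: dict[str, float]
    response_name: str = "tm"
    interaction_coefs: dict[tuple[str, str], float] = field(default_factory=dict)
    bull_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        known = set(COMPONENT_ORDER)
        unknown = set(self.main_coefs) - known
        if unknown:
            raise ValueError(f"unknown components in main_coefs: {sorted(unknown)}")
        canon: dict[tuple[str, str], float] = {}
        for (a, b), v in self.interaction_coefs.items():
            if a == b:
                raise ValueError(f"interaction pair must be distinct: {(a, b)}")
            if a not in known or b not in known:
                raise ValueError(f"unknown components in interaction {(a, b)}")
            canon[tuple(sorted((a, b)))] = v  # type: ignore[index]
        self.interaction_coefs = canon
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def linear_predictor(self, concentrations: pd.DataFrame) -> np.ndarray:
        """Deterministic part of the surface (no bull effect, no noise)."""
        eta = np.full(len(concentrations), self.intercept, dtype=float)
        for name, coef in self.main_coefs.items():
            eta += coef * concentrations[name].to_numpy(dtype=float)
        for (a, b), coef in self.interaction_coefs.items():
            eta += coef * (
                concentrations[a].to_numpy(dtype=float)
                * concentrations[b].to_numpy(dtype=float)
            )
        return eta


def default_true_model(
    response_name: str,
    interactions: dict[tuple[str, str], float] | None = None,
    bull_effects: dict[str, float] | None = None,
    noise_sd: float | None = None,
) -> TrueModel:
    """Ground-truth model anchored on the published prediction equation.

    Parameters
    ----------
    response_name : {"tm", "pm"}
        Total or progressive motility.
    interactions : dict, optional
        Two-way interaction coefficients. Off by default (the published
        equations are main-effects only). :data:`reference.SIGNIFICANT_INTERACTIONS`
        lists the pairs found significant in the ANOVA; their magnitudes
        were not published so they are user-supplied.
    noise_sd : float, optional
        Residual SD; defaults to sqrt of the published residual mean
        square (TM: sqrt(14.49) ~ 3.81, PM: sqrt(13.59) ~ 3.69).
    """
    key = response_name.lower()
    if key not in RESPONSES:
        raise ValueError(f"unknown response {response_name!r}; expected 'tm' or 'pm'")
    if noise_sd is None:
        noise_sd = math.sqrt(reference.RESIDUAL_MEAN_SQUARE[key])
    return TrueModel(
        intercept=reference.INTERCEPT[key],
        main_coefs=dict(reference.COEFFICIENTS[key]),
        response_name=key,
        interaction_coefs=dict(interactions or {}),
        bull_effects=dict(bull_effects or {}),
        noise_sd=noise_sd,
    )


def simulate_bull_effects(
    group_sizes: tuple[int, ...] = reference.BULL_COHORT_SIZES,
    between_group_sd: float = 5.0,
    within_group_sd: float = 2.0,
    seed: int | None = None,
) -> dict[str, float]:
    """Draw per-bull intercept shifts for cohorts of bulls.

    Each cohort receives a mean shift ~ N(0, between_group_sd); each bull
    adds an individual deviation ~ N(0, within_group_sd). The default
    cohort sizes (28, 10, 3, 1) are the published cluster sizes; they sum
    to 42 although 43 bulls entered the study — the published numbers are
    kept as-is (see :data:`reference.BULL_COHORT_SIZES`).

    Returns a mapping bull_id -> shift in % motility, bull ids "B01"... in
    cohort order.
    """
    if any(g <= 0 for g in group_sizes):
        raise ValueError("group sizes must be positive")
    if between_group_sd < 0 or within_group_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    effects: dict[str, float] = {}
    bull = 0
    for g, size in enumerate(group_sizes):
        mean = rng.normal(0.0, between_group_sd) if between_group_sd > 0 else 0.0
        for _ in range(size):
            bull += 1
            dev = rng.normal(0.0, within_group_sd) if within_group_sd > 0 else 0.0
            effects[f"B{bull:02d}"] = mean + dev
    return effects


def assign_bulls(
    design: pd.DataFrame,
    bull_ids: list[str],
    seed: int | None = None,
) -> pd.DataFrame:
    """Assign bulls to rows: each run's replicates go to distinct bulls.

    Mirrors the collection protocol in which each day's ejaculates were
    split across the day's extenders: within a run, the (default 4)
    replicates are served by distinct bulls drawn round-robin from a
    seeded permutation of the pool.
    """
    rng = np.random.default_rng(seed)
    pool = [bull_ids[i] for i in rng.permutation(len(bull_ids))]
    out = design.copy()
    assignment = []
    cursor = 0
    for _, grp in out.groupby("run_id", sort=True):
        n_rep = len(grp)
        if n_rep > len(pool):
            raise ValueError("more replicates per run than bulls in the pool")
        for r in range(n_rep):
            assignment.append(pool[(cursor + r) % len(pool)])
        cursor = (cursor + n_rep) % len(pool)
    out["bull_id"] = assignment
    return out


def _validate_concentrations(design: pd.DataFrame, specs: list[ComponentSpec]) -> None:
    for spec in specs:
        if spec.name not in design.columns:
            raise ValueError(f"design is missing component column {spec.name!r}")
        col = design[spec.name].to_numpy(dtype=float)
        tol = 1e-9 * max(1.0, abs(spec.high))
        if (col < spec.low - tol).any() or (col > spec.high + tol).any():
            raise ValueError(f"concentrations of {spec.name!r} outside [{spec.low}, {spec.high}]")


def simulate_responses(
    design: pd.DataFrame,
    tm_model: TrueModel,
    pm_model: TrueModel,
    seed: int | None = None,
    specs: list[ComponentSpec] | None = None,
) -> pd.DataFrame:
    """Attach simulated tm/pm responses to a design table.

    `design` needs the 12 component columns plus run_id, replicate and
    (if the models carry bull effects) bull_id. Responses are the linear
    predictor + bull effect + N(0, noise_sd), clipped to [0, 100];
    clipping events are counted and logged.
    """
    specs = specs if specs is not None else default_component_specs()
    _validate_concentrations(design, specs)
    rng = np.random.default_rng(seed)
    out = design.copy()
    for model in (tm_model, pm_model):
        eta = model.linear_predictor(out)
        if model.bull_effects:
            missing = set(out["bull_id"]) - set(model.bull_effects)
            if missing:
                raise ValueError(f"bulls without effects: {sorted(missing)}")
            eta = eta + out["bull_id"].map(model.bull_effects).to_numpy(dtype=float)
        if model.noise_sd > 0:
            eta = eta + rng.normal(0.0, model.noise_sd, size=len(out))
        clipped = int(((eta < 0) | (eta > 100)).sum())
        if clipped:
            logger.info("%s: clipped %d of %d responses to [0, 100]",
                        model.response_name, clipped, len(out))
        out[model.response_name] = np.clip(eta, 0.0, 100.0)
    return out


def generate_experiment_table(
    n_runs: int = 122,
    n_replicates: int = 4,
    seed: int = 0,
    noise_sd: float | None = None,
    bull_effects: bool = True,
    between_group_sd: float = 5.0,
    within_group_sd: float = 2.0,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-call generator for a study-structured experiment table.

    Concentrations are drawn uniformly over each component's range (a fast
    stand-in for the optimal design; use :mod:`cryoextender.design` +
    :func:`simulate_responses` to simulate on an I-optimal design), bulls
    assigned round-robin, responses simulated from the published-equation
    ground truth. Fully reproducible from `seed`.
    """
    rng = np.random.default_rng(seed)
    specs = default_component_specs()
    if design is None:
        points = rng.uniform(size=(n_runs, len(specs)))
        rows = []
        for run in range(n_runs):
            for rep in range(1, n_replicates + 1):
                row = {"run_id": run + 1, "replicate": rep}
                for j, spec in enumerate(specs):
                    row[spec.name] = spec.low + points[run, j] * spec.range
                rows.append(row)
        design = pd.DataFrame(rows)
    effects = (
        simulate_bull_effects(
            between_group_sd=between_group_sd,
            within_group_sd=within_group_sd,
            seed=rng.integers(2**31),
        )
        if bull_effects
        else {}
    )
    pool = list(effects) or [
        f"B{i:02d}" for i in range(1, sum(reference.BULL_COHORT_SIZES) + 1)
    ]
    design = assign_bulls(design, pool, seed=rng.integers(2**31))
    tm = default_true_model("tm", bull_effects=effects, noise_sd=noise_sd)
    pm = default_true_model("pm", bull_effects=effects, noise_sd=noise_sd)
    return simulate_responses(design, tm, pm, seed=rng.integers(2**31), specs=specs)
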