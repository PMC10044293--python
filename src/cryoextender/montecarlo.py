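"""Monte Carlo formulation screening and sensitivity analysis.

Candidate extender formulations are drawn from independent truncated
normal distributions (one per component, truncated to the physical
range), predicted motility is evaluated with the linear PLS prediction
equation, and three summaries are produced: a correlation/contribution
sensitivity table, the top-k formulations, and per-component moments of
the best-performing draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .components import ComponentSpec, default_component_specs


@dataclass
class ComponentDistribution:
    name: str
    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        if self.low >= self.high:
            raise ValueError(f"{self.name}: degenerate truncation bounds")


@dataclass
class SimulationSpec:
    distributions: list[ComponentDistribution]
    n_draws: int = 10_000
    seed: int | None = None

    @property
    def component_names(self) -> list[str]:
        return [d.name for d in self.distributions]


def default_simulation_spec(
    specs: list[ComponentSpec] | None = None,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> SimulationSpec:
    """Default per-component normals: mean = range midpoint, sd = range/6,
    truncated to the physical range (so ~99.7% of the untruncated mass
    lies inside the bounds)."""
    specs = specs if specs is not None else default_component_specs()
    dists = [
        ComponentDistribution(
            name=s.name, mean=s.midpoint, sd=s.range / 6.0, low=s.low, high=s.high
        )
        for s in specs
    ]
    return SimulationSpec(distributions=dists, n_draws=n_draws, seed=seed)


def simulate_formulations(spec: SimulationSpec) -> pd.DataFrame:
    """Draw n_draws candidate formulations (inverse-CDF truncated normals).

    A component with sd = 0 is held constant at its mean.
    """
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for d in spec.distributions:
        if d.sd == 0:
            cols[d.name] = np.full(spec.n_draws, d.mean)
        else:
            a = (d.low - d.mean) / d.sd
            b = (d.high - d.mean) / d.sd
            cols[d.name] = stats.truncnorm.rvs(
                a, b, loc=d.mean, scale=d.sd, size=spec.n_draws, random_state=rng
            )
    return pd.DataFrame(cols)


def sensitivity(
    formulations: pd.DataFrame, predictions: np.ndarray | dict[str, np.ndarray]
) -> pd.DataFrame:
    """Correlation and normalized squared-correlation contributions.

    For each component j and response: r_j = Pearson correlation between
    the component's draws and the predicted response, and

        contribution_j (%) = 100 * r_j^2 / sum_k r_k^2.

    Contributions sum to 100 per response; the correlation column keeps
    the sign of r_j.
    """
    if not isinstance(predictions, dict):
        predictions = {"response": np.asarray(predictions, dtype=float)}
    out: dict[str, list[float]] = {}
    components = list(formulations.columns)
    for resp, pred in predictions.items():
        pred = np.asarray(pred, dtype=float)
        if len(pred) != len(formulations):
            raise ValueError("predictions must align with formulation rows")
        rs = []
        for c in components:
            col = formulations[c].to_numpy(float)
            if np.std(col) == 0:
                raise ValueError(f"component {c!r} has zero variance")
            rs.append(float(stats.pearsonr(col, pred)[0]))
        rs = np.asarray(rs)
        total = float((rs**2).sum())
        out[f"correlation_{resp}"] = rs.tolist()
        out[f"contribution_{resp}"] = (100.0 * rs**2 / total).tolist()
    return pd.DataFrame(out, index=components)


def contributions_from_correlations(correlations: dict[str, float]) -> dict[str, float]:
    """Contribution column implied by a correlation column alone."""
    r2 = {k: v**2 for k, v in correlations.items()}
    total = sum(r2.values())
    return {k: 100.0 * v / total for k, v in r2.items()}


def top_k(
    formulations: pd.DataFrame, predictions: np.ndarray, k: int = 10,
    response_name: str = "predicted",
) -> pd.DataFrame:
    """The k best-predicted formulations, ascending by prediction
    (the best candidate is the last row)."""
    pred = np.asarray(predictions, dtype=float)
    if k > len(pred):
        raise ValueError(f"k={k} exceeds the {len(pred)} draws")
    idx = np.argsort(pred, kind="stable")[-k:]
    out = formulations.iloc[idx].copy()
    out[response_name] = pred[idx]
    return out.reset_index(drop=True)


def distribution_summary(selection: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and moment-based skewness per component of selected draws.

    A positive skew of a component among top-performing draws suggests
    lower concentrations suffice; negative skew suggests headroom above.
    Constant components report sd 0 and skewness 0 with a flag.
    """
    if len(selection) < 3:
        raise ValueError("need at least 3 rows to summarize")
    rows = []
    for c in selection.columns:
        v = selection[c].to_numpy(float)
        sd = float(np.std(v, ddof=1))
        constant = sd == 0
        rows.append(
            {
                "component": c,
                "mean": float(v.mean()),
                "sd": sd,
                "skewness": 0.0 if constant else float(stats.skew(v)),
                "constant": constant,
            }
        )
    return pd.DataFrame(rows).set_index("component")
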