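"""Outlier removal, shuffling/splitting, and percentile summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SplitResult:
    calibration: pd.DataFrame
    validation: pd.DataFrame
    removed: pd.DataFrame
    seed: int | None


def remove_top_residual_outliers(
    table: pd.DataFrame, residuals: np.ndarray, k: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop the k rows with the largest absolute residuals.

    Ties are broken by row order (earlier rows removed first), making the
    operation deterministic. Returns (kept, removed).
    """
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(table):
        raise ValueError("residuals length must match table")
    if not (0 <= k < len(table)):
        raise ValueError(f"k={k} must satisfy 0 <= k < n={len(table)}")
    if k == 0:
        return table.copy(), table.iloc[0:0].copy()
    # stable sort descending by |residual|: kind="stable" on the negated key
    order = np.argsort(-np.abs(residuals), kind="stable")
    removed_idx = np.sort(order[:k])
    mask = np.zeros(len(table), dtype=bool)
    mask[removed_idx] = True
    return table.iloc[~mask].copy(), table.iloc[mask].copy()


def shuffle_split(
    table: pd.DataFrame,
    calibration_fraction: float = 0.75,
    seed: int | None = None,
) -> SplitResult:
    """Seeded permutation then a floor(fraction * n) head/tail split."""
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    if not (0.0 < calibration_fraction < 1.0):
        raise ValueError("calibration_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    n_cal = int(np.floor(calibration_fraction * len(table)))
    cal = table.iloc[perm[:n_cal]].copy()
    val = table.iloc[perm[n_cal:]].copy()
    return SplitResult(
        calibration=cal,
        validation=val,
        removed=table.iloc[0:0].copy(),
        seed=seed,
    )


def quantile_summary(values) -> dict[str, float]:
    """Min, 5th pct, quartiles, median, 95th pct, max.

    Uses linear-interpolation quantiles (numpy default), the convention
    documented for all summaries in this package.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    q = np.quantile(v, [0.0, 0.05, 0.25, 0.5, 0.75, 0.95, 1.0])
    return dict(zip(("min", "p5", "q1", "median", "q3", "p95", "max"), map(float, q)))
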