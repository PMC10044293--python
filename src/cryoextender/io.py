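"""CSV readers/writers with schema validation and config handling."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .components import COMPONENT_ORDER, default_component_specs

logger = logging.getLogger(__name__)

META_COLUMNS = ("run_id", "replicate", "bull_id")
RESPONSE_COLUMNS = ("tm", "pm")


def read_experiment_table(path: str | Path, require_responses: bool = True) -> pd.DataFrame:
    """Read and validate an experiment table CSV.

    Requires run_id, replicate, bull_id, the 12 component columns and
    (unless ``require_responses=False``) tm/pm in [0, 100]. Errors name
    the offending column or row.
    """
    path = Path(path)
    table = pd.read_csv(path)
    required = list(META_COLUMNS) + list(COMPONENT_ORDER)
    if require_responses:
        required += list(RESPONSE_COLUMNS)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    for c in COMPONENT_ORDER:
        if not pd.api.types.is_numeric_dtype(table[c]):
            raise ValueError(f"{path.name}: non-numeric concentration column {c!r}")
    for c in RESPONSE_COLUMNS:
        if c in table.columns:
            bad = table.index[(table[c] < 0) | (table[c] > 100)].tolist()
            if bad:
                raise ValueError(
                    f"{path.name}: {c} outside [0, 100] at row(s) {bad[:5]}"
                )
    logger.info("read %d rows from %s", len(table), path)
    return table


def write_experiment_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table CSV plus a JSON sidecar with component units."""
    path = Path(path)
    cols = [c for c in list(META_COLUMNS) + list(COMPONENT_ORDER) + list(RESPONSE_COLUMNS) if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)
    units = {s.name: s.unit for s in default_component_specs()}
    path.with_suffix(".units.json").write_text(json.dumps(units, indent=1))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
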