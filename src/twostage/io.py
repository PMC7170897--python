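"""Readers and writers for the trial-table CSV schema and run manifests.

The interchange format is a header-keyed UTF-8 CSV with '.' decimals and one
row per trial. Required columns::

    subject_id, block_id, condition, param, trial, choice, state,
    is_common, reward, crossing_x, stay

``is_common`` and ``stay`` are booleans with missing values written as empty
fields (``is_common`` is defined only in stochastic blocks, ``stay`` from
trial 2 on); ``crossing_x`` may be missing. Two optional columns,
``reward_left`` and ``reward_right``, carry the realized reward available in
each second-stage state that trial (needed for reward-rate normalization).
Column order is irrelevant; extra columns are preserved.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .fitting import SchemaError

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_trials",
    "write_trials",
    "read_config",
    "write_manifest",
    "read_raw_export",
]

REQUIRED_COLUMNS = (
    "subject_id", "block_id", "condition", "param", "trial", "choice",
    "state", "is_common", "reward", "crossing_x", "stay",
)
OPTIONAL_COLUMNS = ("reward_left", "reward_right", "belief_right")

_BOOL_COLS = ("is_common", "stay")
_INT_COLS = ("trial", "choice", "state")
_FLOAT_COLS = ("param", "reward", "crossing_x")


def _validate(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table misses required columns: {missing}")
    out = trials.copy()
    for c in _BOOL_COLS:
        out[c] = out[c].astype("boolean")
    for c in _INT_COLS:
        if out[c].isna().any():
            bad = out.index[out[c].isna()].tolist()[:5]
            raise SchemaError(f"column {c!r} has missing values (rows {bad})")
        out[c] = out[c].astype(int)
    for c in _FLOAT_COLS:
        out[c] = out[c].astype(float)
    bad_choice = ~out["choice"].isin((0, 1))
    bad_state = ~out["state"].isin((0, 1))
    if bad_choice.any() or bad_state.any():
        rows = out.index[bad_choice | bad_state].tolist()[:5]
        raise SchemaError(f"choice/state must be 0 or 1 (rows {rows})")
    if (stoch := out["condition"] == "stochastic").any():
        if out.loc[stoch, "is_common"].isna().all():
            raise SchemaError("stochastic rows must define is_common")
    return out


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV (missing values: empty fields)."""
    raw = pd.read_csv(path)
    for c in _BOOL_COLS:
        if c in raw.columns and raw[c].dtype == object:
            # mixed strings arise when a column mixes booleans and blanks
            raw[c] = raw[c].replace(
                {"True": True, "False": False, "true": True, "false": False}
            )
    return _validate(raw)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a validated trial table; lossless round trip via read_trials."""
    out = _validate(trials)
    cols = list(REQUIRED_COLUMNS) + [
        c for c in out.columns if c not in REQUIRED_COLUMNS
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out[cols].to_csv(path, index=False, na_rep="")


def read_config(path) -> dict:
    """Read a YAML (or JSON) design/block configuration file."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def write_manifest(
    out_dir,
    command: str,
    seed: Optional[int],
    config: Optional[dict] = None,
    outputs=(),
) -> Path:
    """Write the run manifest JSON that makes an artifact directory reproducible."""
    from . import __version__

    cfg_text = json.dumps(config, sort_keys=True, default=str) if config else ""
    manifest = {
        "command": command,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "master_seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(p) for p in outputs],
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def read_raw_export(path, column_map: Optional[dict] = None) -> pd.DataFrame:
    """Importer stub for externally deposited raw data.

    Reads a CSV and renames columns via ``column_map`` (external name ->
    schema name) before validation. Mapping an external layout onto the
    schema — recoding options/states to 0/1, trial indexing, units — is the
    caller's responsibility; this function only renames and validates.
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=column_map)
    return _validate(raw)
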