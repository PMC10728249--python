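"""Readers/writers for the long-format trial CSV and JSON run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .design import CONDITIONS

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "participant_id",
    "trial",
    "condition",
    "set_id",
    "position",
    "sample_ms",
)

__all__ = ["read_trials", "write_trials", "write_manifest", "config_hash"]


def read_trials(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    require_reproduced: bool = True,
) -> pd.DataFrame:
    """Load and validate a long-format trial table.

    ``column_map`` renames external column names onto the package schema
    (``{"cond": "condition", ...}``).  Durations given in seconds are detected
    by magnitude and converted to milliseconds.  Partial trials (missing
    positions) and unknown condition codes are rejected with row-level detail.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if require_reproduced and "reproduced_ms" not in df.columns:
        raise ValueError(f"{path}: missing required column(s) ['reproduced_ms']")

    bad_cond = sorted(set(df["condition"].unique()) - set(CONDITIONS))
    if bad_cond:
        rows = df.index[df["condition"].isin(bad_cond)].tolist()[:5]
        raise ValueError(
            f"{path}: unknown condition code(s) {bad_cond} (e.g. rows {rows}); "
            f"expected {list(CONDITIONS)}"
        )

    for col in ("sample_ms",) + (("reproduced_ms",) if "reproduced_ms" in df else ()):
        med = float(df[col].median())
        if med < 10.0:  # durations in this task are hundreds of ms / a few s
            logger.info("%s: column %s looks like seconds; converting to ms", path, col)
            df[col] = df[col] * 1000.0

    sizes = df.groupby(["participant_id", "trial"])["position"].agg(["size", "nunique"])
    bad = sizes[(sizes["size"] != 4) | (sizes["nunique"] != 4)]
    if len(bad):
        examples = [f"{pid}/trial {t}" for pid, t in bad.index[:5]]
        raise ValueError(
            f"{path}: {len(bad)} trial(s) without exactly positions 1-4: {examples}"
        )
    df["position"] = df["position"].astype(int)
    df["set_id"] = df["set_id"].astype(int)
    if (df["sample_ms"] <= 0).any():
        raise ValueError(f"{path}: non-positive sample_ms values")
    return df


def write_trials(frame: pd.DataFrame, path) -> None:
    """UTF-8 CSV, header row, '.' decimal."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, *, command: str, config: dict, outputs: list[str]) -> None:
    """JSON manifest from which a run can be reproduced."""
    from . import __version__

    manifest = {
        "command": command,
        "package_version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "outputs": outputs,
    }
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
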