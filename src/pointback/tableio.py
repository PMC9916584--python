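"""Delimited-text formats for trial tables, path configs and result tables.

All tables are comma-separated UTF-8 with a header row; angles are degrees,
lengths are meters. Every file written by a pipeline run carries a comment
header recording the seed and a hash of the run configuration so a bundle
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable

import pandas as pd

from .geometry import PathSpec, build_path
from .hypotheses import predict_all
from .preprocess import TRIAL_COLUMNS

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "read_path_config",
    "write_path_config",
    "write_landmark_table",
    "prediction_table",
    "config_hash",
]

_PATH_COLUMNS = ("path_id", "L1", "L2", "L3", "L4", "turn", "experiment_tag")


def config_hash(payload: dict) -> str:
    """Stable short hash of a JSON-serializable run configuration."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path, header_meta: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_meta:
            for k, v in header_meta.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table, validating the required columns."""
    df = _read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing column(s): {missing}")
    return df


def write_trial_table(df: pd.DataFrame, path, meta: dict | None = None):
    _write_csv(df, path, meta)


def read_path_config(path) -> Dict[str, PathSpec]:
    """Read a path config (one row per path: id, L1..L4, turn, tag)."""
    df = _read_csv(path)
    missing = [c for c in _PATH_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"path config {path} is missing column(s): {missing}")
    specs = {}
    for _, row in df.iterrows():
        specs[str(row["path_id"])] = PathSpec(
            (row["L1"], row["L2"], row["L3"], row["L4"]),
            turn_direction=str(row["turn"]),
            path_id=str(row["path_id"]),
            experiment_tag=str(row.get("experiment_tag", "")),
        )
    return specs


def write_path_config(specs: Iterable[PathSpec], path,
                      meta: dict | None = None):
    rows = [{
        "path_id": s.path_id,
        "L1": s.leg_lengths[0], "L2": s.leg_lengths[1],
        "L3": s.leg_lengths[2], "L4": s.leg_lengths[3],
        "turn": s.turn_direction, "experiment_tag": s.experiment_tag,
    } for s in specs]
    _write_csv(pd.DataFrame(rows), path, meta)


def write_landmark_table(specs: Iterable[PathSpec], path,
                         meta: dict | None = None):
    """Derived vertex/landmark coordinates of each path as delimited text."""
    rows = []
    for s in specs:
        g = build_path(s)
        row = {"path_id": s.path_id, "crossing_class": g.crossing_class}
        for name in ("S", "T1", "T2", "T3", "E", "I", "I_prime", "E_prime",
                     "F1", "F2", "E_prime_far"):
            p = getattr(g, name)
            row[f"{name}_x"] = None if p is None else p[0]
            row[f"{name}_y"] = None if p is None else p[1]
        rows.append(row)
    _write_csv(pd.DataFrame(rows), path, meta)


def prediction_table(specs: Iterable[PathSpec], n_samples: int = 1000,
                     seed=None) -> pd.DataFrame:
    """Predicted arc boundaries and range means for every admissible
    hypothesis of every path (the analogue of the published range table)."""
    rows = []
    for s in specs:
        g = build_path(s)
        for pred in predict_all(g, n_samples=n_samples, seed=seed):
            rows.append({
                "path_id": s.path_id,
                "hypothesis": pred.hypothesis_id,
                "from_deg": pred.interval.from_deg,
                "to_deg": pred.interval.to_deg,
                "mean_deg": pred.mean_direction,
            })
    return pd.DataFrame(rows)
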