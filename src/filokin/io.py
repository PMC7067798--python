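"""CSV/JSON schemas of the observation layer.

All times are minutes after P40, comma-separated UTF-8 with a mandatory
header row and '.' decimals.  Schemas:

* track table — ``object_id, class, t_birth_min, t_death_min`` (empty
  death = censored; class is ``filopodium`` or ``bulb``);
* snapshots — ``t_min`` plus one non-negative integer column per category
  (``sF``, ``lF``, optionally ``sB``, ``synB``);
* count distribution — ``count, frequency`` on a contiguous support
  0..N.

Validation errors name the offending row (1-based, excluding the header).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .params import DevParams, MechParams, load_params, save_params  # re-export

__all__ = [
    "read_track_table",
    "write_track_table",
    "read_snapshots",
    "write_snapshots",
    "read_distribution",
    "write_distribution",
    "load_params",
    "save_params",
]

TRACK_COLUMNS = ["object_id", "class", "t_birth_min", "t_death_min"]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a track table CSV."""
    df = _read_csv(path, TRACK_COLUMNS)
    for col in ("t_birth_min", "t_death_min"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col} at row {int(bad[0]) + 1}"
            )
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df["t_birth_min"].isna()]
    if len(bad):
        raise SchemaError(f"{path}: missing t_birth_min at row {int(bad[0]) + 1}")
    bad = df.index[df["t_death_min"].notna() & (df["t_death_min"] < df["t_birth_min"])]
    if len(bad):
        raise SchemaError(
            f"{path}: death before birth at row {int(bad[0]) + 1}"
        )
    bad = df.index[~df["class"].isin(["filopodium", "bulb"])]
    if len(bad):
        raise SchemaError(
            f"{path}: unknown class {df.loc[bad[0], 'class']!r} at row {int(bad[0]) + 1}"
        )
    return df[TRACK_COLUMNS]


def write_track_table(df: pd.DataFrame, path: str | Path) -> None:
    df[TRACK_COLUMNS].to_csv(path, index=False)


def read_snapshots(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-time-instance count table."""
    df = _read_csv(path, ["t_min"])
    count_cols = [c for c in df.columns if c != "t_min"]
    if not count_cols:
        raise SchemaError(f"{path}: no count columns besides t_min")
    for col in count_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric {col} at row {int(bad[0]) + 1}")
        bad = df.index[(vals < 0) | (vals != vals.round())]
        if len(bad):
            raise SchemaError(
                f"{path}: {col} must be a non-negative integer at row {int(bad[0]) + 1}"
            )
        df[col] = vals.astype(int)
    return df


def write_snapshots(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_distribution(path: str | Path) -> np.ndarray:
    """Read a (count, frequency) CSV into a probability vector on 0..N."""
    df = _read_csv(path, ["count", "frequency"])
    counts = pd.to_numeric(df["count"], errors="coerce")
    freqs = pd.to_numeric(df["frequency"], errors="coerce")
    bad = df.index[counts.isna() | freqs.isna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric entry at row {int(bad[0]) + 1}")
    if (freqs < 0).any():
        row = int(df.index[freqs < 0][0]) + 1
        raise SchemaError(f"{path}: negative frequency at row {row}")
    counts = counts.astype(int)
    if sorted(counts) != list(range(int(counts.max()) + 1)):
        raise SchemaError(f"{path}: counts must cover 0..N contiguously")
    p = np.zeros(int(counts.max()) + 1)
    p[counts.to_numpy()] = freqs.to_numpy()
    total = p.sum()
    if total <= 0:
        raise SchemaError(f"{path}: all frequencies are zero")
    return p / total


def write_distribution(p, path: str | Path) -> None:
    p = np.asarray(p, dtype=float)
    pd.DataFrame({"count": np.arange(len(p)), "frequency": p}).to_csv(path, index=False)
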