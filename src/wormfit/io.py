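"""Readers and writers for the canonical file formats.

CSV is canonical throughout; XLSX is a read-only convenience for
supplementary-table-shaped spreadsheets via an explicit column mapping.
Image pairs travel as 2-slice TIFF stacks (slice 1 brightfield, slice 2
fluorescence).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import OBSERVATION_COLUMNS
from .render import WellImagePair
from .repeatability import RECOUNT_COLUMNS, SPLIT_COLUMNS

__all__ = [
    "read_observations",
    "write_observations",
    "read_recounts",
    "read_split_samples",
    "read_image_pair",
    "write_image_pair",
    "write_json",
]


def _read_table(
    path: str | Path,
    required: list[str],
    fmt: str | None,
    mapping: dict[str, str] | None,
    sheet: str | int = 0,
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if mapping:
        df = df.rename(columns=mapping)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df[required].copy()


def read_observations(
    path: str | Path,
    fmt: str | None = None,
    mapping: dict[str, str] | None = None,
    sheet: str | int = 0,
) -> pd.DataFrame:
    """Read and validate a plate-observation table.

    ``mapping`` renames source columns to the canonical schema (useful for
    spreadsheet ingestion).  Rows with non-integer counts or with
    ``n_gfp > n_total`` are rejected with their row numbers listed.
    """
    df = _read_table(path, OBSERVATION_COLUMNS, fmt, mapping, sheet)
    for col in ("n_total", "n_gfp"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise ValueError(f"{path}: unparseable {col} at rows {bad}")
        df[col] = vals.astype(int)
    bad = df.index[df["n_gfp"] > df["n_total"]].tolist()
    if bad:
        raise ValueError(f"{path}: n_gfp > n_total at rows {bad}")
    if (df[["n_total", "n_gfp"]] < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    obs[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_recounts(
    path: str | Path, fmt: str | None = None,
    mapping: dict[str, str] | None = None, sheet: str | int = 0,
) -> pd.DataFrame:
    """Read a two-pass re-count table (image_id, pass-1 counts, pass-2 counts)."""
    df = _read_table(path, RECOUNT_COLUMNS, fmt, mapping, sheet)
    for col in RECOUNT_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    return df


def read_split_samples(
    path: str | Path, fmt: str | None = None,
    mapping: dict[str, str] | None = None, sheet: str | int = 0,
) -> pd.DataFrame:
    """Read a sorter split-sample table (small and large aliquot counts)."""
    df = _read_table(path, SPLIT_COLUMNS, fmt, mapping, sheet)
    for col in SPLIT_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    return df


def write_image_pair(pair: WellImagePair, path: str | Path) -> None:
    """Save a pair as a 2-slice TIFF stack (brightfield first)."""
    import tifffile

    stack = np.stack(
        [pair.brightfield.astype(np.float32), pair.fluorescence.astype(np.float32)]
    )
    tifffile.imwrite(path, stack)


def read_image_pair(path: str | Path) -> WellImagePair:
    """Load a 2-slice TIFF stack as a well image pair (no ground truth)."""
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-slice stack, got {stack.shape}")
    return WellImagePair(
        brightfield=np.asarray(stack[0], dtype=float),
        fluorescence=np.asarray(stack[1], dtype=float),
    )


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
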