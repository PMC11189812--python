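"""Readers and writers for the four CSV dialects plus session manifests.

All dialects are comma-separated UTF-8 with a mandatory header row and dot
decimals.  Floats are written with 17 significant digits so write-then-read
round-trips the in-memory values exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activation import META_COLS, validate_count_table
from .errors import EventValidationError, FormatError
from .photometry import PhotometryTrace, validate_event_log

__all__ = [
    "read_counts", "write_counts",
    "read_coords", "write_coords",
    "read_trace", "write_trace",
    "read_events", "write_events",
    "read_manifest", "write_manifest",
    "FLOAT_FMT",
]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

COORD_COLS = ("animal_id", "group", "ap_mm", "ml_mm", "dv_mm")
TRACE_COLS = ("time_s", "fluorescence")
EVENT_FILE_COLS = ("onset_s", "offset_s", "label", "trial")


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: header lacks columns {missing}")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read an animals x regions cell-count CSV (animal_id, group, regions...)."""
    df = _read_csv(path, META_COLS)
    regions = [c for c in df.columns if c not in META_COLS]
    for col in regions:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2  # header is line 1
            raise FormatError(f"{Path(path).name}: non-numeric count at line {line}, region {col!r}")
        if (vals < 0).any():
            line = int(vals.index[vals < 0][0]) + 2
            raise FormatError(f"{Path(path).name}: negative count at line {line}, region {col!r}")
        df[col] = vals.astype(int)
    validate_count_table(df)
    log.info("read %d animals x %d regions from %s", len(df), len(regions), path)
    return df


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    validate_count_table(table)
    table.to_csv(path, index=False)


def read_coords(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, COORD_COLS)
    for col in ("ap_mm", "ml_mm", "dv_mm"):
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise FormatError(f"{Path(path).name}: non-finite coordinate in {col!r}")
    log.info("read %d cell coordinates from %s", len(df), path)
    return df


def write_coords(coords: pd.DataFrame, path: str | Path) -> None:
    coords.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trace(
    path: str | Path, baseline_interval: tuple[float, float],
    rate: float | None = None,
) -> PhotometryTrace:
    """Read a (time_s, fluorescence) CSV; the sampling rate is inferred from
    the time column unless given."""
    df = _read_csv(path, TRACE_COLS)
    trace = PhotometryTrace.from_frame(df, baseline_interval, rate=rate)
    log.info("read %d samples at %.6g Hz from %s", trace.time.size, trace.rate, path)
    return trace


def write_trace(trace_df: pd.DataFrame, path: str | Path) -> None:
    trace_df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ("onset_s", "offset_s", "label"))
    if "trial" not in df.columns:
        df["trial"] = np.arange(1, len(df) + 1)
    try:
        validate_event_log(df)
    except EventValidationError as e:
        raise EventValidationError(f"{Path(path).name}: {e}") from e
    log.info("read %d events from %s", len(df), path)
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in EVENT_FILE_COLS if c in events.columns]
    events[cols].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_manifest(path: str | Path) -> dict:
    """Session manifest (YAML or JSON) declaring at least baseline_start_s /
    baseline_end_s."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest not found: {path}")
    text = path.read_text()
    manifest = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
    for key in ("baseline_start_s", "baseline_end_s"):
        if key not in manifest:
            raise FormatError(f"{path.name}: manifest lacks {key!r}")
    return manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
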