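"""Reading, validation and writing of nest-record tables and results.

The on-disk format is comma-delimited UTF-8 with a header row and the
columns nest_id, species, flush_distance_m, defence_category, fate
(optionally initiation_date and measurement_date for nest-age checks).
Species and fate vocabularies match case-insensitively; a column-mapping
option accommodates externally named columns.  Spreadsheet input is
supported through an explicit conversion step rather than silent parsing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "NestTableSchema",
    "SchemaError",
    "read_nest_table",
    "write_nest_table",
    "convert_spreadsheet",
    "nest_age_days",
    "write_results",
]

REQUIRED_COLUMNS = ("nest_id", "species", "flush_distance_m", "defence_category", "fate")
OPTIONAL_COLUMNS = ("initiation_date", "measurement_date")


class SchemaError(ValueError):
    """A table-level or row-level validation failure, with row numbers."""


@dataclass(frozen=True)
class NestTableSchema:
    """Schema for delimited nest tables.

    ``column_map`` renames external columns to the canonical names before
    validation.  ``missing_token`` marks missing values (alongside empty
    cells).  Species/fate token matching is case-insensitive and accepts the
    aliases in ``species_aliases``/``fate_aliases``.
    """

    column_map: Dict[str, str] = field(default_factory=dict)
    missing_token: str = "NA"
    species_aliases: Dict[str, str] = field(
        default_factory=lambda: {
            "sandpiper": "sandpiper",
            "white-rumped sandpiper": "sandpiper",
            "wrsa": "sandpiper",
            "phalarope": "phalarope",
            "red phalarope": "phalarope",
            "reph": "phalarope",
        }
    )
    fate_aliases: Dict[str, str] = field(
        default_factory=lambda: {
            "hatched": "hatched",
            "hatch": "hatched",
            "successful": "hatched",
            "depredated": "depredated",
            "predated": "depredated",
            "failed": "depredated",
            "unknown": "unknown",
        }
    )


def read_nest_table(path, schema: NestTableSchema = NestTableSchema()) -> pd.DataFrame:
    """Read and validate a delimited nest table.

    Returns a frame with canonical columns and normalised vocabularies.
    Raises :class:`SchemaError` naming missing columns, or listing every
    failing row with its 1-based data row number.
    """
    df = pd.read_csv(path, na_values=[schema.missing_token, ""], skipinitialspace=True)
    df = df.rename(columns={**{c: c.strip() for c in df.columns}, **schema.column_map})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    errors: List[str] = []
    out = df.copy()

    sp = df["species"].astype(str).str.strip().str.lower().map(schema.species_aliases)
    for i in df.index[sp.isna()]:
        errors.append(f"row {i + 1}: unknown species {df.loc[i, 'species']!r}")
    out["species"] = sp

    fate = df["fate"].astype(str).str.strip().str.lower().map(schema.fate_aliases)
    for i in df.index[fate.isna()]:
        errors.append(f"row {i + 1}: unknown fate {df.loc[i, 'fate']!r}")
    out["fate"] = fate

    dist = pd.to_numeric(df["flush_distance_m"], errors="coerce")
    for i in df.index[dist.isna() & df["flush_distance_m"].notna()]:
        errors.append(f"row {i + 1}: unparseable flush_distance_m {df.loc[i, 'flush_distance_m']!r}")
    for i in df.index[dist < 0]:
        errors.append(f"row {i + 1}: negative flush_distance_m {dist[i]}")
    out["flush_distance_m"] = dist

    cat = pd.to_numeric(df["defence_category"], errors="coerce")
    bad_cat = ~cat.isin([1, 2, 3, 4])
    for i in df.index[bad_cat]:
        errors.append(f"row {i + 1}: defence_category must be 1-4, got {df.loc[i, 'defence_category']!r}")
    out["defence_category"] = cat.astype("Int64")

    for col in OPTIONAL_COLUMNS:
        if col in df.columns:
            out[col] = pd.to_datetime(df[col], errors="coerce", format="ISO8601")

    if errors:
        raise SchemaError("invalid rows:\n" + "\n".join(errors))
    out["defence_category"] = out["defence_category"].astype(int)
    return out[[c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in out.columns]]


def write_nest_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def convert_spreadsheet(xlsx_path, csv_path, sheet=0) -> None:
    """Explicit spreadsheet-to-CSV conversion step (requires openpyxl)."""
    pd.read_excel(xlsx_path, sheet_name=sheet).to_csv(csv_path, index=False)


def nest_age_days(df: pd.DataFrame) -> pd.Series:
    """Nest age at the flush measurement: measurement minus initiation, days."""
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"nest age requires column {col!r}")
    return (df["measurement_date"] - df["initiation_date"]).dt.days


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def write_results(results: Dict[str, object], output_dir, config: Optional[Dict] = None) -> List[Path]:
    """Write one JSON file per result plus a human-readable report.

    ``results`` maps a result name (e.g. ``"dip"``) to a result dataclass,
    dict or frame.  The resolved configuration (seeds included) is echoed to
    ``config.json``; machine-readable outputs keep full float precision so a
    rerun with the same inputs is byte-identical.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    if config is not None:
        p = outdir / "config.json"
        p.write_text(json.dumps(_jsonable(config), indent=2, sort_keys=True) + "\n")
        written.append(p)
    lines = []
    for name, res in results.items():
        p = outdir / f"{name}.json"
        payload = _jsonable(res)
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)
        if isinstance(payload, dict):
            flat = {}
            for k, v in payload.items():
                if isinstance(v, (int, float, str, bool)):
                    flat[k] = round(v, 4) if isinstance(v, float) else v
                elif isinstance(v, dict) and all(
                    isinstance(u, (int, float, str, bool)) for u in v.values()
                ):
                    for kk, u in v.items():
                        flat[f"{k}.{kk}"] = round(u, 4) if isinstance(u, float) else u
            lines.append(f"{name}: " + ", ".join(f"{k}={v}" for k, v in flat.items()))
        else:
            lines.append(f"{name}: written")
    report = outdir / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    written.append(report)
    return written
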