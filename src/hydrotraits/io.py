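"""Flat-file table I/O with schema checks.

One CSV dialect everywhere: comma-separated, UTF-8, header row, "." decimal.
Readers validate required columns (extra columns pass through) and report the
offending row when a number fails to parse, so a locale decimal comma fails
loudly instead of silently becoming text.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


class TableError(ValueError):
    pass


def read_table(
    path: str | Path,
    required: list[str],
    numeric: list[str] | None = None,
) -> pd.DataFrame:
    """Read a CSV, checking required columns and numeric parsability."""
    path = Path(path)
    if not path.exists():
        raise TableError(f"missing input file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise TableError(f"{path}: malformed CSV ({err})") from err
    for col in required:
        if col not in df.columns:
            raise TableError(f"{path}: missing required column {col!r}")
    for col in numeric or []:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TableError(
                f"{path}: malformed number in column {col!r} at row {row}: "
                f"{df[col].iloc[row]!r} (decimal comma?)"
            )
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
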