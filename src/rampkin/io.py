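"""Sample-table CSV I/O with metadata comment lines.

The on-disk format is RFC-4180 CSV (UTF-8, "." decimal) preceded by
``# key=value`` comment lines carrying the scheme name and config hash.
Extra user columns survive a read/write round trip untouched.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError, SchemaError
from .rig import CONC_COLUMNS, TABLE_COLUMNS, SampleTable

_META_PREFIX = "# "


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"{_META_PREFIX}scheme={table.scheme_name}\n")
        fh.write(f"{_META_PREFIX}config_hash={table.config_hash}\n")
        table.data.to_csv(fh, index=False)


def read_sample_table(path: str | Path) -> SampleTable:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)

    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample table {path} is missing columns: {missing}")
    numeric = [c for c in TABLE_COLUMNS if c != "ramp_id"]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise DataError(
                f"{path}: malformed numeric value in column {col!r}, "
                f"data row(s) {list(bad + 2)} (1-based, counting the header)"
            )
        if converted.isna().any():
            raise DataError(f"{path}: missing value in column {col!r}")
        df[col] = converted
    if (df[CONC_COLUMNS].to_numpy() < 0).any():
        raise DataError(f"{path}: negative concentrations")
    return SampleTable(
        df, scheme_name=meta.get("scheme", ""), config_hash=meta.get("config_hash", "")
    )
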