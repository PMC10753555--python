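"""Strict CSV/JSON I/O with a fixed dialect.

All tabular files use UTF-8, comma separators, ``.`` decimal points and
``#`` comment lines. Parsing is deliberately strict: a row with the wrong
field count or a numeric column containing a locale-style decimal comma
raises :class:`ParseError` naming the offending line, rather than being
silently coerced.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from pathlib import Path

import pandas as pd

__all__ = ["ParseError", "read_table", "write_report", "file_checksum"]

_FLOAT_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_DECIMAL_COMMA_RE = re.compile(r"^[+-]?\d+,\d+$")


class ParseError(ValueError):
    """Malformed tabular input; the message carries the 1-based line number."""


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a dialect-conforming CSV into a DataFrame.

    Columns whose every value parses as a float become float columns;
    columns with no parseable value stay strings; a mixed column is an
    error. Comment lines (leading ``#``) and blank lines are skipped.
    """
    path = Path(path)
    header: list[str] | None = None
    rows: list[list[str]] = []
    line_numbers: list[int] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, record in enumerate(csv.reader(fh), start=1):
            if not record or record[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in record]
                continue
            if len(record) != len(header):
                raise ParseError(
                    f"{path.name}:{lineno}: expected {len(header)} fields, got {len(record)}"
                )
            rows.append([c.strip() for c in record])
            line_numbers.append(lineno)
    if header is None:
        raise ParseError(f"{path.name}: no header row found")

    data: dict[str, list] = {}
    for j, name in enumerate(header):
        raw = [row[j] for row in rows]
        parsed: list[float] = []
        ok = 0
        for value, lineno in zip(raw, line_numbers):
            if _DECIMAL_COMMA_RE.match(value):
                raise ParseError(
                    f"{path.name}:{lineno}: locale-style decimal comma in {value!r} "
                    "(the dialect uses '.' decimals)"
                )
            if _FLOAT_RE.match(value):
                parsed.append(float(value))
                ok += 1
            else:
                parsed.append(float("nan"))
        if ok == len(raw) and raw:
            data[name] = parsed
        elif ok == 0 or not raw:
            data[name] = raw
        else:
            bad = next(
                ln for v, ln in zip(raw, line_numbers) if not _FLOAT_RE.match(v)
            )
            raise ParseError(
                f"{path.name}:{bad}: mixed numeric/text values in column {name!r}"
            )
    return pd.DataFrame(data)


def write_report(report, path: str | Path, fmt: str | None = None) -> None:
    """Write a report dict (or list of row dicts) as JSON or CSV."""
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        path.write_text(json.dumps(report, indent=2, default=_jsonable) + "\n")
    elif fmt == "csv":
        rows = report if isinstance(report, list) else [report]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.generic):
            return obj.item()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def file_checksum(path: str | Path) -> str:
    """SHA-256 hex digest, recorded in reports for input auditability."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
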