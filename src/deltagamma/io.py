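"""Reading rainfall-style data files.

Accepted formats: plain text with one nonnegative number per line, or a
CSV with a named column.  Exact zeros are significant (they are the
zero-inflation component); negative or unparseable values are rejected
with the offending line reported.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import ZeroInflatedSample
from .errors import DataParseError

__all__ = ["read_values"]


def read_values(path, column: str | None = None) -> ZeroInflatedSample:
    """Load a sample from ``path``.

    Parameters
    ----------
    path : str or Path
        Input file.
    column : str, optional
        If given, the file is parsed as CSV and this column is used;
        otherwise one number per line is expected (blank lines skipped).
    """
    path = Path(path)
    if column is not None:
        df = pd.read_csv(path)
        if column not in df.columns:
            raise DataParseError(
                f"{path}: no column {column!r} (found {list(df.columns)})"
            )
        series = pd.to_numeric(df[column], errors="coerce")
        if series.isna().any():
            row = int(series.index[series.isna()][0]) + 2  # header is line 1
            raise DataParseError(f"{path}: non-numeric value in {column!r} at line {row}")
        neg = series < 0
        if neg.any():
            row = int(series.index[neg][0]) + 2
            raise DataParseError(f"{path}: negative value at line {row}")
        return ZeroInflatedSample(series.to_numpy(dtype=float))

    values = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                v = float(text)
            except ValueError as exc:
                raise DataParseError(
                    f"{path}: cannot parse {text!r} at line {lineno}"
                ) from exc
            if v < 0:
                raise DataParseError(f"{path}: negative value {v} at line {lineno}")
            values.append(v)
    if not values:
        raise DataParseError(f"{path}: no data")
    return ZeroInflatedSample(values)
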