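"""Reading and writing sample tables and run configurations.

The interchange format is a plain UTF-8 CSV with a header row:
``animal_id,treatment,phase,<region>,...`` — comma separator, ``.`` decimal.
Factor levels are normalized case-insensitively on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ParseError
from .sample_table import FACTOR_COLUMNS, validate_sample_table


def read_sample_table(path) -> pd.DataFrame:
    """Read and validate a sample-table CSV.

    Raises :class:`ParseError` naming the offending row/column for a
    missing required column, duplicate animal id, non-numeric or negative
    count, or unknown factor level.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read sample table {path}: {exc}") from exc
    return validate_sample_table(raw)


def write_sample_table(table: pd.DataFrame, path) -> None:
    """Write a sample table as CSV in the dialect :func:`read_sample_table` accepts.

    The table is validated first; writing an empty table is an error, never
    an empty file.
    """
    if len(table) == 0:
        raise ParseError("refusing to write an empty sample table")
    validated = validate_sample_table(table)
    cols = [*FACTOR_COLUMNS, *[c for c in validated.columns if c not in FACTOR_COLUMNS]]
    validated[cols].to_csv(path, index=False)
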