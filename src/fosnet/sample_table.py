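"""The per-animal activation table and its validation.

The single input object of every analysis stage is a pandas ``DataFrame``
with three factor columns — ``animal_id`` (unique), ``treatment``
(``MA``/``SAL``), ``phase`` (``light``/``dark``) — followed by one numeric
column per brain region holding the averaged number of c-Fos-positive cells
for that animal.  Counts are nonnegative reals: bilateral and across-section
averaging routinely yields non-integers.
"""

from __future__ import annotations

from typing import List

import numpy as np
import pandas as pd

from .errors import ParseError

FACTOR_COLUMNS = ("animal_id", "treatment", "phase")
TREATMENTS = ("MA", "SAL")
PHASES = ("light", "dark")


def region_columns(table: pd.DataFrame) -> List[str]:
    """Region (count) columns of a sample table, in file order."""
    return [c for c in table.columns if c not in FACTOR_COLUMNS]


def validate_sample_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample table.

    Factor levels are normalized case-insensitively (``ma`` → ``MA``,
    ``Light`` → ``light``); unknown levels, duplicate animal ids,
    non-numeric or negative counts and all-missing region columns are
    rejected with a :class:`~fosnet.errors.ParseError` naming the offending
    row/column.

    Returns a normalized copy; the input is not modified.
    """
    for col in FACTOR_COLUMNS:
        if col not in table.columns:
            raise ParseError(f"required column {col!r} is missing")

    out = table.copy()

    ids = out["animal_id"].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ParseError(f"duplicate animal_id values: {', '.join(map(str, dup))}")
    out["animal_id"] = ids

    treat = out["treatment"].astype(str).str.strip().str.upper()
    bad = sorted(set(treat) - set(TREATMENTS))
    if bad:
        raise ParseError(
            f"unknown treatment level(s) {bad}; expected one of {list(TREATMENTS)}"
        )
    out["treatment"] = treat

    phase = out["phase"].astype(str).str.strip().str.lower()
    bad = sorted(set(phase) - set(PHASES))
    if bad:
        raise ParseError(f"unknown phase level(s) {bad}; expected one of {list(PHASES)}")
    out["phase"] = phase

    regions = region_columns(out)
    if not regions:
        raise ParseError("table has no region columns")

    for col in regions:
        raw = out[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad_mask = numeric.isna() & raw.notna()
        if bad_mask.any():
            row = out.loc[bad_mask, "animal_id"].iloc[0]
            raise ParseError(
                f"non-numeric count in column {col!r}, animal {row!r}: "
                f"{raw[bad_mask].iloc[0]!r}"
            )
        if numeric.isna().all():
            raise ParseError(f"region column {col!r} is entirely missing")
        neg = numeric < 0
        if neg.any():
            row = out.loc[neg, "animal_id"].iloc[0]
            raise ParseError(
                f"negative count in column {col!r}, animal {row!r}: {numeric[neg].iloc[0]}"
            )
        out[col] = numeric.astype(float)

    return out


def region_matrix(table: pd.DataFrame) -> np.ndarray:
    """Region counts as a float matrix (animals × regions)."""
    return table[region_columns(table)].to_numpy(dtype=float)
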