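"""Schema-validated CSV interfaces for every table the pipeline touches.

All tabular inputs and outputs are plain CSV with explicit column
contracts; violations raise :class:`~hfrmrp.strata.ValidationError` naming
the offending column and row. Round-trips are lossless for integer-coded
tables and stable to printed precision for estimate tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fss import SmoothedFSS, SuicideTable
from .strata import (
    LEVELS,
    STRATA_FIELDS,
    SURVEY_LEVELS,
    PopulationTable,
    StrataFrame,
    ValidationError,
)

MICRODATA_COLUMNS = ["year", "survey"] + list(STRATA_FIELDS) + ["response"]


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValidationError(f"{what} missing column(s) {sorted(missing)}")


def _check_codes(df: pd.DataFrame, what: str, states: set[str] | None = None) -> None:
    for fld, allowed in LEVELS.items():
        bad = ~df[fld].isin(allowed)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(
                f"{what}: column {fld!r} row {row}: invalid code {df[fld].iloc[row]!r}"
            )
    if states is not None:
        bad = ~df["state"].isin(states)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValidationError(
                f"{what}: column 'state' row {row}: unknown state {df['state'].iloc[row]!r}"
            )


def read_microdata(
    path, frame: StrataFrame, years: tuple[int, int] | None = None
) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, MICRODATA_COLUMNS, "microdata")
    _check_codes(df, "microdata", set(frame.table["state"]))
    bad = ~df["survey"].isin(SURVEY_LEVELS)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(f"microdata: column 'survey' row {row}: invalid code")
    bad = ~df["response"].isin([0, 1])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(f"microdata: column 'response' row {row}: not 0/1")
    if years is not None:
        out = (df["year"] < years[0]) | (df["year"] > years[1])
        if out.any():
            row = int(df.index[out][0])
            raise ValidationError(
                f"microdata: column 'year' row {row}: year {int(df['year'].iloc[row])} "
                f"outside window {years}"
            )
    return df


def write_microdata(df: pd.DataFrame, path) -> None:
    df[MICRODATA_COLUMNS].to_csv(path, index=False)


def read_population(path, frame: StrataFrame) -> PopulationTable:
    df = pd.read_csv(path)
    _require_columns(df, list(STRATA_FIELDS) + ["year", "population"], "population table")
    _check_codes(df, "population table", set(frame.table["state"]))
    return PopulationTable.from_tidy(df, frame)


def write_population(pop: PopulationTable, path) -> None:
    pop.to_tidy().to_csv(path, index=False)


def read_suicides(path, frame: StrataFrame) -> SuicideTable:
    df = pd.read_csv(path)
    _require_columns(
        df, list(STRATA_FIELDS) + ["year", "suicides", "firearm_suicides"], "suicide table"
    )
    _check_codes(df, "suicide table", set(frame.table["state"]))
    return SuicideTable.from_tidy(df, frame)


def write_suicides(tab: SuicideTable, path) -> None:
    tab.to_tidy().to_csv(path, index=False)


def write_smoothed_fss(sm: SmoothedFSS, path) -> None:
    sm.to_tidy().to_csv(path, index=False)


def read_smoothed_fss(path, frame: StrataFrame) -> SmoothedFSS:
    df = pd.read_csv(path)
    _require_columns(df, list(STRATA_FIELDS) + ["year", "estimate"], "smoothed FSS table")
    _check_codes(df, "smoothed FSS table", set(frame.table["state"]))
    years = tuple(sorted(df["year"].unique()))
    if len(df) != len(frame) * len(years):
        raise ValidationError(
            f"smoothed FSS table has {len(df)} rows; expected {len(frame) * len(years)}"
        )
    values = np.zeros((len(frame), len(years)))
    pos = frame.positions(df)
    y_idx = np.searchsorted(years, df["year"].to_numpy())
    values[pos, y_idx] = df["estimate"].to_numpy()
    return SmoothedFSS(frame=frame, years=years, values=values)


def write_estimates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_state_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["state_code", "has_urban_county"], "state metadata")
    return df


def ensure_inputs_exist(paths: dict[str, str | Path]) -> None:
    """Fail before any computation if a declared input file is absent."""
    missing = {name: str(p) for name, p in paths.items() if p is not None and not Path(p).exists()}
    if missing:
        raise ValidationError(f"missing input file(s): {missing}")
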