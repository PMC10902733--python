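"""Analytic strata: state x gender x marital status x race/ethnicity x urbanicity.

The estimation grid crosses the 50 US states with four binary demographic
factors. States flagged in the state metadata as having no large, densely
populated county contribute only nonurban strata, so with the packaged
metadata (7 such states) the frame has 43*16 + 7*8 = 744 strata.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENDER_LEVELS = ("man", "woman")
MARITAL_LEVELS = ("married", "not_married")
RACE_LEVELS = ("other", "white_aian")
URBANICITY_LEVELS = ("nonurban", "urban")

STRATA_FIELDS = ("state", "gender", "marital", "race", "urbanicity")

#: survey-mode codes: the small in-person survey and the large telephone one
SURVEY_SMALL = "in_person"
SURVEY_LARGE = "telephone"
SURVEY_LEVELS = (SURVEY_SMALL, SURVEY_LARGE)

#: closed code sets for the four demographic factors
LEVELS = {
    "gender": GENDER_LEVELS,
    "marital": MARITAL_LEVELS,
    "race": RACE_LEVELS,
    "urbanicity": URBANICITY_LEVELS,
}


class ValidationError(ValueError):
    """Raised when an input table violates a schema or coding contract."""


def default_state_metadata() -> pd.DataFrame:
    """Packaged 50-state metadata (7 states flagged as having no large
    densely populated county: AK, ME, MT, ND, SD, VT, WY)."""
    ref = importlib.resources.files("hfrmrp.data").joinpath("state_metadata.csv")
    with ref.open("r") as fh:
        meta = pd.read_csv(fh)
    return meta


@dataclass(frozen=True)
class StrataFrame:
    """Deterministic enumeration of analytic strata.

    ``table`` has one row per stratum with the five key columns, sorted
    lexicographically on (state, gender, marital, race, urbanicity); the row
    position is the stratum's stable integer id.
    """

    table: pd.DataFrame
    _index: dict = field(repr=False, hash=False, compare=False, default=None)

    def __post_init__(self):
        idx = {tuple(row): i for i, row in enumerate(self.table[list(STRATA_FIELDS)].itertuples(index=False))}
        object.__setattr__(self, "_index", idx)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def states(self) -> list[str]:
        return sorted(self.table["state"].unique())

    def position(self, key: tuple) -> int:
        """Integer id of a (state, gender, marital, race, urbanicity) key."""
        try:
            return self._index[tuple(key)]
        except KeyError:
            raise KeyError(f"stratum {key!r} not in frame") from None

    def positions(self, records: pd.DataFrame) -> np.ndarray:
        """Vectorised stratum lookup for a table carrying the five key columns.

        Raises ValidationError naming the first offending row if any record
        does not map to a stratum in the frame.
        """
        keys = list(zip(*(records[f] for f in STRATA_FIELDS)))
        out = np.empty(len(keys), dtype=np.int64)
        for i, k in enumerate(keys):
            pos = self._index.get(k)
            if pos is None:
                raise ValidationError(f"row {i}: stratum {k!r} not in frame")
            out[i] = pos
        return out

    def mask(self, target: dict | None) -> np.ndarray:
        """Boolean mask over strata selected by a {field: value-or-list} dict.

        ``None`` (or ``{}``) selects every stratum (the national margin).
        """
        m = np.ones(len(self.table), dtype=bool)
        if not target:
            return m
        for fld, val in target.items():
            if fld not in STRATA_FIELDS:
                raise ValidationError(f"unknown stratum field {fld!r}")
            vals = [val] if isinstance(val, str) else list(val)
            allowed = set(self.table[fld].unique()) if fld == "state" else set(LEVELS[fld])
            bad = set(vals) - allowed
            if bad:
                raise ValidationError(f"unknown code(s) {sorted(bad)!r} for field {fld!r}")
            m &= self.table[fld].isin(vals).to_numpy()
        return m


def build_strata_frame(state_metadata: pd.DataFrame | None = None) -> StrataFrame:
    """Enumerate every admissible stratum given per-state urbanicity metadata.

    Parameters
    ----------
    state_metadata
        Table with columns ``state_code`` and ``has_urban_county`` (0/1)
        covering exactly 50 states. Defaults to the packaged metadata.
    """
    if state_metadata is None:
        state_metadata = default_state_metadata()
    required = {"state_code", "has_urban_county"}
    missing = required - set(state_metadata.columns)
    if missing:
        raise ValidationError(f"state metadata missing column(s) {sorted(missing)}")
    codes = state_metadata["state_code"].astype(str)
    dupes = codes[codes.duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate state code(s): {sorted(set(dupes))}")
    bad_len = [c for c in codes if len(c) != 2 or not c.isalpha() or c.upper() != c]
    if bad_len:
        raise ValidationError(f"unknown state code(s): {bad_len}")

    rows = []
    for code, has_urban in sorted(zip(codes, state_metadata["has_urban_county"])):
        urb_levels = URBANICITY_LEVELS if int(has_urban) else ("nonurban",)
        for g in GENDER_LEVELS:
            for m in MARITAL_LEVELS:
                for r in RACE_LEVELS:
                    for u in urb_levels:
                        rows.append((code, g, m, r, u))
    rows.sort()
    table = pd.DataFrame(rows, columns=list(STRATA_FIELDS))
    return StrataFrame(table)


@dataclass(frozen=True)
class PopulationTable:
    """Adult population counts per stratum-year, aligned to a StrataFrame.

    ``counts`` has shape (n_strata, n_years), row i matching ``frame`` row i
    and column j matching ``years[j]``.
    """

    frame: StrataFrame
    years: tuple[int, ...]
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (len(self.frame), len(self.years)):
            raise ValidationError(
                f"counts shape {c.shape} != ({len(self.frame)}, {len(self.years)})"
            )
        if (c < 0).any():
            raise ValidationError("population counts must be non-negative")
        # every state-year needs someone to poststratify over
        for y_idx, year in enumerate(self.years):
            by_state = pd.Series(c[:, y_idx]).groupby(self.frame.table["state"].values).sum()
            empty = by_state[by_state <= 0]
            if len(empty):
                raise ValidationError(
                    f"state(s) {list(empty.index)} have zero population in {year}"
                )

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(int(year))
        except ValueError:
            raise ValidationError(f"year {year} outside population table window") from None

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: year, five key columns, population."""
        base = self.table_repeated()
        base["population"] = np.asarray(self.counts).T.reshape(-1)
        return base

    def table_repeated(self) -> pd.DataFrame:
        reps = pd.concat([self.frame.table] * len(self.years), ignore_index=True)
        reps.insert(0, "year", np.repeat(self.years, len(self.frame)))
        return reps

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, frame: StrataFrame) -> "PopulationTable":
        need = set(STRATA_FIELDS) | {"year", "population"}
        missing = need - set(tidy.columns)
        if missing:
            raise ValidationError(f"population table missing column(s) {sorted(missing)}")
        neg = tidy.index[tidy["population"] < 0]
        if len(neg):
            raise ValidationError(f"row {neg[0]}: negative population count")
        years = tuple(sorted(tidy["year"].unique()))
        counts = np.zeros((len(frame), len(years)), dtype=np.int64)
        pos = frame.positions(tidy)
        y_idx = np.searchsorted(years, tidy["year"].to_numpy())
        counts[pos, y_idx] = tidy["population"].to_numpy()
        # completeness: every (stratum, year) pair must be present
        if len(tidy) != len(frame) * len(years):
            raise ValidationError(
                f"population table has {len(tidy)} rows; expected "
                f"{len(frame) * len(years)} (every stratum-year pair)"
            )
        return cls(frame=frame, years=years, counts=counts)


def compute_weights(
    pop: PopulationTable,
    frame: StrataFrame,
    target: dict | None,
    year: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Poststratification weights for a target margin in a given year.

    Returns ``(positions, weights)``: the integer ids of the selected strata
    and their population shares, which sum to 1 over the selection. The
    weight of stratum s is pop(s, year) / sum of pop over the selection.
    """
    if frame is not pop.frame and not frame.table.equals(pop.frame.table):
        raise ValidationError("frame does not match population table frame")
    y = pop.year_index(year)
    m = frame.mask(target)
    sel = np.flatnonzero(m)
    tot = pop.counts[sel, y].sum()
    if tot <= 0:
        raise ValidationError("empty target population")
    w = pop.counts[sel, y] / tot
    return sel, w
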