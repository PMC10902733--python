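"""Covariate encoding shared by the ownership model and the FSS smoother.

One row per observation (respondent or stratum-year cell) with: numeric
year, one dummy per state, the four demographic indicators (man, married,
white/AIAN, nonurban), and optionally the survey-mode indicator and the
smoothed firearm-suicide-fraction covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .strata import SURVEY_LARGE


def covariate_matrix(
    table: pd.DataFrame,
    states: list[str],
    survey: bool = False,
    fss: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Encode a table carrying the five strata fields plus ``year`` (and
    ``survey`` when requested) into a dense design matrix."""
    cols: list[str] = ["year"]
    blocks = [table["year"].to_numpy(dtype=float)[:, None]]
    st = table["state"].to_numpy()
    onehot = np.zeros((len(table), len(states)))
    index = {s: i for i, s in enumerate(states)}
    onehot[np.arange(len(table)), [index[s] for s in st]] = 1.0
    blocks.append(onehot)
    cols += [f"state_{s}" for s in states]
    for name, fld, level in (
        ("man", "gender", "man"),
        ("married", "marital", "married"),
        ("white_aian", "race", "white_aian"),
        ("nonurban", "urbanicity", "nonurban"),
    ):
        blocks.append((table[fld].to_numpy() == level).astype(float)[:, None])
        cols.append(name)
    if survey:
        blocks.append((table["survey"].to_numpy() == SURVEY_LARGE).astype(float)[:, None])
        cols.append("telephone")
    if fss is not None:
        blocks.append(np.asarray(fss, dtype=float)[:, None])
        cols.append("smoothed_fss")
    return np.hstack(blocks), cols


def augment_for_logistic(X: np.ndarray, cols: list[str]) -> tuple[np.ndarray, list[str]]:
    """Extra parametric terms the linear-logistic fallback cannot learn on
    its own: the woman x married interaction and a quadratic year term."""
    c = {name: i for i, name in enumerate(cols)}
    year = X[:, c["year"]]
    yc = year - year.mean()
    woman_married = (1.0 - X[:, c["man"]]) * X[:, c["married"]]
    extra = np.column_stack([woman_married, yc * yc / 100.0])
    return np.hstack([X, extra]), cols + ["woman_x_married", "year_sq"]
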