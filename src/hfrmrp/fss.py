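"""Firearm-suicide share (FSS): raw fractions and the smoothed surface.

The raw fraction firearm/total is undefined wherever a cell recorded no
suicides and extremely noisy wherever it recorded few — which at stratum
granularity is most cells. The smoother fits a probit tree-ensemble (or the
logistic fallback) to the binomial suicide counts as a function of year,
state, and the four demographics, and reports the model-predicted firearm
probability for every stratum-year, defined even where counts are zero and
partially pooled toward similar strata everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bart import BartSettings, ProbitBart
from .design import augment_for_logistic, covariate_matrix
from .logistic import RidgeLogistic
from .strata import STRATA_FIELDS, StrataFrame, ValidationError

_CLIP = 1e-7


@dataclass(frozen=True)
class SuicideTable:
    """Total and firearm suicide counts per stratum-year."""

    frame: StrataFrame
    years: tuple[int, ...]
    total: np.ndarray       # (n_strata, n_years) int
    firearm: np.ndarray     # (n_strata, n_years) int

    def __post_init__(self):
        t = np.asarray(self.total)
        f = np.asarray(self.firearm)
        shape = (len(self.frame), len(self.years))
        if t.shape != shape or f.shape != shape:
            raise ValidationError("suicide table shape mismatch")
        if (t < 0).any() or (f < 0).any():
            raise ValidationError("suicide counts must be non-negative")
        if (f > t).any():
            raise ValidationError("firearm suicides exceed total suicides in some cell")

    def to_tidy(self) -> pd.DataFrame:
        base = pd.concat([self.frame.table] * len(self.years), ignore_index=True)
        base.insert(0, "year", np.repeat(self.years, len(self.frame)))
        base["suicides"] = np.asarray(self.total).T.reshape(-1)
        base["firearm_suicides"] = np.asarray(self.firearm).T.reshape(-1)
        return base

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, frame: StrataFrame) -> "SuicideTable":
        need = set(STRATA_FIELDS) | {"year", "suicides", "firearm_suicides"}
        missing = need - set(tidy.columns)
        if missing:
            raise ValidationError(f"suicide table missing column(s) {sorted(missing)}")
        years = tuple(sorted(tidy["year"].unique()))
        if len(tidy) != len(frame) * len(years):
            raise ValidationError(
                f"suicide table has {len(tidy)} rows; expected {len(frame) * len(years)}"
            )
        total = np.zeros((len(frame), len(years)), dtype=np.int64)
        firearm = np.zeros_like(total)
        pos = frame.positions(tidy)
        y_idx = np.searchsorted(years, tidy["year"].to_numpy())
        total[pos, y_idx] = tidy["suicides"].to_numpy()
        firearm[pos, y_idx] = tidy["firearm_suicides"].to_numpy()
        return cls(frame=frame, years=years, total=total, firearm=firearm)


def compute_raw_fss(suicides: SuicideTable, by: list[str] | None = None) -> pd.DataFrame:
    """Raw firearm-suicide fraction after aggregating counts to ``by`` units.

    ``by`` is a list of stratum fields (e.g. ``["state"]`` for state-years,
    ``["race"]`` for race-years, ``[]`` for national years); ``None`` keeps
    full stratum granularity. Counts are summed first, then divided —
    never averaged as ratios. Cells with zero total get ``fss = NaN`` and
    ``defined = False``.
    """
    if by is None:
        by = list(STRATA_FIELDS)
    bad = set(by) - set(STRATA_FIELDS)
    if bad:
        raise ValidationError(f"unknown aggregation field(s) {sorted(bad)}")
    tidy = suicides.to_tidy()
    keys = list(by) + ["year"]
    agg = tidy.groupby(keys, as_index=False)[["suicides", "firearm_suicides"]].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["fss"] = np.where(
            agg["suicides"] > 0, agg["firearm_suicides"] / agg["suicides"], np.nan
        )
    agg["defined"] = agg["suicides"] > 0
    return agg.sort_values(keys, kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SmoothedFSS:
    """Model-predicted firearm-suicide probability for every stratum-year."""

    frame: StrataFrame
    years: tuple[int, ...]
    values: np.ndarray                # (n_strata, n_years), strictly in (0,1)
    draws: np.ndarray | None = field(default=None, compare=False)
    engine: str = "bart"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != (len(self.frame), len(self.years)):
            raise ValidationError("smoothed FSS shape mismatch")
        if not ((v > 0) & (v < 1)).all():
            raise ValidationError("smoothed FSS must be strictly in (0,1)")

    def lookup(self, positions: np.ndarray, years: np.ndarray) -> np.ndarray:
        y_idx = np.searchsorted(self.years, years)
        ok = (y_idx < len(self.years)) & (np.asarray(self.years)[np.minimum(y_idx, len(self.years) - 1)] == years)
        if not ok.all():
            bad = np.asarray(years)[~ok][0]
            raise ValidationError(f"year {bad} missing from smoothed FSS surface")
        return self.values[positions, y_idx]

    def to_tidy(self) -> pd.DataFrame:
        base = pd.concat([self.frame.table] * len(self.years), ignore_index=True)
        base.insert(0, "year", np.repeat(self.years, len(self.frame)))
        base["estimate"] = np.asarray(self.values).T.reshape(-1)
        if self.draws is not None:
            lo = np.percentile(self.draws, 2.5, axis=0)
            hi = np.percentile(self.draws, 97.5, axis=0)
            base["lo95"] = lo.T.reshape(-1)
            base["hi95"] = hi.T.reshape(-1)
        return base


def fit_fss_smoother(
    suicides: SuicideTable,
    engine: str = "bart",
    settings: BartSettings | None = None,
    penalty: float = 1.0,
    seed: int = 0,
    keep_draws: bool = False,
) -> SmoothedFSS:
    """Fit the auxiliary firearm-fraction model on binomial cell counts.

    The likelihood is the binomial cell-count likelihood (identical to one
    record per suicide, far cheaper); predictions cover the full
    stratum x year grid, so zero-count cells inherit partially pooled
    values from similar strata, states, and adjacent years.
    """
    frame, years = suicides.frame, suicides.years
    total = np.asarray(suicides.total)
    firearm = np.asarray(suicides.firearm)
    if total.sum() == 0:
        raise ValidationError("no events to fit")

    grid = pd.concat([frame.table] * len(years), ignore_index=True)
    grid.insert(0, "year", np.repeat(years, len(frame)))
    X, cols = covariate_matrix(grid, frame.states)
    k = firearm.T.reshape(-1)
    n = total.T.reshape(-1)

    if engine == "bart":
        model = ProbitBart(settings or BartSettings(), seed=seed)
        model.fit(X, k, n, X_pred=X)
        draws = model.pred_draws_
    elif engine == "logistic":
        Xa, _ = augment_for_logistic(X, cols)
        n_draws = (settings or BartSettings()).n_draws
        model = RidgeLogistic(n_draws=n_draws, penalty=penalty, seed=seed)
        model.fit(Xa, k, n, X_pred=Xa)
        draws = model.pred_draws_
    else:
        raise ValidationError(f"unknown engine {engine!r}")

    values = np.clip(
        draws.mean(axis=0).astype(np.float64), _CLIP, 1 - _CLIP
    ).reshape(len(years), len(frame)).T
    draw_cube = None
    if keep_draws:
        draw_cube = draws.reshape(draws.shape[0], len(years), len(frame)).transpose(0, 2, 1)
    return SmoothedFSS(frame=frame, years=years, values=values, draws=draw_cube, engine=engine)
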