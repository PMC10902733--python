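"""The household-firearm ownership model: fit and stratum-year prediction.

Respondent-level binary responses are regressed on year, state, the four
demographic indicators, the survey-mode indicator, and (by default) the
smoothed firearm-suicide share for the respondent's stratum-year. The
default engine is the probit tree ensemble; a ridge-logistic fallback is
selectable for fast runs. Predictions on the full stratum x year grid, with
the survey indicator held at a reference level, are the posterior
probability surface that all downstream poststratification consumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bart import BartSettings, ProbitBart
from .design import augment_for_logistic, covariate_matrix
from .fss import SmoothedFSS
from .logistic import RidgeLogistic
from .strata import (
    LEVELS,
    STRATA_FIELDS,
    SURVEY_LEVELS,
    SURVEY_SMALL,
    StrataFrame,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EngineSettings:
    """Which posterior engine to use and at what scale."""

    engine: str = "bart"              # "bart" | "logistic"
    bart: BartSettings = field(default_factory=BartSettings)
    penalty: float = 1.0              # ridge precision of the fallback
    n_draws: int = 500                # fallback draw count


@dataclass
class ModelInputs:
    """Assembled design matrix, outcome, and drop accounting."""

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    frame: StrataFrame
    include_fss: bool
    dropped: dict[str, int]
    strata_pos: np.ndarray
    years: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)


def assemble_design(
    records: pd.DataFrame,
    smoothed_fss: SmoothedFSS | None,
    frame: StrataFrame,
    include_fss: bool = True,
) -> ModelInputs:
    """One design row per usable respondent; invalid records are dropped
    (complete-case) with per-reason counts reported.

    A respondent whose stratum-year is absent from the smoothed-FSS surface
    is an error (the surface is supposed to cover the full grid), not a drop.
    """
    need = {"year", "survey", "response"} | set(STRATA_FIELDS)
    missing = need - set(records.columns)
    if missing:
        raise ValidationError(f"microdata missing column(s) {sorted(missing)}")
    if include_fss and smoothed_fss is None:
        raise ValidationError("include_fss=True requires a smoothed FSS surface")

    recs = records.copy()
    dropped: dict[str, int] = {}

    m_missing = recs[list(need)].isna().any(axis=1)
    dropped["missing_field"] = int(m_missing.sum())
    recs = recs[~m_missing]

    ok = recs["state"].isin(set(frame.table["state"]))
    for fld in ("gender", "marital", "race", "urbanicity"):
        ok &= recs[fld].isin(LEVELS[fld])
    ok &= recs["survey"].isin(SURVEY_LEVELS)
    ok &= recs["response"].isin([0, 1])
    dropped["unknown_code"] = int((~ok).sum())
    recs = recs[ok]

    # a respondent key may still miss the frame (e.g. urban cell of an
    # urban-free state)
    key_ok = np.ones(len(recs), dtype=bool)
    pos = np.empty(len(recs), dtype=np.int64)
    for i, key in enumerate(zip(*(recs[f] for f in STRATA_FIELDS))):
        p = frame._index.get(key)
        if p is None:
            key_ok[i] = False
        else:
            pos[i] = p
    dropped["not_in_frame"] = int((~key_ok).sum())
    recs = recs[key_ok]
    pos = pos[key_ok]

    if smoothed_fss is not None:
        in_window = recs["year"].isin(smoothed_fss.years)
        dropped["year_outside_window"] = int((~in_window).sum())
        recs = recs[in_window]
        pos = pos[in_window.to_numpy()]

    for reason, n in dropped.items():
        if n:
            log.info("assemble_design: dropped %d record(s): %s", n, reason)

    fss_vals = None
    if include_fss:
        fss_vals = smoothed_fss.lookup(pos, recs["year"].to_numpy())
    X, cols = covariate_matrix(recs, frame.states, survey=True, fss=fss_vals)
    return ModelInputs(
        X=X,
        y=recs["response"].to_numpy(dtype=np.int64),
        columns=cols,
        frame=frame,
        include_fss=include_fss,
        dropped=dropped,
        strata_pos=pos,
        years=recs["year"].to_numpy(),
    )


@dataclass
class HFRModel:
    """A fitted engine plus everything needed to rebuild prediction rows."""

    engine: object
    settings: EngineSettings
    columns: list[str]
    frame: StrataFrame
    include_fss: bool
    seed: int

    def predict_draws(self, X: np.ndarray) -> np.ndarray:
        if self.settings.engine == "logistic":
            X, _ = augment_for_logistic(X, self.columns)
        return self.engine.predict_draws(X)


def fit_hfr_model(
    inputs: ModelInputs, settings: EngineSettings | None = None, seed: int = 0
) -> HFRModel:
    """Fit the selected engine on the assembled design."""
    settings = settings or EngineSettings()
    uniq = np.unique(inputs.y)
    if len(uniq) < 2:
        raise ValidationError("constant outcome: cannot fit a binary model")
    if settings.engine == "bart":
        eng = ProbitBart(settings.bart, seed=seed)
        eng.fit(inputs.X, inputs.y)
    elif settings.engine == "logistic":
        Xa, _ = augment_for_logistic(inputs.X, inputs.columns)
        eng = RidgeLogistic(n_draws=settings.n_draws, penalty=settings.penalty, seed=seed)
        eng.fit(Xa, inputs.y)
    else:
        raise ValidationError(f"unknown engine {settings.engine!r}")
    return HFRModel(
        engine=eng,
        settings=settings,
        columns=inputs.columns,
        frame=inputs.frame,
        include_fss=inputs.include_fss,
        seed=seed,
    )


@dataclass(frozen=True)
class HFRPosterior:
    """Posterior draws of P(household firearm) on the stratum x year grid."""

    frame: StrataFrame
    years: tuple[int, ...]
    draws: np.ndarray            # (n_draws, n_strata, n_years), in (0,1)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        d = np.asarray(self.draws)
        if d.ndim != 3 or d.shape[1:] != (len(self.frame), len(self.years)):
            raise ValidationError("posterior draw cube shape mismatch")
        if not ((d > 0).all() and (d < 1).all()):
            raise ValidationError("posterior draws must be strictly in (0,1)")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean_surface(self) -> np.ndarray:
        """Posterior-mean probability per stratum-year, shape (S, Y)."""
        return self.draws.mean(axis=0, dtype=np.float64)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            draws=self.draws.astype(np.float32),
            years=np.asarray(self.years),
            meta=json.dumps(self.meta, default=str),
        )

    @classmethod
    def load(cls, path, frame: StrataFrame) -> "HFRPosterior":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                frame=frame,
                years=tuple(int(y) for y in z["years"]),
                draws=z["draws"],
                meta=json.loads(str(z["meta"])),
            )


def prediction_grid(
    frame: StrataFrame,
    years: tuple[int, ...],
    smoothed_fss: SmoothedFSS | None,
    include_fss: bool,
    reference_survey: str = SURVEY_SMALL,
) -> tuple[np.ndarray, list[str]]:
    """Design rows for every stratum-year, survey fixed at the reference."""
    if reference_survey not in SURVEY_LEVELS:
        raise ValidationError(f"unknown reference survey {reference_survey!r}")
    grid = pd.concat([frame.table] * len(years), ignore_index=True)
    grid.insert(0, "year", np.repeat(years, len(frame)))
    grid["survey"] = reference_survey
    fss_vals = None
    if include_fss:
        if smoothed_fss is None:
            raise ValidationError("prediction grid requires smoothed FSS")
        pos = np.tile(np.arange(len(frame)), len(years))
        fss_vals = smoothed_fss.lookup(pos, grid["year"].to_numpy())
    return covariate_matrix(grid, frame.states, survey=True, fss=fss_vals)


def predict_strata_probabilities(
    model: HFRModel,
    frame: StrataFrame,
    years: tuple[int, ...],
    smoothed_fss: SmoothedFSS | None = None,
    reference_survey: str = SURVEY_SMALL,
) -> HFRPosterior:
    """Posterior probability draws for the full stratum x year grid.

    Every cell receives predictions, including strata with no respondents
    in a year: those values are pure partial pooling through the fitted
    regression surface.
    """
    X, _ = prediction_grid(frame, years, smoothed_fss, model.include_fss, reference_survey)
    flat = model.predict_draws(X)           # (D, Y*S), year-major
    eps = np.float32(1e-7)
    flat = np.clip(flat, eps, 1 - eps)
    cube = flat.reshape(flat.shape[0], len(years), len(frame)).transpose(0, 2, 1)
    meta = {
        "engine": model.settings.engine,
        "seed": model.seed,
        "reference_survey": reference_survey,
        "include_fss": model.include_fss,
    }
    return HFRPosterior(frame=frame, years=tuple(int(y) for y in years), draws=cube, meta=meta)
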