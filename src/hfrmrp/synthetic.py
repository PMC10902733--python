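"""Synthetic survey microdata, population drift, and suicide counts.

Everything downstream of the raw data is testable against a known truth
surface: a logistic model of household-firearm probability over strata and
years with state effects, four demographic main effects, a gender x marital
interaction (married women shifted toward married men), and a linear year
trend. The generator emulates the shape of the real inputs: a small
in-person survey fielded in 16 waves over 1990-2018, a large telephone
survey fielded in 3 years, population composition drifting toward urban,
unmarried, and minority groups, and stratum-year suicide counts whose
firearm fraction tracks true ownership through a logit link with
group-specific method-preference offsets (the systematic biases of the
firearm-suicide proxy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .strata import (
    STRATA_FIELDS,
    SURVEY_LARGE,
    SURVEY_SMALL,
    PopulationTable,
    StrataFrame,
    ValidationError,
)
from .fss import SuicideTable

#: in-person survey wave years, biennial after 1994 (16 waves in 1990-2018)
SMALL_WAVE_YEARS = (
    1990, 1991, 1993, 1994, 1996, 1998, 2000, 2002,
    2004, 2006, 2008, 2010, 2012, 2014, 2016, 2018,
)
LARGE_YEARS = (2001, 2002, 2004)

#: full-scale per-wave sample sizes: the telephone survey's three published
#: waves plus the in-person survey's 22,430 respondents split as evenly as
#: integers allow over its 16 waves (total 713,458)
PAPER_SCALE_LARGE_N = (192_700, 221_920, 276_408)
PAPER_SCALE_SMALL_N = (1402,) * 14 + (1401,) * 2


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions.

    Sample sizes are scaled for desk runtime (16 x 1,400 in-person plus
    3 x 5,000 telephone respondents); ``paper_scale()`` restores the
    published wave sizes for accounting checks only.
    """

    seed: int = 20180
    years: tuple[int, int] = (1990, 2018)
    small_wave_years: tuple[int, ...] = SMALL_WAVE_YEARS
    small_wave_n: tuple[int, ...] = (1400,) * 16
    large_years: tuple[int, ...] = LARGE_YEARS
    large_n: tuple[int, ...] = (5000,) * 3
    #: log-odds offset added for telephone-survey responses; truth is the
    #: mode-free (in-person) probability
    mode_effect: float = 0.3

    # truth-surface coefficients, all log-odds scale
    intercept: float = -2.45
    sd_state: float = 0.5
    gender_effect: float = 0.65        # man vs woman
    marital_effect: float = 0.70       # married vs not
    race_effect: float = 1.00          # white/AIAN vs other
    urban_effect: float = 0.90         # nonurban vs urban
    gender_marital_interaction: float = 0.55   # extra lift for married women
    year_trend: float = -0.012         # per year

    # population composition, 1990 margins and per-year linear drifts
    man_share: float = 0.48
    urban_share_1990: float = 0.42
    married_share_1990: float = 0.60
    white_share_1990: float = 0.78
    urban_drift: float = 0.004
    unmarried_drift: float = 0.005
    minority_drift: float = 0.004
    mean_state_pop: int = 150_000
    state_pop_spread: float = 10.0     # largest/smallest state population ratio

    # suicide process
    suicide_rate_per_100k: float = 14.0
    fss_alpha0: float = 0.8
    fss_alpha1: float = 1.0
    #: method-preference offsets, keyed "field:level", added to logit(q)
    fss_offsets: tuple[tuple[str, float], ...] = (
        ("race:other", 0.40),
        ("urbanicity:urban", 0.25),
        ("marital:not_married", 0.30),
        ("gender:woman", -0.25),
    )

    def __post_init__(self):
        y0, y1 = self.years
        if y0 > y1:
            raise ValidationError("years range must be ordered")
        if len(self.small_wave_n) != len(self.small_wave_years):
            raise ValidationError("one sample size per in-person wave required")
        if len(self.large_n) != len(self.large_years):
            raise ValidationError("one sample size per telephone year required")
        for y in tuple(self.small_wave_years) + tuple(self.large_years):
            if not (y0 <= y <= y1):
                raise ValidationError(f"wave year {y} outside study window {self.years}")
        if any(n <= 0 for n in tuple(self.small_wave_n) + tuple(self.large_n)):
            raise ValidationError("all wave sample sizes must be positive")
        span = y1 - y0
        for name, base, drift in (
            ("urban", self.urban_share_1990, self.urban_drift),
            ("married", self.married_share_1990, -self.unmarried_drift),
            ("white", self.white_share_1990, -self.minority_drift),
        ):
            for share in (base, base + drift * span):
                if not (0.0 < share < 1.0):
                    raise ValidationError(
                        f"{name} share drifts outside (0,1): {share:.3f}"
                    )
        if not (0.0 < self.man_share < 1.0):
            raise ValidationError("man share must be in (0,1)")
        if self.suicide_rate_per_100k < 0:
            raise ValidationError("suicide rate must be non-negative")

    @property
    def year_list(self) -> tuple[int, ...]:
        return tuple(range(self.years[0], self.years[1] + 1))

    def paper_scale(self) -> "SyntheticConfig":
        """The same conditions at the published survey sizes (713,458 total)."""
        return replace(self, small_wave_n=PAPER_SCALE_SMALL_N, large_n=PAPER_SCALE_LARGE_N)

    def total_respondents(self) -> int:
        return int(sum(self.small_wave_n) + sum(self.large_n))


@dataclass(frozen=True)
class TruthSurface:
    """True household-firearm probability for every stratum-year."""

    frame: StrataFrame
    years: tuple[int, ...]
    p: np.ndarray                     # (n_strata, n_years), strictly in (0,1)
    coefficients: dict = field(compare=False)

    def __post_init__(self):
        arr = np.asarray(self.p)
        if arr.shape != (len(self.frame), len(self.years)):
            raise ValidationError("truth surface shape mismatch")
        if not ((arr > 0) & (arr < 1)).all():
            raise ValidationError("truth probabilities must be strictly in (0,1)")

    @property
    def logit(self) -> np.ndarray:
        return logit(self.p)


def _stream_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


def generate_truth_surface(config: SyntheticConfig, frame: StrataFrame) -> TruthSurface:
    """Deterministic (seeded) truth surface on the stratum x year grid."""
    years = np.asarray(config.year_list)
    t = frame.table
    rng = _stream_rng(config.seed, 1)
    states = sorted(t["state"].unique())
    state_eff = dict(zip(states, rng.normal(0.0, config.sd_state, size=len(states))))

    eta = np.full(len(t), config.intercept, dtype=float)
    eta += t["state"].map(state_eff).to_numpy()
    eta += np.where(t["gender"] == "man", config.gender_effect, 0.0)
    eta += np.where(t["marital"] == "married", config.marital_effect, 0.0)
    eta += np.where(t["race"] == "white_aian", config.race_effect, 0.0)
    eta += np.where(t["urbanicity"] == "nonurban", config.urban_effect, 0.0)
    eta += np.where(
        (t["gender"] == "woman") & (t["marital"] == "married"),
        config.gender_marital_interaction,
        0.0,
    )
    trend = config.year_trend * (years - years[0])
    surface = expit(eta[:, None] + trend[None, :])
    coeffs = {
        "intercept": config.intercept,
        "state_effects": state_eff,
        "gender_effect": config.gender_effect,
        "marital_effect": config.marital_effect,
        "race_effect": config.race_effect,
        "urban_effect": config.urban_effect,
        "gender_marital_interaction": config.gender_marital_interaction,
        "year_trend": config.year_trend,
    }
    return TruthSurface(frame=frame, years=tuple(config.year_list), p=surface, coefficients=coeffs)


def _margin_shares(config: SyntheticConfig, year: int) -> dict[str, dict[str, float]]:
    dt = year - config.years[0]
    urban = config.urban_share_1990 + config.urban_drift * dt
    married = config.married_share_1990 - config.unmarried_drift * dt
    white = config.white_share_1990 - config.minority_drift * dt
    return {
        "gender": {"man": config.man_share, "woman": 1 - config.man_share},
        "marital": {"married": married, "not_married": 1 - married},
        "race": {"white_aian": white, "other": 1 - white},
        "urbanicity": {"urban": urban, "nonurban": 1 - urban},
    }


def _state_populations(config: SyntheticConfig, states: list[str]) -> dict[str, float]:
    # deterministic log-spaced spread over alphabetised states, interleaved
    # so that neighbouring letters do not sort by size
    k = len(states)
    sizes = np.geomspace(1.0, config.state_pop_spread, k)
    sizes *= k * config.mean_state_pop / sizes.sum()
    order = np.argsort([(i * 17) % k for i in range(k)], kind="stable")
    return {s: float(sizes[j]) for s, j in zip(states, order)}


def generate_population(config: SyntheticConfig, frame: StrataFrame) -> PopulationTable:
    """Population counts from product-of-margins shares with linear drift.

    Urban-free states (no urban strata in the frame) place their whole
    population in nonurban cells; counts are deterministic given the config.
    """
    t = frame.table
    years = config.year_list
    state_pop = _state_populations(config, sorted(t["state"].unique()))
    has_urban = t.groupby("state")["urbanicity"].transform(lambda s: "urban" in set(s))

    counts = np.zeros((len(t), len(years)), dtype=np.int64)
    for j, year in enumerate(years):
        shares = _margin_shares(config, year)
        cell = (
            t["gender"].map(shares["gender"]).to_numpy()
            * t["marital"].map(shares["marital"]).to_numpy()
            * t["race"].map(shares["race"]).to_numpy()
        )
        urb = t["urbanicity"].map(shares["urbanicity"]).to_numpy()
        cell = cell * np.where(has_urban.to_numpy(), urb, 1.0)
        counts[:, j] = np.rint(cell * t["state"].map(state_pop).to_numpy()).astype(np.int64)
    return PopulationTable(frame=frame, years=tuple(years), counts=counts)


def simulate_survey_microdata(
    truth: TruthSurface, pop: PopulationTable, config: SyntheticConfig
) -> pd.DataFrame:
    """Respondent-level table: year, survey, five strata fields, response.

    Respondents are drawn with probability proportional to stratum population
    in their wave-year; the binary response is Bernoulli with probability
    inverse-logit(logit(truth) + mode_effect for the telephone survey).
    """
    rng = _stream_rng(config.seed, 2)
    waves = [
        (y, SURVEY_SMALL, n) for y, n in zip(config.small_wave_years, config.small_wave_n)
    ] + [(y, SURVEY_LARGE, n) for y, n in zip(config.large_years, config.large_n)]
    waves.sort(key=lambda w: (w[0], w[1]))

    frames = []
    for year, survey, n in waves:
        if n == 0:
            continue
        yi = pop.year_index(year)
        weights = pop.counts[:, yi].astype(float)
        total_pop = weights.sum()
        if n > total_pop:
            raise ValidationError(
                f"wave {year}/{survey}: requested n={n} exceeds population {int(total_pop)}"
            )
        strata_idx = rng.choice(len(weights), size=n, p=weights / total_pop)
        eta = truth.logit[strata_idx, truth.years.index(year)]
        if survey == SURVEY_LARGE:
            eta = eta + config.mode_effect
        resp = (rng.random(n) < expit(eta)).astype(np.int8)
        block = truth.frame.table.iloc[strata_idx].reset_index(drop=True)
        block.insert(0, "survey", survey)
        block.insert(0, "year", year)
        block["response"] = resp
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    return out


def _fss_offsets_vector(config: SyntheticConfig, frame: StrataFrame) -> np.ndarray:
    t = frame.table
    off = np.zeros(len(t))
    for key, val in config.fss_offsets:
        fld, level = key.split(":")
        if fld not in STRATA_FIELDS:
            raise ValidationError(f"unknown offset field {fld!r}")
        off += np.where(t[fld] == level, float(val), 0.0)
    return off


def true_firearm_fraction(
    truth: TruthSurface, config: SyntheticConfig
) -> np.ndarray:
    """The generator's q: probability a suicide uses a firearm, per cell."""
    off = _fss_offsets_vector(config, truth.frame)
    return expit(config.fss_alpha0 + config.fss_alpha1 * truth.logit + off[:, None])


def simulate_suicide_counts(
    truth: TruthSurface, pop: PopulationTable, config: SyntheticConfig
) -> SuicideTable:
    """Poisson totals and binomial firearm suicides per stratum-year.

    logit(q) = alpha0 + alpha1 * logit(true HFR) + method-preference offsets,
    so the firearm fraction is correlated with, but systematically biased
    relative to, true ownership.
    """
    rng = _stream_rng(config.seed, 3)
    lam = pop.counts * (config.suicide_rate_per_100k / 1e5)
    total = rng.poisson(lam)
    q = true_firearm_fraction(truth, config)
    firearm = rng.binomial(total, q)
    return SuicideTable(
        frame=truth.frame, years=truth.years, total=total, firearm=firearm
    )


def true_hfr(
    truth: TruthSurface, pop: PopulationTable, target: dict | None, year: int
) -> float:
    """Closed-form poststratified truth: sum of w_s * p_s over the target."""
    from .strata import compute_weights

    sel, w = compute_weights(pop, truth.frame, target, year)
    yi = truth.years.index(int(year))
    return float(w @ truth.p[sel, yi])
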