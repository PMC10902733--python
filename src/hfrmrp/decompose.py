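"""Structural analyses of the estimated ownership surface.

Three analyses: (1) a Kitagawa-style split of each unit's 1990-to-2018
change in HFR into a within-strata rate component (composition frozen at
the start year) and a composition component (the remainder); (2) the same
identity applied cross-sectionally to a state-vs-national difference over
shared demographic cells; (3) a variance partition of the stratum-year
estimate surface over the six factor groups (state, race, gender, marital
status, urbanicity, year) using LMG/Shapley averaging of R-squared gains
over all orderings of the groups.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HFRPosterior
from .strata import PopulationTable, ValidationError, compute_weights


@dataclass(frozen=True)
class DecompositionResult:
    """Additive split of an HFR difference into rate and composition parts."""

    unit: str
    year0: int
    year1: int
    total: float
    rate_component: float
    composition_component: float
    composition_share: float | None     # composition / total, if total != 0

    def __post_init__(self):
        gap = abs(self.rate_component + self.composition_component - self.total)
        if gap > 1e-9:
            raise ValidationError(f"decomposition identity violated by {gap:.2e}")


def _unit_weights(pop: PopulationTable, post: HFRPosterior, unit: str | None, year: int):
    target = None if unit in (None, "national") else {"state": unit}
    return compute_weights(pop, post.frame, target, year)


def decompose_temporal(
    post: HFRPosterior,
    pop: PopulationTable,
    unit: str | None,
    year0: int,
    year1: int,
    symmetric: bool = False,
    surface: np.ndarray | None = None,
) -> DecompositionResult:
    """Split a unit's HFR change between two years into rate vs composition.

    Default convention freezes composition at the ``year0`` weights for the
    rate component and reports composition as the residual; ``symmetric``
    switches to the average-of-endpoints variant in which both components
    use midpoint weights/rates (the identity still holds exactly).
    """
    p = post.mean_surface() if surface is None else surface
    sel0, w0 = _unit_weights(pop, post, unit, year0)
    sel1, w1 = _unit_weights(pop, post, unit, year1)
    if not np.array_equal(sel0, sel1):
        raise ValidationError("strata selection changed between years")
    y0 = post.years.index(int(year0))
    y1 = post.years.index(int(year1))
    p0 = p[sel0, y0]
    p1 = p[sel0, y1]
    total = float(w1 @ p1 - w0 @ p0)
    if symmetric:
        rate = float(0.5 * (w0 + w1) @ (p1 - p0))
    else:
        rate = float(w0 @ (p1 - p0))
    comp = total - rate
    share = comp / total if total != 0.0 else None
    return DecompositionResult(
        unit=unit or "national",
        year0=int(year0),
        year1=int(year1),
        total=total,
        rate_component=rate,
        composition_component=comp,
        composition_share=share,
    )


def decompose_temporal_draws(
    post: HFRPosterior,
    pop: PopulationTable,
    unit: str | None,
    year0: int,
    year1: int,
    symmetric: bool = False,
) -> pd.DataFrame:
    """Per-draw decomposition; columns total, rate, composition."""
    sel, w0 = _unit_weights(pop, post, unit, year0)
    _, w1 = _unit_weights(pop, post, unit, year1)
    y0 = post.years.index(int(year0))
    y1 = post.years.index(int(year1))
    p0 = np.asarray(post.draws[:, sel, y0], dtype=np.float64)
    p1 = np.asarray(post.draws[:, sel, y1], dtype=np.float64)
    total = p1 @ w1 - p0 @ w0
    if symmetric:
        rate = (p1 - p0) @ (0.5 * (w0 + w1))
    else:
        rate = (p1 - p0) @ w0
    return pd.DataFrame({"total": total, "rate": rate, "composition": total - rate})


_DEMO_FIELDS = ("gender", "marital", "race", "urbanicity")


def decompose_state_vs_national(
    post: HFRPosterior,
    pop: PopulationTable,
    state: str,
    year: int,
    surface: np.ndarray | None = None,
) -> DecompositionResult:
    """Split (state HFR - national HFR) over shared demographic cells.

    The 16 demographic cells (gender x marital x race x urbanicity) are the
    shared strata definitions: the rate part weighs state-vs-national rate
    differences by the state's cell shares, the composition part weighs the
    share differences by national cell rates.
    """
    p = post.mean_surface() if surface is None else surface
    yi = post.years.index(int(year))
    table = post.frame.table
    sel_s, w_s = _unit_weights(pop, post, state, year)
    sel_n, w_n = _unit_weights(pop, post, None, year)

    cells = list(itertools.product(*[sorted(set(table[f])) for f in _DEMO_FIELDS]))
    rate = comp = 0.0
    for cell in cells:
        m = np.ones(len(table), dtype=bool)
        for f, lvl in zip(_DEMO_FIELDS, cell):
            m &= (table[f] == lvl).to_numpy()
        in_s = m[sel_s]
        in_n = m[sel_n]
        ws_d = w_s[in_s].sum()
        wn_d = w_n[in_n].sum()
        p_us_d = (w_n[in_n] @ p[sel_n[in_n], yi]) / wn_d if wn_d > 0 else 0.0
        p_st_d = (w_s[in_s] @ p[sel_s[in_s], yi]) / ws_d if ws_d > 0 else p_us_d
        rate += ws_d * (p_st_d - p_us_d)
        comp += (ws_d - wn_d) * p_us_d
    total = float(w_s @ p[sel_s, yi] - w_n @ p[sel_n, yi])
    # rate + comp equals total analytically; enforce the identity to the
    # floating-point residual by folding rounding into the composition part
    comp = total - rate
    share = comp / total if total != 0.0 else None
    return DecompositionResult(
        unit=state,
        year0=int(year),
        year1=int(year),
        total=total,
        rate_component=float(rate),
        composition_component=float(comp),
        composition_share=share,
    )


@dataclass(frozen=True)
class VariancePartition:
    """LMG attribution of the estimate surface's variance to factor groups."""

    total_r2: float
    contributions: dict
    r2_with_interactions: float | None
    interactions: tuple
    n_cells: int
    dropped_factors: tuple


def _factor_groups(table: pd.DataFrame, years: np.ndarray):
    n_s = len(table)
    n_y = len(years)
    rep = pd.concat([table] * n_y, ignore_index=True)
    year_col = np.repeat(np.asarray(years), n_s)
    groups: dict[str, np.ndarray] = {}
    for name, col in (
        ("state", rep["state"]),
        ("race", rep["race"]),
        ("gender", rep["gender"]),
        ("marital", rep["marital"]),
        ("urbanicity", rep["urbanicity"]),
        ("year", pd.Series(year_col)),
    ):
        levels = sorted(pd.unique(col))
        if len(levels) < 2:
            groups[name] = None
            continue
        dummies = np.column_stack(
            [(col.to_numpy() == lvl).astype(float) for lvl in levels[1:]]
        )
        groups[name] = dummies
    return groups, rep


def variance_partition(
    surface: np.ndarray,
    frame,
    years,
    interactions: list[tuple[str, str]] | None = None,
    weights: np.ndarray | None = None,
) -> VariancePartition:
    """Partition the variance of posterior-mean stratum-year estimates.

    Fits OLS (or WLS when population ``weights`` with shape (S, Y) are
    given) of the flattened surface on factor dummy groups; the per-factor
    contribution is the LMG/Shapley average of its marginal R-squared gain
    over all orderings of the groups, which sums exactly to the full
    main-effects R-squared. Degenerate factors (a single observed level)
    are dropped with a warning.
    """
    if interactions is None:
        interactions = [("gender", "marital")]
    y = np.asarray(surface, dtype=np.float64).T.reshape(-1)   # year-major
    groups, rep = _factor_groups(frame.table, np.asarray(years))
    dropped = tuple(k for k, v in groups.items() if v is None)
    for k in dropped:
        warnings.warn(f"factor {k!r} is constant; dropped from the partition")
    groups = {k: v for k, v in groups.items() if v is not None}
    names = list(groups)
    k = len(names)

    if weights is not None:
        sw = np.sqrt(np.asarray(weights, dtype=np.float64).T.reshape(-1))
    else:
        sw = None

    def r2_of(blocks: list[np.ndarray]) -> float:
        A = np.column_stack([np.ones(len(y))] + blocks)
        if sw is None:
            Aw, yw = A, y
        else:
            Aw, yw = A * sw[:, None], y * sw
        coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
        resid = yw - Aw @ coef
        mean_w = (yw @ (sw if sw is not None else np.ones(len(y)))) / (
            (sw @ sw) if sw is not None else len(y)
        )
        tss = ((yw - mean_w * (sw if sw is not None else 1.0)) ** 2).sum()
        return 1.0 - (resid @ resid) / tss

    r2 = {}
    for r in range(k + 1):
        for combo in itertools.combinations(range(k), r):
            blocks = [groups[names[i]] for i in combo]
            r2[frozenset(combo)] = r2_of(blocks) if blocks else 0.0

    contrib = {}
    for i in range(k):
        total = 0.0
        for S in r2:
            if i in S:
                continue
            w = math.factorial(len(S)) * math.factorial(k - 1 - len(S)) / math.factorial(k)
            total += w * (r2[S | {i}] - r2[S])
        contrib[names[i]] = total
    full = r2[frozenset(range(k))]

    r2_int = None
    if interactions:
        blocks = [groups[n] for n in names]
        for a, b in interactions:
            if a in groups and b in groups:
                ga, gb = groups[a], groups[b]
                inter = np.hstack([ga * gb[:, [j]] for j in range(gb.shape[1])])
                blocks.append(inter)
        r2_int = r2_of(blocks)

    return VariancePartition(
        total_r2=float(full),
        contributions={n: float(c) for n, c in contrib.items()},
        r2_with_interactions=None if r2_int is None else float(r2_int),
        interactions=tuple(interactions),
        n_cells=len(y),
        dropped_factors=dropped,
    )
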