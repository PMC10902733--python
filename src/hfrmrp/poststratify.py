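"""Poststratification: population-weighted aggregation of the posterior.

Any margin — national, a state, a demographic group, or an intersection —
is a population-share-weighted sum of stratum probabilities, applied draw by
draw so posterior uncertainty propagates into equal-tailed credible
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HFRPosterior
from .strata import PopulationTable, ValidationError, compute_weights


@dataclass(frozen=True)
class HFREstimate:
    """A poststratified proportion with its 95% credible interval."""

    target: dict | None
    year: int
    estimate: float
    lo95: float
    hi95: float

    def __post_init__(self):
        if not (self.lo95 <= self.estimate <= self.hi95):
            raise ValidationError("interval must bracket the point estimate")


def margin_label(target: dict | None) -> str:
    if not target:
        return "national"
    parts = []
    for fld in sorted(target):
        val = target[fld]
        val = val if isinstance(val, str) else "|".join(val)
        parts.append(f"{fld}={val}")
    return "&".join(parts)


def aggregate_draws(
    post: HFRPosterior, pop: PopulationTable, target: dict | None, year: int
) -> np.ndarray:
    """Per-draw weighted estimate for a margin, shape (n_draws,)."""
    sel, w = compute_weights(pop, post.frame, target, year)
    yi = post.years.index(int(year))
    return np.asarray(post.draws[:, sel, yi], dtype=np.float64) @ w


def aggregate(
    post: HFRPosterior, pop: PopulationTable, target: dict | None, year: int
) -> HFREstimate:
    draws = aggregate_draws(post, pop, target, year)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return HFREstimate(
        target=target,
        year=int(year),
        estimate=float(draws.mean()),
        lo95=float(min(lo, draws.mean())),
        hi95=float(max(hi, draws.mean())),
    )


def estimate_panel(
    post: HFRPosterior,
    pop: PopulationTable,
    margins: list[dict | None],
    years: list[int],
) -> pd.DataFrame:
    """Batch aggregation; one row per margin-year, deterministically sorted."""
    rows = []
    for target in margins:
        for year in years:
            est = aggregate(post, pop, target, year)
            rows.append(
                {
                    "margin": margin_label(target),
                    "year": est.year,
                    "estimate": est.estimate,
                    "lo95": est.lo95,
                    "hi95": est.hi95,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["margin", "year"], kind="stable").reset_index(drop=True)


def state_panel(post: HFRPosterior, pop: PopulationTable, years: list[int]) -> pd.DataFrame:
    """Convenience: one estimate per state-year."""
    margins = [{"state": s} for s in post.frame.states]
    panel = estimate_panel(post, pop, margins, years)
    panel["state"] = panel["margin"].str.removeprefix("state=")
    return panel
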