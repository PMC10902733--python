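"""Calibration of the firearm-suicide share as a proxy for ownership.

The proxy is the best linear map FSS -> HFR in the least-squares sense,
fitted over state-years on raw (count-aggregated) FSS. Residuals of that
map — proxy minus HFR, so positive means the proxy overestimates ownership
— are then averaged by state, by demographic group, and by group-year to
expose the systematic biases that make FSS more than a noisy surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strata import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProxyCalibration:
    """OLS intercept/slope of HFR on FSS plus per-unit residuals."""

    intercept: float
    slope: float
    n_units: int
    correlation: float
    residuals: pd.DataFrame      # unit keys, year, fss, hfr, proxy, residual

    def apply(self, fss: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(fss, dtype=float)


def fit_linear_proxy(fss: pd.DataFrame, hfr: pd.DataFrame) -> ProxyCalibration:
    """Least-squares linear transformation of state-year FSS onto HFR.

    ``fss`` needs columns state, year, fss (NaN where undefined); ``hfr``
    needs state, year, estimate. Undefined-FSS state-years are excluded
    with a logged count. The closed form slope = cov(FSS,HFR)/var(FSS) is
    used directly.
    """
    need_f = {"state", "year", "fss"}
    need_h = {"state", "year", "estimate"}
    if not need_f <= set(fss.columns):
        raise ValidationError(f"fss table needs columns {sorted(need_f)}")
    if not need_h <= set(hfr.columns):
        raise ValidationError(f"hfr table needs columns {sorted(need_h)}")
    merged = fss.merge(hfr[["state", "year", "estimate"]], on=["state", "year"], how="inner")
    undefined = merged["fss"].isna()
    if undefined.any():
        log.info("fit_linear_proxy: excluded %d unit(s) with undefined FSS", int(undefined.sum()))
    merged = merged[~undefined].sort_values(["state", "year"], kind="stable").reset_index(drop=True)
    if len(merged) < 2:
        raise ValidationError("need at least 2 units with defined FSS")
    x = merged["fss"].to_numpy(dtype=float)
    y = merged["estimate"].to_numpy(dtype=float)
    var = float(np.var(x))
    if var == 0.0:
        raise ValidationError("degenerate proxy: FSS has zero variance")
    slope = float(np.cov(x, y, bias=True)[0, 1] / var)
    intercept = float(y.mean() - slope * x.mean())
    proxy = intercept + slope * x
    resid = proxy - y                       # positive: proxy overestimates HFR
    corr = float(np.corrcoef(x, y)[0, 1])
    residuals = merged.assign(proxy=proxy, residual=resid)
    return ProxyCalibration(
        intercept=intercept,
        slope=slope,
        n_units=len(merged),
        correlation=corr,
        residuals=residuals,
    )


def proxy_bias_by_state(cal: ProxyCalibration) -> pd.DataFrame:
    """Mean over years of (proxy - HFR) per state; positive = overestimate."""
    out = (
        cal.residuals.groupby("state", as_index=False)["residual"]
        .mean()
        .rename(columns={"residual": "mean_bias"})
        .sort_values("state", kind="stable")
        .reset_index(drop=True)
    )
    return out


def proxy_bias_by_group(
    fss_by_group: pd.DataFrame,
    hfr_by_group: pd.DataFrame,
    cal: ProxyCalibration,
    group_field: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residuals of the state-year calibration applied to group margins.

    ``fss_by_group`` carries group_field, year, fss; ``hfr_by_group``
    carries group_field, year, estimate. Returns (per-group mean bias,
    per-group-year series). Groups with no defined FSS in any year are
    flagged and excluded from the means.
    """
    merged = fss_by_group.merge(hfr_by_group, on=[group_field, "year"], how="inner")
    merged = merged.sort_values([group_field, "year"], kind="stable").reset_index(drop=True)
    all_undef = merged.groupby(group_field)["fss"].transform(lambda s: s.isna().all())
    if all_undef.any():
        bad = sorted(merged.loc[all_undef, group_field].unique())
        log.warning("proxy_bias_by_group: group(s) %s have no defined FSS; excluded", bad)
        merged = merged[~all_undef]
    merged = merged[~merged["fss"].isna()].copy()
    merged["proxy"] = cal.apply(merged["fss"].to_numpy())
    merged["residual"] = merged["proxy"] - merged["estimate"]
    per_year = merged[[group_field, "year", "fss", "estimate", "proxy", "residual"]]
    per_group = (
        per_year.groupby(group_field, as_index=False)["residual"]
        .mean()
        .rename(columns={"residual": "mean_bias"})
    )
    return per_group.reset_index(drop=True), per_year.reset_index(drop=True)
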