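"""End-to-end pipeline: strata -> smoothing -> model -> poststratify ->
decomposition -> proxy calibration, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import io as hio
from .bart import BartSettings
from .decompose import decompose_state_vs_national, decompose_temporal, variance_partition
from .fss import compute_raw_fss, fit_fss_smoother
from .model import (
    EngineSettings,
    assemble_design,
    fit_hfr_model,
    predict_strata_probabilities,
)
from .poststratify import estimate_panel, state_panel
from .proxy import fit_linear_proxy, proxy_bias_by_group, proxy_bias_by_state
from .strata import LEVELS, SURVEY_SMALL, ValidationError, build_strata_frame
from .synthetic import (
    SyntheticConfig,
    generate_population,
    generate_truth_surface,
    simulate_suicide_counts,
    simulate_survey_microdata,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; unknown keys in a config file are errors."""

    seed: int = 20180
    years: tuple[int, int] = (1990, 2018)
    engine: str = "bart"                  # outcome-model engine
    fss_engine: str = "bart"              # smoother engine
    include_fss: bool = True              # smoothed-FSS covariate toggle
    reference_survey: str = SURVEY_SMALL
    symmetric_decomposition: bool = False
    weighted_variance: bool = False
    n_trees: int = 50
    n_burn: int = 300
    n_draws: int = 500
    thin: int = 2
    penalty: float = 1.0
    # input paths; None means synthesize from `synthetic` overrides
    microdata: str | None = None
    population: str | None = None
    suicides: str | None = None
    state_metadata: str | None = None
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.years[0] > self.years[1]:
            raise ValidationError("years range must be ordered")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "years" in raw:
            raw["years"] = tuple(raw["years"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["years"] = list(self.years)
        return d

    def engine_settings(self) -> EngineSettings:
        return EngineSettings(
            engine=self.engine,
            bart=BartSettings(
                n_trees=self.n_trees, n_burn=self.n_burn,
                n_draws=self.n_draws, thin=self.thin,
            ),
            penalty=self.penalty,
            n_draws=self.n_draws,
        )

    def synthetic_config(self) -> SyntheticConfig:
        base = SyntheticConfig(seed=self.seed, years=self.years)
        if self.synthetic:
            overrides = dict(self.synthetic)
            for key in ("small_wave_years", "small_wave_n", "large_years", "large_n", "fss_offsets"):
                if key in overrides:
                    overrides[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in overrides[key]
                    )
            base = replace(base, **overrides)
        return base


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and write all outputs under ``outdir``.

    Returns a dict of in-memory results; identical config + seed reproduces
    every numeric output byte for byte.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    hio.ensure_inputs_exist(
        {
            "microdata": config.microdata,
            "population": config.population,
            "suicides": config.suicides,
            "state_metadata": config.state_metadata,
        }
    )

    def stage(name):
        log.info("pipeline stage: %s", name)

    stage("strata")
    meta = (
        hio.read_state_metadata(config.state_metadata)
        if config.state_metadata
        else None
    )
    frame = build_strata_frame(meta)
    counts["strata"] = len(frame)

    stage("data")
    syn = config.synthetic_config()
    truth = None
    if config.population and config.microdata and config.suicides:
        pop = hio.read_population(config.population, frame)
        micro = hio.read_microdata(config.microdata, frame, config.years)
        suicides = hio.read_suicides(config.suicides, frame)
    else:
        truth = generate_truth_surface(syn, frame)
        pop = generate_population(syn, frame)
        micro = simulate_survey_microdata(truth, pop, syn)
        suicides = simulate_suicide_counts(truth, pop, syn)
        hio.write_population(pop, out / "population.csv")
        hio.write_microdata(micro, out / "microdata.csv")
        hio.write_suicides(suicides, out / "suicides.csv")
    counts["respondents"] = len(micro)
    counts["population_cells"] = pop.counts.size

    stage("smooth-fss")
    smoothed = None
    if config.include_fss:
        smoothed = fit_fss_smoother(
            suicides,
            engine=config.fss_engine,
            settings=config.engine_settings().bart,
            penalty=config.penalty,
            seed=config.seed + 1,
        )
        hio.write_smoothed_fss(smoothed, out / "smoothed_fss.csv")
        counts["smoothed_cells"] = smoothed.values.size

    stage("fit")
    inputs = assemble_design(micro, smoothed, frame, include_fss=config.include_fss)
    counts["design_rows"] = inputs.n
    counts["dropped_records"] = int(sum(inputs.dropped.values()))
    model = fit_hfr_model(inputs, config.engine_settings(), seed=config.seed + 2)
    years = tuple(range(config.years[0], config.years[1] + 1))
    post = predict_strata_probabilities(
        model, frame, years, smoothed, reference_survey=config.reference_survey
    )
    post.save(out / "posterior.npz")
    counts["posterior_draws"] = post.n_draws

    stage("estimate")
    margins = [None] + [{"state": s} for s in frame.states]
    for fld in ("gender", "marital", "race", "urbanicity"):
        margins += [{fld: lvl} for lvl in LEVELS[fld]]
    panel = estimate_panel(post, pop, margins, [years[0], years[-1]])
    hio.write_estimates(panel, out / "estimates.csv")
    counts["estimates"] = len(panel)

    stage("decompose")
    rows = []
    for unit in [None] + frame.states:
        d = decompose_temporal(
            post, pop, unit, years[0], years[-1], symmetric=config.symmetric_decomposition
        )
        rows.append(
            {
                "unit": d.unit,
                "total": d.total,
                "rate_component": d.rate_component,
                "composition_component": d.composition_component,
                "composition_share": d.composition_share,
            }
        )
    decomp = pd.DataFrame(rows)
    hio.write_estimates(decomp, out / "decomposition.csv")

    rows = []
    for st in frame.states:
        d = decompose_state_vs_national(post, pop, st, years[-1])
        rows.append(
            {
                "state": d.unit,
                "difference": d.total,
                "rate_component": d.rate_component,
                "composition_component": d.composition_component,
            }
        )
    hio.write_estimates(pd.DataFrame(rows), out / "state_vs_national.csv")

    stage("variance")
    vp = variance_partition(
        post.mean_surface(),
        frame,
        years,
        weights=pop.counts if config.weighted_variance else None,
    )
    vp_rows = [{"term": "main_effects_r2", "value": vp.total_r2}] + [
        {"term": f"contribution_{k}", "value": v} for k, v in vp.contributions.items()
    ]
    if vp.r2_with_interactions is not None:
        vp_rows.append({"term": "r2_with_interactions", "value": vp.r2_with_interactions})
    hio.write_estimates(pd.DataFrame(vp_rows), out / "variance_partition.csv")

    stage("proxy")
    fss_state = compute_raw_fss(suicides, by=["state"])
    hfr_state = state_panel(post, pop, list(years))
    cal = fit_linear_proxy(fss_state, hfr_state[["state", "year", "estimate"]])
    with open(out / "proxy_calibration.json", "w") as fh:
        json.dump(
            {
                "intercept": cal.intercept,
                "slope": cal.slope,
                "n_units": cal.n_units,
                "correlation": cal.correlation,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    hio.write_estimates(proxy_bias_by_state(cal), out / "proxy_bias_state.csv")
    group_rows, groupyear_rows = [], []
    for fld in ("gender", "marital", "race", "urbanicity"):
        fss_g = compute_raw_fss(suicides, by=[fld])
        hfr_g = estimate_panel(post, pop, [{fld: l} for l in LEVELS[fld]], list(years))
        hfr_g[fld] = hfr_g["margin"].str.split("=").str[-1]
        per_group, per_year = proxy_bias_by_group(
            fss_g, hfr_g[[fld, "year", "estimate"]], cal, group_field=fld
        )
        per_group.insert(0, "field", fld)
        per_year.insert(0, "field", fld)
        group_rows.append(per_group.rename(columns={fld: "group"}))
        groupyear_rows.append(per_year.rename(columns={fld: "group"}))
    hio.write_estimates(pd.concat(group_rows, ignore_index=True), out / "proxy_bias_group.csv")
    hio.write_estimates(
        pd.concat(groupyear_rows, ignore_index=True), out / "proxy_bias_group_year.csv"
    )

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "row_counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "frame": frame,
        "population": pop,
        "truth": truth,
        "microdata": micro,
        "suicides": suicides,
        "smoothed_fss": smoothed,
        "posterior": post,
        "estimates": panel,
        "decomposition": decomp,
        "variance_partition": vp,
        "proxy_calibration": cal,
        "manifest": manifest,
        "outdir": out,
    }
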