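"""Fit the ownership model and poststratify to population estimates.

This example uses the fast ridge-logistic engine; switch to
h.EngineSettings() for the default probit tree ensemble (a couple of
minutes instead of seconds). Estimates are posterior means with equal-tailed
95% credible intervals, and can target any margin: national, one state, a
demographic group, or an intersection.
"""

import hfrmrp as h

frame = h.build_strata_frame()
cfg = h.SyntheticConfig()
truth = h.generate_truth_surface(cfg, frame)
pop = h.generate_population(cfg, frame)
micro = h.simulate_survey_microdata(truth, pop, cfg)
suicides = h.simulate_suicide_counts(truth, pop, cfg)

smoothed = h.fit_fss_smoother(suicides, engine="logistic", seed=cfg.seed + 1)
inputs = h.assemble_design(micro, smoothed, frame)
model = h.fit_hfr_model(inputs, h.EngineSettings(engine="logistic"), seed=cfg.seed + 2)
post = h.predict_strata_probabilities(model, frame, truth.years, smoothed)

for target, label in [
    (None, "national"),
    ({"state": "MT"}, "Montana"),
    ({"gender": "woman"}, "women"),
    ({"gender": "man", "marital": "married", "race": "white_aian",
      "urbanicity": "nonurban"}, "married nonurban white/AIAN men"),
]:
    est = h.aggregate(post, pop, target, 2018)
    tr = h.true_hfr(truth, pop, target, 2018)
    print(f"{label:34s} 2018: {est.estimate:.3f} "
          f"[{est.lo95:.3f}, {est.hi95:.3f}]  truth {tr:.3f}")
# Point estimates should sit within a couple of points of the generator
# truth, with the truth inside the interval for ~95% of margins.
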