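"""Calibrate the firearm-suicide share as a linear proxy for ownership.

The best linear map FSS -> HFR is fitted over the 1,450 state-years; its
residuals (proxy minus HFR, positive = overestimate) reveal the systematic
group biases the generator builds in through method-preference offsets.
"""

import numpy as np
import pandas as pd

import hfrmrp as h

frame = h.build_strata_frame()
cfg = h.SyntheticConfig()
truth = h.generate_truth_surface(cfg, frame)
pop = h.generate_population(cfg, frame)
suicides = h.simulate_suicide_counts(truth, pop, cfg)

# truth surface as the HFR side: isolates the proxy arithmetic
post = h.HFRPosterior(frame=frame, years=truth.years,
                      draws=np.repeat(truth.p[None], 4, axis=0))
fss_state = h.compute_raw_fss(suicides, by=["state"])
hfr_state = h.state_panel(post, pop, list(truth.years))
cal = h.fit_linear_proxy(fss_state, hfr_state[["state", "year", "estimate"]])
print(f"proxy = {cal.intercept:.3f} + {cal.slope:.3f} * FSS "
      f"over {cal.n_units} state-years; r = {cal.correlation:.2f}")

bias = h.proxy_bias_by_state(cal)
worst = bias.reindex(bias["mean_bias"].abs().sort_values(ascending=False).index)
print("\nlargest state biases (positive = proxy overestimates ownership):")
print(worst.head(5).to_string(index=False))

fss_race = h.compute_raw_fss(suicides, by=["race"])
hfr_race = h.estimate_panel(post, pop, [{"race": r} for r in ("other", "white_aian")],
                            list(truth.years))
hfr_race["race"] = hfr_race["margin"].str.split("=").str[-1]
per_group, _ = h.proxy_bias_by_group(fss_race, hfr_race[["race", "year", "estimate"]],
                                     cal, "race")
print("\nrace-group bias (generator gives the minority group a firearm-method preference):")
print(per_group.to_string(index=False))
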