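"""Build the analytic strata frame and compute poststratification weights.

The frame crosses 50 states with binary gender, marital status,
race/ethnicity, and urbanicity; the 7 states without a large densely
populated county contribute only nonurban cells, giving 744 strata.
"""

import hfrmrp as h

frame = h.build_strata_frame()
print(f"analytic strata: {len(frame)}")
print(frame.table.head(4).to_string(index=False))

cfg = h.SyntheticConfig()
pop = h.generate_population(cfg, frame)

sel, w = h.compute_weights(pop, frame, {"state": "MT"}, 2018)
print(f"\nMontana 2018: {len(sel)} strata, weights sum to {w.sum():.12f}")
print("largest stratum share:", round(w.max(), 3),
      "->", tuple(frame.table.iloc[sel[w.argmax()]]))
# Each weight is that stratum's share of the state's adult population and is
# what turns stratum-level probabilities into population estimates.
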