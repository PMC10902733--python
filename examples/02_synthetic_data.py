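"""Generate the synthetic study: truth surface, drifting population,
survey microdata, and sparse suicide counts.

The truth surface is a logistic model with state effects, demographic main
effects, a gender x marital interaction, and a declining year trend; the
population drifts toward urban/unmarried/minority composition, which is
what later makes the composition component of the decline non-trivial.
"""

import hfrmrp as h

frame = h.build_strata_frame()
cfg = h.SyntheticConfig()
truth = h.generate_truth_surface(cfg, frame)
pop = h.generate_population(cfg, frame)
micro = h.simulate_survey_microdata(truth, pop, cfg)
suicides = h.simulate_suicide_counts(truth, pop, cfg)

print(f"respondents: {len(micro)} "
      f"({(micro['survey'] == 'in_person').sum()} in-person, "
      f"{(micro['survey'] == 'telephone').sum()} telephone)")
print(f"true national HFR: {h.true_hfr(truth, pop, None, 1990):.3f} (1990) -> "
      f"{h.true_hfr(truth, pop, None, 2018):.3f} (2018)")

tidy = pop.to_tidy()
for year in (1990, 2018):
    sub = tidy[tidy["year"] == year]
    share = sub.loc[sub["urbanicity"] == "urban", "population"].sum() / sub["population"].sum()
    print(f"urban population share {year}: {share:.3f}")

zero = (suicides.total == 0).mean()
print(f"stratum-years with zero suicides: {zero:.1%} "
      "(the sparsity that motivates smoothing the firearm-suicide share)")
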