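"""Decompose the decline in ownership and partition the surface variance.

The temporal decomposition splits each state's 1990-2018 change into a
within-strata rate component (composition frozen at 1990) and a
composition component; the variance partition attributes the estimate
surface's variance to the six factor groups by LMG/Shapley averaging.
Uses the generator truth as the probability surface so it runs instantly.
"""

import numpy as np

import hfrmrp as h

frame = h.build_strata_frame()
cfg = h.SyntheticConfig()
truth = h.generate_truth_surface(cfg, frame)
pop = h.generate_population(cfg, frame)
post = h.HFRPosterior(
    frame=frame, years=truth.years, draws=np.repeat(truth.p[None], 4, axis=0)
)

d = h.decompose_temporal(post, pop, None, 1990, 2018)
print(f"national change 1990->2018: {d.total:+.3f}")
print(f"  rate component (within strata): {d.rate_component:+.3f}")
print(f"  composition component:          {d.composition_component:+.3f}"
      f"  ({d.composition_share:.0%} of the change)")

d_mt = h.decompose_state_vs_national(post, pop, "MT", 2018)
print(f"\nMontana minus national 2018: {d_mt.total:+.3f} "
      f"(composition explains {d_mt.composition_component / d_mt.total:.0%})")

vp = h.variance_partition(truth.p, frame, truth.years)
print(f"\nmain-effects R^2 of the truth surface: {vp.total_r2:.3f} "
      f"(+gender x marital interaction: {vp.r2_with_interactions:.3f})")
for k, v in sorted(vp.contributions.items(), key=lambda kv: -kv[1]):
    print(f"  {k:11s} {v:.3f}")
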