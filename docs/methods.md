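# Methods

## Estimand and strata

The estimand is HFR: the probability that an adult lives in a household
with a firearm, for each cell of state × gender × marital status ×
race/ethnicity × urbanicity and each year 1990–2018. All five factors are
closed binary/categorical codings; urbanicity distinguishes residence in a
large densely populated county from all other counties. Seven states are
flagged in the packaged metadata as having no such county (AK, ME, MT, ND,
SD, VT, WY — a documented, editable fixture choice: the flag, not the list,
is the rule), so the frame has 43×16 + 7×8 = 744 strata. Strata are ordered
lexicographically on the five fields; the row position is the stable id used
by every array in the package. Washington DC and territories are out of
scope.

## Synthetic study conditions

The generator defines the conditions under which the package demonstrates
recovery; it emulates the *shape* of the real inputs, not their full
complexity.

**Truth surface.** logit p = β₀ + state_s + g·man + m·married +
r·white/AIAN + u·nonurban + γ·(woman & married) + δ·(year − 1990), with
defaults β₀ = −2.45, state effects ~ N(0, 0.5²) (seeded), g = 0.65,
m = 0.70, r = 1.00, u = 0.90, γ = 0.55, δ = −0.012/yr. These give a
national truth of 43.6% in 1990 declining to 30.5% in 2018, top subgroup
(married nonurban white/AIAN men) around 0.6 and bottom subgroup below 0.1 —
realistic levels and gradients. The married-women lift γ makes marriage
matter more for women than men, the one interaction the linear fallback is
given explicitly.

**Population.** State adult populations are deterministic (no sampling
noise): a ×10 log-spaced spread around a mean of 150,000, interleaved across
the alphabet so neighbouring codes differ in size. Cell shares are products
of margins; urban, unmarried, and minority shares drift linearly
(+0.004, +0.005, +0.004 per year from 1990 bases 0.42, 0.40, 0.22),
emulating composition change toward lower-ownership groups. Drift that
would push any share out of (0,1) is a config error, not a clamp.

**Surveys.** 16 in-person waves (1990–2018, biennial after 1994) and 3
telephone years (2001/2002/2004). Desk-scale defaults are 1,400 and 5,000
respondents per wave (37,400 total); `SyntheticConfig.paper_scale()`
restores the published sizes (691,028 telephone + 22,430 in-person =
713,458) for accounting checks only. Respondents are drawn proportional to
stratum population; the telephone survey adds a +0.3 log-odds mode offset,
and truth is defined as the mode-free (in-person) probability. Real survey
design features — clustering, RDD weighting, nonresponse — are not
emulated, so passing tests say nothing about design-effect robustness.

**Suicides.** Totals are Poisson(population × 14/100k) per stratum-year
(~30k events; ~38% of cells have zero events — the sparsity that motivates
smoothing). Firearm suicides are Binomial(total, q) with logit q = 0.8 +
logit(p) + method-preference offsets (+0.40 other race, +0.25 urban, +0.30
unmarried, −0.25 women), making the firearm share a correlated but
systematically biased reflection of ownership.

All generators are deterministic under (seed, config); derived stages use
seed+1 (smoother) and seed+2 (outcome model) so stages are independently
reseedable.

## Posterior engines

**Probit tree ensemble (default).** Sum of 50 trees with the standard
regularisation prior: P(split at depth d) = 0.95·(1+d)⁻², leaf values
N(0, σ_μ²) with σ_μ = 3/(k√m), k = 2; an offset Φ⁻¹(ȳ) centres the latent
scale. Binary outcomes enter via truncated-normal latent augmentation;
binomial cell counts contribute the *sum* of their latent variables, which
is exactly the expanded-record likelihood at cell cost (used by the FSS
smoother; respondent data is the trials-equal-one special case). Trees move
by grow (0.25) / prune (0.25) / change (0.50) Metropolis proposals with the
conventional cancellation of rule priors against rule proposals; cutpoints
are up to 100 quantiles of the observed values per covariate. Default chain:
300 burn-in, 500 kept draws at thinning 2 (1,300 iterations). Kept forests
are stored compactly so the posterior can be evaluated at arbitrary
covariate rows after fitting. Year is a continuous covariate, so trees pool
adjacent years; state enters as 50 indicators; predictions fix the survey
indicator at the in-person level (configurable — the reference mode is a
sensitivity knob, since a mode-free level is an identification choice, not
a fact).

**Ridge-logistic fallback.** Binomial logistic regression with N(0, 1/λ)
priors on all non-intercept coefficients (λ = 1 by default; the intercept is
effectively flat), fitted by Newton iterations with step-halving; the
posterior is approximated as Gaussian at the penalised MLE with
inverse-observed-information covariance, and coefficient draws yield
predictive draws. Because a linear-logistic model cannot represent the
generator's interaction or curvature, the design is augmented for this
engine with a woman×married term and a quadratic year term. The fallback is
used for fast tests and as an agreement cross-check against the tree
ensemble; it is exact only when the truth is close to main-effects logistic.

## Poststratification and intervals

Weights are year-specific population shares within the target margin;
estimates are computed per posterior draw (so any margin's interval is an
exact functional of the joint posterior), with equal-tailed 2.5/97.5
percentile intervals. Equal-tailed rather than highest-density is a
simplicity choice; for the near-symmetric posteriors here the difference is
negligible. Aggregation is linear, so state-then-national equals direct
national aggregation to machine precision — a tested identity.

## Decomposition conventions

The temporal split freezes composition at the start-year weights for the
rate component and defines composition as the remainder, matching the
"composition held constant at 1990" phrasing; a symmetric midpoint variant
is available behind a flag as a robustness check. The state-vs-national
split works over the 16 shared demographic cells: rate = Σ_d w_d^state
(p_d^state − p_d^US), composition = Σ_d (w_d^state − w_d^US) p_d^US. Both
identities hold exactly (floating-point rounding is folded into the
residual component and asserted below 1e-12).

The variance partition fits OLS of the 21,576 posterior-mean cells on dummy
blocks for the six factor groups (year as a categorical block). Per-factor
contributions are LMG/Shapley averages of the marginal R² gain over all
orderings — the standard order-invariant attribution, chosen because any
sequential attribution of correlated factors is ordering-dependent. The
partition is unweighted over cells by default (population weighting is a
flag). A factor with a single observed level (e.g. urbanicity in an
all-urban-free reduced frame) is dropped with a warning.

## Proxy calibration

The proxy is fitted on raw count-aggregated state-year FSS (not smoothed
FSS), because the comparison concerns the measure practitioners can compute
for large populations. OLS of poststratified HFR posterior means on FSS;
HFR uncertainty is not propagated into the fit. Residuals use the
convention proxy − HFR, positive meaning the proxy overestimates ownership;
a group whose suicides are more firearm-intensive than its ownership implies
therefore shows positive bias. State and group biases are unweighted means
over years; group series are reported per year for trend inspection.
Degenerate inputs (constant FSS, <2 defined units) are errors; undefined
units are excluded with a logged count.

## Numerical choices

- Truncated-normal latents are sampled by inverse CDF with the uniform
  clipped to [1e-12, 1−1e-12]; at the |mean| ≤ 4 scales that occur here the
  clipping is inert.
- Smoothed FSS values and posterior draws are clipped to
  [1e-7, 1−1e-7] so strict-(0,1) invariants survive float32 storage.
- Posterior cubes are float32 (500×744×29 ≈ 43 MB); saved as compressed
  `.npz` with a JSON metadata sidecar field.
- The smoothness check on the posterior-mean year profiles treats
  adjacent-year moves below 0.005 as noise when testing that a
  monotone-truth surface does not flip trend direction.
- All CSV outputs are written at full round-trip precision; identical
  config + seed reproduces every numeric output byte for byte.

## Problem sizes

Default test and demonstration sizes — 37,400 respondents, 50 trees, 500
kept draws, 744×29 grid — were chosen so a complete default-conditions run
(smoothing + fit + prediction) takes on the order of two minutes on one
CPU while leaving national recovery error well inside two percentage
points. The generator's `paper_scale()` preset exists only for respondent
accounting; fitting at that scale is unnecessary for any property the
package tests.

## Known limitations

- The Laplace posterior of the fallback engine understates skewness for
  rare outcomes; it is a cross-check, not the reference engine.
- BART interval calibration is demonstrated on the synthetic conditions
  (~92% coverage of stratum-year truth at defaults); real-data coverage
  additionally depends on survey biases the generator does not model.
- The smoothed-FSS covariate is a point surface (posterior mean); its own
  uncertainty is not propagated into the outcome model, mirroring the
  two-stage design.
- Piecewise-constant year effects mean estimates between survey waves move
  in steps rather than smoothly; with the default trend this bias is well
  below interval widths.
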