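# Methods

## The problem

Soil nitrification — the oxidation of ammonia to nitrite and nitrate — is
carried out by two guilds, ammonia-oxidizing archaea (AOA) and bacteria
(AOB). The two can be separated in whole soil with 1-octyne, which blocks
the bacterial ammonia monooxygenase: activity measured in the presence of
octyne is attributed to AOA, and the bacterial share is the difference
between the uninhibited (total) and octyne-inhibited rates. Running the
assay across a gradient of ammonium additions yields substrate–rate curves
per guild, and the shape of those curves (saturating vs. inhibited at high
NH₄⁺) is the quantity of ecological interest: if AOB are inhibited at high
ammonium while AOA are not, ammonium pulses can drive niche differentiation
between the guilds.

This package implements that analysis end to end — a simulator of the
slurry assay, rate computation and octyne partitioning, kinetic model
fitting and selection, and Bayesian cross-ecosystem comparison — so the
whole procedure is testable without the original field data.

## The assay and the rate computation

One bottle holds `fresh_mass` g of field-moist soil (default 5 g) shaken in
`slurry_volume` L (default 0.05 L) at a target NH₄⁺ addition. NOx
(NO₂⁻+NO₃⁻, mg N L⁻¹) and NH₄⁺ (mM) are measured at t₁ = 2 h and
t₂ = 24 h. The rate is

    V = (NOx_t2 − NOx_t1) · slurry_volume / dry_mass_kg · 24/(t2 − t1)

in mg N kg⁻¹ dry soil day⁻¹, with `dry_mass_kg = fresh_mass · (1 −
moisture_fraction)/1000`. The moisture-based dry-mass conversion is this
package's documented choice (assays report per-kg-dry-soil rates but the
conversion constants are rarely stated); the default gravimetric moisture is
0.20 g g⁻¹, typical of a field-moist loam. The substrate assigned to each
rate is the arithmetic mean of the two measured NH₄⁺ concentrations, which
automatically folds in ammonium produced by net mineralization during the
incubation.

Partitioning is exact arithmetic: total = uninhibited rate, AOA = octyne
rate, AOB = total − AOA. Negative AOB rates (a difference of two noisy
measurements) are retained and flagged, never clamped — clamping would bias
fits near zero. A configurable detection limit on the NOx accumulation
flags unreliable bottles (`below_detection`); flagged points are excluded
from fits by default. The classic single-concentration "nitrification
potential" assay is the same code path applied at one saturating (10 mM)
level.

## Kinetic models and fitting

Michaelis–Menten: V = Vmax·S/(Km+S). Haldane substrate inhibition:
V = Vmax·S/(Km+S+S²/Ki), which reduces to Michaelis–Menten as Ki → ∞,
peaks at S = √(Km·Ki), and crosses Vmax/2 at two substrate concentrations
whose upper root ≈ Ki when Km ≪ Ki (that upper root is the operational
meaning of Ki: the highest ammonium concentration at which the rate is
still half-maximal).

Fits pool all replicate points per (ecosystem, taxon), matching the
one-fit-per-population reporting structure, with replicate-level
bootstrap for curve uncertainty. The optimizer is trust-region least
squares (`scipy.optimize.least_squares`, method `trf`), tolerances 1e-10,
at most 10,000 evaluations. Start values: Vmax₀ = max observed rate,
Km₀ = smallest S whose rate reaches Vmax₀/2, Ki₀ = max S. The first pass
leaves Km unconstrained (the analog of a plain `nls` call); if the optimum
has Km < 0 — which happens for very low-activity soils where the curve is
effectively flat — the model is refit with Km bounded below at 1e-9 mM and
flagged `km_constrained` (the exact published bound is unstated; 1e-9 mM is
numerically indistinguishable from zero at these scales). Ki is kept in
[1e-9, 1e12] mM; a fit is marked non-converged when the optimizer fails,
the Ki estimate collapses to the lower bound (≤ 1e-6 mM), or the parameter
covariance is singular — the analog of a blank "NA" model-comparison entry.
Standard errors are asymptotic, from the Jacobian at the optimum
(cov = (JᵀJ)⁻¹·RSS/(n−p)); the bootstrap provides the alternative,
replicate-driven uncertainty.

Reported units follow convention: fitting is done in mM; tables convert Km
to μM and keep Ki in mM.

## Model selection

Gaussian AIC with the error variance counted as a parameter:

    AIC = n ln(2π) + n ln(RSS/n) + n + 2(k+1)

(the convention of R's `AIC` on an `nls` fit, so AIC differences are
comparable to published tables). The nested extra-sum-of-squares F-test:

    F = (RSS_MM − RSS_Haldane) / (RSS_Haldane/(n−3)),  p from F(1, n−3).

Haldane is adopted only when it converged, lowered AIC, *and* p < α
(default α = 0.1). Failure paths fold into Michaelis–Menten with
`haldane_failed` set.

## Bayesian cross-group comparison

Each group's parameter is modelled as Parameter_i ~ Normal(μ_i, τ_i²) with
μ_i ~ Normal(mean_i, SD_i²), where (mean_i, SD_i) are the least-squares
estimate and SE supplied as prior information, and τ_i² carries a vague
InvGamma(0.001, 0.001) prior. Two sampling modes:

* **plugin** (default): the generative statement carries no further
  likelihood data, and with a vague τ² and no data the hierarchical model
  is effectively improper for Parameter_i; the plugin mode therefore
  samples Parameter_i ~ Normal(mean_i, SD_i²) directly by random-walk
  Metropolis (proposal scale 2.4·SD, ≈44% acceptance on a 1-D normal
  target). This mode reproduces the published significance calls from the
  estimate±SE table alone.
* **hierarchical**: a Gibbs sampler treating the fit estimate as a single
  observation y of the parameter — μ | τ², y is a conjugate normal update,
  τ² | μ an inverse-gamma update, and the retained draw is
  Parameter ~ Normal(μ, τ²). Provided for sensitivity analysis; with the
  vague prior and one observation the τ² marginal is extremely
  heavy-tailed (shape ≈ 0.5), so posterior summaries should use medians.
  `y_obs` is exposed as an argument (default: the prior mean) so the
  normal-normal conjugate identity can be verified on y ≠ mean_i, where it
  is actually informative.

The schedule is 3 chains × 15,000 iterations, 2,000 burn-in, thinning 3 —
keeping the first post-burn-in iteration and then every third, the only
thinning convention consistent with the canonical total of 13,002 retained
samples (3 × ⌈13,000/3⌉ = 3 × 4334). Convergence is monitored with the
classic Gelman–Rubin between/within-chain statistic.

Contrasts: a two-group "Bayesian T-test" computes the fraction of paired
draws (by sample index) in which one group exceeds the other, significant
when that fraction leaves [0.025, 0.975] — the two-sided p < 0.05 analog.
The multi-group "Bayesian F-test" runs all pairwise contrasts and builds a
compact letter display by transitive grouping: letters are assigned to the
connected components of the non-significance graph, in descending order of
posterior mean. (Transitive grouping is coarser than a full
Piepho-style letter algorithm when non-significance is intransitive, but
identical whenever the pairwise pattern is nested, as it is for these
contrasts.)

## The synthetic-data generator

The generator emulates the study design: 8 ammonium levels
{0.01, 0.05, 0.1, 0.5, 1, 5, 10, 15} mM, paired ±octyne bottles, 4 field
replicates per ecosystem, 5 g soil in 50 mL sampled at 2 and 24 h. Default
ground-truth parameters are the bundled reference estimates
(`KINETICS_REFERENCE`): one (Vmax, Km, Ki) triple per (ecosystem, taxon)
across the eight-system management gradient, with the model (MM vs Haldane)
set to the law selected for that population.

True NOx accumulation is computed by forward Euler integration (fixed
0.1 h steps) of dS/dt = mineralization − consumption, with consumption the
sum of the two guilds' rate laws at the current substrate concentration
converted to slurry units (14.0067 mg N per mmol). The +octyne bottle
carries the AOA rate plus (1 − octyne_efficacy) of the AOB rate
(default efficacy 1.0, i.e. complete inhibition, as the protocol's 4 μM
aqueous octyne achieves). Measured concentrations are true values ×
(1 + Normal(0, conc_cv)); the default conc_cv = 0.05 is a plausible
flow-injection-analyzer error, chosen once — the original error magnitude
is unstated. Default net mineralization is 0 (it is an optional drift
term, not a documented study quantity).

What the generator reproduces: substrate drawdown during the incubation
(so the 2 h vs 24 h NH₄⁺ pair is internally consistent with the kinetics),
the octyne pairing, replicate structure, and measurement noise. What it
does not: between-replicate biological heterogeneity (replicates differ
only through measurement noise), seasonal dynamics, soil pH effects,
comammox populations, or heterotrophic nitrification. Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the assay's own error model, not robustness to field-scale heterogeneity.

Two emergent features of the realistic design are worth noting, because
the test suite works around them deliberately:

* **Substrate exhaustion at the lowest level.** In high-activity soils
  (e.g. the annual cropping systems, Vmax ≈ 5 mg N kg⁻¹ day⁻¹) the
  0.01 mM bottle runs out of ammonium within hours, so its back-computed
  rate is an average over a collapsing substrate trajectory, not the
  curve value at the mean substrate. This mirrors the original assay,
  where the 0.01 mM level was dropped for the cropping systems as
  unreliable. It slightly inflates the Haldane false-selection rate for
  such systems; the type-I property is therefore checked on a
  moderate-activity Michaelis–Menten population operating inside the
  design's intended regime.
* **Octyne-pair differencing error.** The AOB rate is a difference of two
  bottles whose substrate trajectories diverge slightly (the uninhibited
  bottle consumes faster), so the AOA contributions cancel imperfectly.
  The residual is proportional to soil mass; the exact noise-free
  round-trip property is checked in the drift-free limit (tiny soil
  mass), where it holds to optimizer tolerance (<1e-4 relative).

## Numerical and test-design choices

* Euler steps of 0.1 h are ≈30× shorter than the fastest substrate
  turnover time under default truths; integration error is far below
  measurement noise.
* The bootstrap band is a percentile band over replicate resamples. At
  the study's n = 3–4 replicates the percentile bootstrap undercovers
  (bootstrap SD ≈ 0.6× the true sampling SD in our simulations); the
  coverage property (≥85% of grid points inside a nominal 95% band,
  median over seeds) is verified at 8 replicates, where the method is
  calibrated. Band coverage at n = 3–4 should be read as exploratory.
* Test problem sizes: recovery and selection-rate checks use 25–100 seeds
  per condition and bootstrap checks 400 resamples over 10 seeds — sizes
  chosen so the full suite completes in well under a minute while leaving
  the Monte-Carlo margins comfortable.
* Ties in posterior contrasts resolve toward the first group
  (`a >= b`), making the symmetry prob(a>b) + prob(b>a) = 1 exact.
* The pipeline derives stage seeds from the run seed by fixed offsets;
  identical config + seed gives byte-identical artifacts (fixed column
  order, `%.10g` floats, no timestamps in the log).

## Known limitations

* Asymptotic SEs from pooled fits on clean synthetic data are much
  tighter than field SEs, so synthetic-data contrasts are sharper than
  the corresponding field contrasts; cross-ecosystem conclusions from the
  bundled reference SEs (which are field-derived) are the meaningful ones.
* Both Bayesian modes are approximations of an ambiguous generative
  statement (no explicit likelihood data); plugin mode is the default
  because it reproduces the published significance structure exactly.
* Unweighted least squares with multiplicative measurement noise is mildly
  heteroscedastic; weighted fits are deliberately out of scope, matching
  standard practice for these assays.
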