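# Methods

## The experimental design being modeled

Eight reef-building coral species are each sampled as genetically distinct
colonies (genets) from several of six collection sites (three to five sites
per species, depending on abundance): 30 genets per species, except 22 for
*Montipora flabellata*. Each genet is fragmented into clonal ramets and
distributed over four treatments — control, ocean warming (+2 °C), ocean
acidification (−0.2 pH) and combined — with the constraint that four genets
per species contribute three ramets per treatment and the remainder one,
and no genet places two ramets in the same mesocosm. Each treatment runs
ten mesocosms fed from two header tanks. The full default design is
1184 ramets: 38 per species × treatment for 30-genet species, 30 for the
22-genet species.

The phenotype is the calcification rate over a 63-day assay,
`(w_final − w_initial)/(w_initial · days)` in g g⁻¹ d⁻¹, from buoyant
weights. Negative rates (net dissolution) are legitimate and never clamped.

## Synthetic data

`generate_experiment` draws one effect per genet, site, header tank and
mesocosm from zero-mean Gaussians with the configured variances, adds the
treatment mean (grand mean + temperature + pH + optional interaction
shifts) and a per-ramet residual, then back-computes the final buoyant
weight from a log-normal initial weight. Acclimatization mortality is an
independent Bernoulli(0.015) per ramet, the rate observed in this kind of
year-long husbandry, and is deliberately design-independent: observed
mortality concentrates in the acclimatization phase rather than tracking
treatments. Genet effects are drawn independently of site — site enters as
its own factor, not as a hierarchy over genets.

Default magnitudes: grand mean 2×10⁻³ g g⁻¹ d⁻¹ with treatment shifts of
−6×10⁻⁴ (warming) and −3×10⁻⁴ (acidification), zero interaction (the
additive response seen in seven of eight species); variance components
(1.0, 0.2, 0.1, 0.1, 1.1)×10⁻⁷ for genet, site, tank, mesocosm, residual —
total phenotypic variance 2.5×10⁻⁷ and implied H² = 0.40, the middle of
the 0.23–0.56 range these corals exhibit. Rates of this order correspond
to a few tenths of a percent of skeletal mass per day, consistent with
linear extension of 1–10 cm yr⁻¹.

What the simulator does **not** emulate: seasonal temperature/pH
trajectories (treatments are categorical; the idealized DHW series lives in
the `calcify` module), carbonate chemistry, symbiont communities, spatial
genetic structure among sites, and treatment-linked mortality. Passing
tests therefore demonstrate correctness of the estimators under the
assumed additive Gaussian variance-component world, not robustness to
violations of it.

## Degree heating weeks

NOAA Coral Reef Watch convention on daily series: hotspot = max(0, T − MMM)
against the monthly-maximum-mean climatology; days with hotspot ≥ 1 °C
contribute hotspot/7 to the accumulation (°C-weeks). The 1 °C inclusion
threshold is configurable. A +2 °C anomaly sustained for the 49 days
spanning the assay's seasonal peak accumulates exactly 14 DHW, the thermal
dose of the warming treatments. Gaps in a dated series raise unless
explicitly tolerated (gap days then contribute zero).

## Treatment ANOVA

Sequential (Type I) sums of squares in a fixed term order — temperature,
pH, temperature×pH, site, genet, header tank, mesocosm — each F-tested
against the residual mean square. Nesting (genet in site; mesocosm in tank
in treatment) needs no explicit coding: every term enters as a full
indicator block and its degrees of freedom are the rank increment, which
is exactly the nested df. Type I was chosen because the design is balanced
enough that SS types nearly coincide, and sequential projections make the
df bookkeeping exact under rank deficiency. If the model saturates the
data (residual df ≤ 0, as happens for small samplings), nested terms are
dropped from the back (mesocosm first) with a warning, mirroring the
two-stage fit such data require.

Tukey HSD uses the fitted model's residual mean square and df
(Tukey–Kramer SE for unequal group sizes) with p-values from the
studentized-range distribution; the compact letter display is a greedy
clique cover of the non-significance graph, visiting groups by ascending
mean with label-order tie-breaks.

Dead ramets are excluded before fitting (`alive == 0`); in the source
experiments these are acclimatization deaths, while assay-phase deaths are
retained upstream by simply not flagging them.

## Heritability sampler

Plain Gibbs with conjugate full conditionals: Gaussian for the fixed
effects (near-flat N(0, 10⁸) prior on the standardized scale) and each
random-effect vector (levels are conditionally independent, so each factor
updates as one diagonal-precision block), inverse-gamma for each variance.
Chain settings default to 100 000 iterations, thin 50, burn-in 15 000 —
1700 retained draws. Factor levels are encoded by first appearance, which
makes the chain exactly invariant to relabeling. A non-positive-definite
fixed-effect conditional is retried once with a 10⁻⁸ jitter, then aborts
with diagnostics.

The response is divided by its sample SD before sampling. H² is
scale-free, so this is exact; it decouples prior calibration from
measurement units, and reported chains are mapped back to the original
scale.

**Priors.** The default variance prior is scaled-inverse-χ²(ν = 1,
s² = 0.004), i.e. inverse-gamma(shape 0.5, scale 0.002) on the
standardized scale. Fully vague IG(ε, ε) priors were rejected after a
simulation calibration at the study design: with only 3–5 site levels the
site-variance posterior keeps a fat right tail that inflates the
phenotypic denominator and biases the H² point estimate down by ≈ 0.045;
one pseudo-observation of prior information at a small scale removes most
of that bias (to ≈ −0.015) while being negligible against the data for
well-replicated components (the residual likelihood carries ~75
equivalent observations). The vague prior and the MCMCglmm-style (V, ν)
parameterization remain available (`prior_shape`, `prior_scale`,
`mcmcglmm_prior`). Doubling the default scale moves the H² posterior mean
by well under 0.05 on reference simulations.

Per draw, H² = σ²_G/(σ²_G + σ²_S + σ²_H + σ²_M + σ²_e). The denominator
includes every modeled variance by default ("phenotypic variance" without
exclusions); `h2_denominator="genet+residual"` exposes the narrower
convention. Summaries: posterior mean, kernel-density mode (Gaussian KDE,
Silverman bandwidth, falling back to the mean on a flat density), central
95% interval, ESS and split-chain R̂ (arviz). Temperature×pH is excluded
from the fixed effects by default and available by flag.

Known limitations: with a handful of site levels the site variance is
intrinsically weakly identified and H² uncertainty is genuinely wide; a
single 20 000-iteration chain on one simulated experiment typically spans
±0.2 around the truth. The sampler fits one species at a time; there is no
multivariate animal model.

## Tolerances and the trade-off test

Per genet: mean rate per treatment over its surviving ramets; temperature
tolerance = warming mean − control mean, pH tolerance = acidification mean
− control mean (signed differences; `relative=True` divides by the control
mean as a robustness check). Genets lacking a surviving ramet in any
required treatment are dropped and counted. The trade-off test is a
Pearson correlation between the two tolerance axes with the exact
t-distributed p-value on n − 2 df; the combined treatment plays no role
here (it informs the ANOVA interaction instead).

## Selection projections

Binomial logistic fits parameterize **mortality** (so LD20 = 20%
mortality): IRLS to the maximum-likelihood coefficients, convergence at
log-likelihood change < 10⁻¹⁰ or 100 iterations, observed-information
covariance. Complete separation is detected both by coefficient divergence
(‖β‖ > 50) and by a perfect all-or-nothing fit, either of which aborts
with guidance. LDp = (logit(p) − β₀)/β₁ with a delta-method SE
(cross-checked by Monte Carlo in the tests).

The 1970→2017 LD change is rescaled linearly to the 50-year horizon
(× 50/47); this convention reproduces the published 20.0 DHW headline from
the published LD20 pair (1.30, 20.17). S = R/H² and projected R = H²·S are
computed per Monte Carlo draw (default 100 000): R draws are Gaussian from
the delta-method SE; H² draws come from the posterior when chains are
supplied, else a truncated Gaussian on [0, 1]; non-positive H² draws are
resampled (and counted) before division. R and H² are treated as
independent — they derive from disjoint datasets. The reference selection
differential defaults to the *Montipora capitata* value, the lower
(conservative) of the two species with historical data. The per-draw
identity R = H²·S is exact; a paired-draw mode preserves it through the
round trip S = R/H² → R = H²·S.

`dhw_to_degC` inverts a user-supplied, strictly monotone table of mean
annual DHW accumulation versus sustained warming level by linear
interpolation; out-of-range queries are clamped to the nearest knot and
flagged, never silently extrapolated. No climatology rasters are fetched.

## Pipeline and reproducibility

`run_pipeline` executes simulate → rates → ANOVA/Tukey → H² → tolerances →
projections; every stochastic stage derives its seed as
SHA-256(global_seed:stage) mod 2³¹, so one config value fixes the entire
run and reruns are byte-identical (modulo the recorded wall time). Outputs
carry the SHA-256 of every input file. CSV schemas are strict — errors name
the file, row and offending column.

## Problem sizes used in validation

The test suite runs reduced-but-honest configurations chosen to keep each
calibration statistically meaningful: H² coverage/bias uses 100 replicate
experiments at the full 1184-ramet design with 20 000-iteration chains
(replicates cycling over all eight species so the site-configuration
randomness is averaged over); the ANOVA type-I study uses 500 replicates
with tank and mesocosm variance set to zero, because only then is the
residual mean square the exactly correct denominator for the
treatment-level F test — with tank variance present the test is the usual
approximate mesocosm analysis; the species-ranking check averages six
replicate fits per species. The null-calibration variance choices are part
of the test design, fixed a priori by that argument, not tuned.
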