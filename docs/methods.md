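# Methods

`motomort` implements the analysis chain of an ecological, multi-city study
of motorcyclist road-traffic mortality: cause-of-death classification and
redistribution of garbage codes, completeness-corrected person-years, direct
age standardization, negative binomial mixed-model regression of death
counts on standardized city exposures, and Rubin's-rule pooling across
redistribution draws. A synthetic-data generator emulates the study design
with known ground truth so every stage has a recoverable target.

## Cause classification and redistribution

Motorcyclist deaths are ICD-10 V20–V39 (occupants of two- and three-wheeled
motor vehicles). Other specific road-traffic groups are pedestrians
(V01–V09), bicyclists (V10–V19), car occupants (V40–V49) and a residual
specific group (V50–V86, V90–V98). "Partially defined" road-traffic codes
(default V87–V89, V99) identify a road-traffic death without a road-user
group; "ill defined" external codes (default X59, Y10–Y34) identify not even
the mechanism. Both garbage sets are configurable, as published analyses
rarely print them.

Redistribution is stratified and two-stage. Allocation probabilities are
estimated per (country, sex, 5-year age group, 3-year period) — periods are
calendar blocks from the first study year, with a short remainder joined to
the last full block (2019 joins 2016–18). Stage 1 splits each stratum's
ill-defined deaths between road traffic and other external causes in
proportion to the stratum's observed external-cause composition; stage 2
allocates the partially-defined pool (original plus stage-1 arrivals) across
specific road-user groups in proportion to observed specific counts. Both
stages are multinomial draws, repeated M times (M = 100 in the full design);
each draw conserves the allocated total exactly, integer by integer. A
stratum with no observed specific deaths backs off to (country, sex, age),
then (country, sex), then country; a stratum that is empty even at the
country margin is a hard error rather than a silent drop. Stage 1 can be
disabled (`two_stage=False`) to force all ill-defined deaths into road
traffic, since published descriptions are ambiguous on this point; two-stage
is the default because it keeps both corrections conservative.

Randomness uses one master seed; draw d runs on a substream spawned with key
d, so any draw is reproducible in isolation and results do not depend on how
many draws are requested.

## Person-years and rates

Person-years per stratum are the sum over calendar years of the population
estimate times a year-specific correction factor. The factor is the
estimated completeness of death registration (≤ 1 when registration is
incomplete): with observed deaths D_obs = c·D_true, the rate
D_obs / (c·N) is unbiased for the true rate. Crude rates are
1e5·deaths/person-years. Direct standardization weights age-specific rates
by the WHO world standard population for 2000–2025, packaged as a versioned
YAML file with the published 80–84 and 85+ groups collapsed into 80+ (by
summing) to match the 17-group scheme; weights are normalized to unit sum
before use. An age group with positive standard weight but zero
person-years is an error (the rate is undefined, not zero). The
registration-denominator variant divides draw-averaged deaths by motorcycle
registration-years; cities without registration data are excluded with a
logged notice. Medians and IQRs use linear-interpolation (type-7) quantiles.

## The negative binomial mixed model

Counts y_ci per city × sex × age stratum (pooled over the study period)
follow NB2 (Var = μ + αμ²) with
log μ = x'β + log(person-years) + u_c, u_c ~ N(0, σ²) a city random
intercept. Fixed effects: intercept, country indicators (reference: first
country alphabetically), male indicator (reference female), age-group
indicators (reference 0–4), and the exposure terms. Exposures are z-scored
once over the analysis city set (sample SD, ddof = 1) except the binary
transit indicator, so coefficients are log rate ratios per 1 SD. Strata
with zero person-years are dropped with a logged count.

The marginal likelihood integrates the random intercept per city by
Gauss–Hermite quadrature adapted at the empirical-Bayes mode: the mode and
curvature of the log integrand are found by a damped, globally convergent
Newton iteration (the integrand is strictly concave in u), and 15 nodes are
centered and scaled there. Fifteen mode-centered nodes reproduce a
2001-point trapezoid integration to better than 1e-6 relative even for
cities with thousands of deaths, and moving between 7, 15 and 31 nodes
shifts coefficients by less than 1e-4.

The score is computed analytically as the posterior expectation of the
complete-data score at the quadrature nodes, and the observed information by
Louis' identity (expected complete-data Hessian plus posterior variance of
the complete-data score), verified in the tests against numerical
differentiation. Optimization is L-BFGS-B on (β, log α, log σ) with bounds
log α ∈ [−12, 5], log σ ∈ [log 1e-3, 2], relative function tolerance 1e-9
and gradient tolerance 1e-6; starting values come from a fixed-effects NB2
fit (statsmodels), with one deterministic perturbed restart on failure. The
fit is fully deterministic and the achieved likelihood is checked against
the start. σ can be fixed at 0, which collapses the model to fixed-effects
NB2; this path is cross-checked against statsmodels to 1e-5.

The cluster-robust variance is the sandwich A⁻¹BA⁻¹ with A the observed
information of the marginal likelihood, B the sum of per-city marginal score
outer products, and a g/(g−1) finite-cluster factor. It is applied on the
mixed model by default; the model-based A⁻¹ is also reported.

## Rubin pooling and the model set

Each redistribution draw is fitted separately; per exposure, the pooled
log-RR is Q̄ (mean), total variance T = W + (1+1/M)B with W the mean
within-draw variance and B the between-draw sample variance, and degrees of
freedom (M−1)(1 + W/((1+1/M)B))², infinite when B = 0 or M = 1. The classic
Rubin df is used rather than the Barnard–Rubin small-sample correction: at
M = 100 (or even 20) the difference is negligible. Intervals are t-based on
the log scale and exponentiated. Pooling requires at least 90% of draws to
converge (the count of excluded draws is reported); fewer is a hard error,
so draws can never be dropped silently.

Model 1 fits one exposure at a time (adjusting for country, sex, age);
Model 2 includes all exposures simultaneously, with collinearity diagnostics
(condition number, VIF) logged because two exposures are strongly
correlated by design. The registration subanalysis restricts to cities with
motorcycle registration data (refusing below 10), z-scores the motorization
rate within that subset, and reruns both model forms. The street-layout
sensitivity analysis refits Model 2 on subsets of the four interrelated
street variables, with terms in canonical order so the full subset
reproduces Model 2 exactly. The city random intercept is retained in every
model form uniformly.

## Descriptive surfaces

Cities are assigned to quartiles of the age-standardized rate by rank, so
group sizes differ by at most one (337 cities → 84/84/84/85) and membership
is invariant under monotone transforms. The between-quartile Wald test
regresses the rank-based inverse-normal (Blom) transform of each exposure on
three quartile indicators and jointly tests those coefficients with HC3
covariance; the named test is underdetermined in published descriptions
(trend tests and ANOVA F are alternatives), so this operationalization is
deliberately documented. The within-country ICC uses unbalanced one-way
ANOVA variance components on log rates (flag for the natural scale), with a
negative between-country component truncated at zero. Pearson correlations
are pairwise-complete, banded weak/moderate/strong at 0.3/0.6.

## The synthetic generator

The generator emulates: ~300 cities in 7 countries observed 2010–2019; city
populations lognormal (median 300k, log-SD 0.8, floor 100k) with a fixed age
pyramid and 1%/year growth; 11 exposures from a Gaussian copula with
configurable target correlations (default: patch density × intersection
density 0.7) and lognormal/normal/Bernoulli marginals of realistic
magnitudes; motorcyclist counts NB2 (α = 0.5 yearly) around a log-linear
model with per-SD effects, country offsets (SD 0.13, keeping the
within-country ICC of standardized rates near 0.1) and a city intercept
(SD 0.3); a male/female baseline ratio of 8 with a piecewise-constant age
profile peaking at 20–24; other road-user groups at fixed multiples of the
motorcyclist baseline, sharing the city profile (the exposures describe road
environment common to all road users); flat non-traffic external rates; and
per-city registration completeness drawn from U(0.85, 1), applied as
binomial thinning of deaths with the true completeness written to the
correction-factor file.

Garbage coding is designed around the identifying assumption of
composition-based redistribution: ill-defined miscoding hits every external
death at the same rate (1−s)·p regardless of true cause, and
partially-defined miscoding additionally hits road-traffic deaths at rate
s·p/ρ (ρ = expected road-traffic share of external deaths), so the overall
garbage fraction among external deaths equals the configured p (default
0.11, split parameter s = 0.5) and the two-stage estimator is unbiased in
expectation. An optional gradient makes garbage propensity decrease with
the city's social-environment z-score, which biases complete-case analysis
but not redistribution — used to demonstrate the value of redistribution.
A small residual attenuation remains because allocation probabilities are
country-level while true compositions vary by city; simulation places it
below half a standard error at 98 cities.

What the generator does not emulate: spatial structure, time-varying
exposures or rates, individual risk factors, non-multiplicative age–sex
interactions, and realistic marginal distributions of every exposure
(quartile tables of synthetic exposures are not expected to match any
published table). Passing tests therefore demonstrate internal statistical
correctness of the chain, not external validity on real vital-registration
data.

## Problem sizes used in the test suite

The recovery study runs 100 replicates of 98 cities (7 × 14) with M = 20
draws at true RR 0.88/SD, σ_city = 0.3, α = 0.5, p = 0.11; the type-I study
runs 200 replicates of 84 cities with M = 10 on a null exposure; the
determinism check runs the full pipeline twice at 42 cities with M = 20.
These sizes keep the default suite fast while leaving the statistical
conditions untouched. The acceptance script runs the default 301-city
scenario with M = 20 draws.

## Known limitations

Model-based and cluster-robust standard errors are both mildly
anti-conservative below ~50 cities, and more noticeably so for city-level
exposures with strongly skewed distributions, where a few high-leverage
cities dominate the sandwich (small-sample leverage corrections such as
Bell–McCaffrey are not implemented); the quadrature's per-city adaptation
assumes a unimodal integrand (guaranteed here by concavity); the Wald
quartile test and the ICC scale are documented choices among several
defensible ones; and the redistribution's country-level probabilities
attenuate city-level contrasts slightly, an inherent property of the method
rather than of this implementation.
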