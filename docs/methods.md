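# Methods

This note documents the models, default parameters and numerical choices
behind `hydrotraits`, and what the synthetic-data generator does and does
not emulate.

## Vulnerability curves

Percent embolism as a function of xylem water potential Ψ (MPa, negative)
is modelled as a two-parameter sigmoid,

    PE(Ψ) = 100 − 100/(1 + e^{a(Ψ − b)}),

with `b` the water potential at 50% embolism (P50) and `a` (MPa⁻¹,
negative) the steepness. Equivalently, individual conduit thresholds are
logistic with median `b` and scale 1/|a|; the generator samples event
thresholds from exactly this distribution via the closed-form inverse
Ψ_u = b + ln(u/(1−u))/a. Reference points Px (P12, P50, P88) use the same
inverse.

**Fitting.** Nonlinear least squares on the cumulative trace, all points
weighted equally. Initialisation: b₀ = first Ψ crossing 50%; a₀ from the
empirical 20–80% spread. Up to five deterministically jittered restarts
(fixed internal seed) before declaring non-convergence; a fitted a ≥ 0 is
rejected as non-physical. Traces that never span both tails (< 20% and
> 80% cumulative embolism) are flagged *poorly constrained* rather than
rejected.

**Standard error of P50.** Cumulative traces are empirical CDFs: their
residuals are strongly autocorrelated, so the usual nonlinear-LS covariance
underestimates the sampling variance of `b` severely (by an order of
magnitude at n = 2000 events). When the total event count n is known, the
reported `b_se` is instead the asymptotic SE of the median of n logistic
draws, 2/(|a|·√n). In seeded simulations this matches the across-replicate
spread of the estimate well (e.g. 0.011 nominal vs 0.009 empirical at
a = −4.03, n = 2000); the covariance-based value is used only as a
fallback when n is unknown.

**Species curves** average fitted parameters arithmetically across leaves
(SE = sd/√n), rather than pooling raw traces: the reported per-species
mean ± SE of P50 and slope implies parameter-level averaging. P12/P50/P88
are evaluated at the mean parameters.

## Optical embolism quantification

Frame differencing counts pixels whose absolute intensity change exceeds a
configurable threshold (no claimed default: real thresholds depend on
camera and illumination; synthetic stacks use clean intensity steps).
Artefact removal — manual in bench practice — is replaced by a
deterministic rule: drop events below 2 pixels and above the 0.995
quantile of nonzero event sizes (both configurable). Water potential is
aligned to frames by linear interpolation of the psychrometer log in time
(10-min log vs 5-min frames); constant-endpoint extrapolation is allowed
up to one log interval and anything further raises. Cumulative percent
embolism is the running sum of kept pixels over the total, so a complete
trace ends at exactly 100%. No spatial connected-component analysis is
performed by default (pixels, not components, are counted).

## Pressure–Volume analysis

The symplastic linear-elasticity model underlies both the generator and
the trait extraction:

    Ψ = Ψs + Ψp,  Ψs = −Ψ_osm/R,  Ψp = max(0, Ψ_osm − ε(1 − R)),

with R the (symplastic) relative water content, Ψ_osm > 0 the magnitude of
the osmotic potential at full turgor, and ε the bulk elastic modulus. Its
turgor loss point is the closed form TLP = −Ψ_osm/(1 − Ψ_osm/ε), used as
the analytic oracle throughout the tests.

**Turgid mass** comes directly from a Ψ = 0 point when present, otherwise
from OLS extrapolation of mass on Ψ over points wetter than −1 MPa (≥ 3
required; fallback: maximum fresh mass). Apoplastic water is assumed zero
in extraction (symplast = total), the same simplification the generator
uses by default; a nonzero apoplastic fraction is supported in the
generator to probe robustness.

**Tail detection.** On (d, 1/Ψ) with d = 1 − RWC, the post-turgor region
is exactly linear under the model. The inflection is located in two
deterministic passes: (1) the largest dry-end suffix (≥ 3 points) whose
OLS fit reaches r² ≥ 0.99 (configurable); (2) a wet-end trim that drops
the wettest tail point while its residual exceeds 3× the RMSE of the fit
through the remaining points. The trim is needed because r² is
scale-blind: for some parameter combinations it happily absorbs one or two
pre-turgor points at high leverage, which would bias the osmotic
intercept. On noiseless model data the surviving tail is exactly the
post-turgor region and all three traits are recovered to better than 1e-6
relative error.

**Traits.** Ψ_osm = −1/intercept of the tail line; TLP is the Ψ of the
wettest tail datum (breakpoint datum) by default — the analytic
two-segment intersection is available via `tlp_rule="intersection"`, the
choice between the two being genuinely open; ε is the OLS slope of turgor
pressure (Ψ − Ψs) against RWC over the pre-turgor points (a regression
pools all ΔP/Δ(V/V) pairs), reported missing below 3 such points.

Note the breakpoint-datum convention quantises the TLP to the measured
drying grid: its error under noise is a step function of tail
misdetection, while Ψ_osm and ε degrade smoothly.

## Safety margins and predicted percent embolism

HSM = Ψ_min − Px and SSM = TLP − Px share the same arithmetic; the sign
convention makes margins positive when the plant operates above the
threshold and reproduces the published negative dry-period margin of the
most vulnerable species. PPE applies the species-mean curve to each
individual's Ψ_min and then averages: for steep curves the mean of the
transform differs materially from the transform at the mean Ψ (a factor
> 3 for the steepest species in this community), which is why the
individual-level definition is used. The SSM standard error, where
reported, is the propagated √(SE_TLP² + SE_P50²) — a convention, since
within-species pairing of PV and OV leaves is not defined.

## Statistical layer

GLMs use the Gaussian family with a log link, fitted by IRLS
(statsmodels). Damage responses are percentages that can touch 0 and 100,
so they are clamped into [0.5, 99.5] before fitting and the clamp is
recorded on the fit. AIC uses the Gaussian log-likelihood with per-model
estimated dispersion; McFadden R² = 1 − ℓ_model/ℓ_null with the same
likelihoods (an unusual statistic for Gaussian models, documented rather
than endorsed); deviance explained = 1 − residual/null deviance. VIF comes
from the linear design including the intercept; it is 1 by convention for
single-predictor models, which are therefore never excluded. Model
enumeration covers all predictor subsets of sizes 1..3 in deterministic
order (92 formulas for 8 traits); ties on AIC break towards fewer
predictors, then lexicographic order. Fits with ≤ 1 residual degree of
freedom are flagged *saturated-regime*: with five or six species and three
predictors the near-unity fit statistics carry little information, and the
pipeline surfaces the flag as a warning instead of suppressing the fits.
Compact letters for Tukey HSD use greedy insert-and-absorb; only the
letter-sharing structure is meaningful, not the labels.

## Standardized Precipitation Index

Trailing sums over a 12-month window (configurable) are transformed
through H(x) = q + (1−q)·GammaCDF(x), with q the zero fraction and the
gamma fitted by maximum likelihood with location pinned at 0, then mapped
through the standard-normal quantile function. One pooled fit across all
windows is the default (a single long-term SPI-12 trace); per-ending-month
fitting is available for strict standards compliance when seasonality
matters. Records shorter than 30 windows warn.

## Synthetic generator: what it emulates, and what it does not

Defaults mirror the bench and field protocols of the thicket study:
images every 5 min, psychrometer log every 10 min, linear bench drying at
0.06 MPa h⁻¹ (a full curve takes roughly 2–6 days depending on xylem
resistance; an exponential trajectory is available since the real drying
law is unrecorded), 2000 one-pixel embolism events per leaf (total pixels
define 100%), 15-point PV series with the full-turgor and turgor-loss
points on the grid and ~half the points beyond turgor loss, drying to
1.5× |TLP|, leaves of 0.2 g dry mass holding 0.3 g water at saturation,
≥ 6 individuals per species per field period with Ψ_md ~ Normal truncated
at −0.01 MPa, and site-like rainfall (monthly Gamma(2, 14) ≈ 338 mm yr⁻¹,
with optional reduced-scale drought blocks). Species-level parameters
default to the published trait table of the six-species community; two
unreported entries (the dry-period Ψ_min and Huber value of one species)
are filled with plausible values and marked as synthetic fills in
`hydrotraits.reference`.

Damage surveys are generated as clip(exp(Xβ), 0, 100) plus Gaussian
observer noise averaged over two observers — deliberately the same
log-link form as the analysis GLM, which makes coefficient recovery a
well-posed test of the fitting machinery rather than of model
misspecification.

Not emulated: leaf optics and texture (image stacks are clean intensity
steps, so differencing is exact), psychrometer physics, registration
errors or leaf movement (artefact filtering is exercised on constructed
inputs instead), apoplastic-water effects by default, and any weather
structure beyond i.i.d. gamma months. Passing tests therefore demonstrate
the correctness of the estimators on data obeying the stated models, and
their noise robustness at bench-realistic noise levels — not performance
on real imagery with movement artefacts or on real rainfall with
persistence.

## Problem sizes

The test suite and acceptance computations use the study-scale defaults:
6 species × 3 leaves for curves, 2000 events per leaf, 15-point PV series,
8–10 individuals per species, 100-replicate recovery simulations, and
40–60-year rainfall records. A full synthetic pipeline run completes in a
few seconds on one CPU.

## Known limitations

Tail detection needs ≥ 3 post-turgor points and a clean osmotic region;
heavy balance noise (≳ 5 mg on a 0.3 g water column) can wash out the
linear region entirely, which raises rather than returning a biased fit.
The compact-letter algorithm is greedy and may use more letters than the
minimum for pathological significance patterns. McFadden R² for Gaussian
GLMs can be negative in principle for badly misspecified models; it is
reported as computed. The SPI gamma fit is pooled by default, which blurs
seasonality in strongly seasonal climates.
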