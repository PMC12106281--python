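# hydrotraits

Drought-physiology trait analysis for woody plants: from raw leaf-drying
observations to xylem vulnerability parameters, Pressure–Volume traits,
safety margins, predicted percent embolism, and trait–damage model
selection — with a synthetic-data generator that provides ground-truth test
beds for every stage.

The package is aimed at plant ecophysiologists working with the optical
vulnerability (OV) technique and bench-drying Pressure–Volume curves, and is
parameterised throughout by the trait values of six dominant woody evergreen
species of South Africa's Albany Subtropical Thicket.

## What it computes

**Xylem vulnerability curves.** Embolism events detected as pixel changes
between sequential images of a dehydrating leaf are cumulated, aligned to a
psychrometer log of water potential Ψ, and fitted with the sigmoid

    PE(Ψ) = 100 − 100 / (1 + e^{a(Ψ − b)}),

where *b* is the water potential at 50% embolism (P50, MPa) and *a* (MPa⁻¹)
the sensitivity to declining Ψ. P12 and P88 follow from the closed-form
inverse Ψₓ = b + ln(x/(100−x))/a.

**Pressure–Volume traits.** On the transformed plot 1/Ψ vs water deficit
(1 − RWC) the post-turgor-loss region is linear; the analysis finds that
region deterministically and reads off the osmotic potential at full turgor
(Ψ_osm, from the intercept), the turgor loss point (TLP, breakpoint datum),
and the bulk elastic modulus ε = ΔP/(ΔV/V) (OLS slope of turgor pressure
vs RWC before turgor loss).

**Safety margins and predicted embolism.** Hydraulic safety margin
HSM = Ψ_min − Px, stomatal safety margin SSM = TLP − Px, and predicted
percent embolism (PPE) — the species-mean curve evaluated at each
individual's minimum water potential, averaged at the individual level.

**Statistics.** Trait ANOVA with Tukey HSD compact letters, paired period
comparisons, single-trait OLS, and exhaustive Gaussian log-link GLM
selection over all trait combinations up to three predictors, ranked by
AIC with Akaike weights and screened for collinearity (VIF ≤ 10).

**Climate.** The 12-month Standardized Precipitation Index via a gamma fit
to rolling rainfall sums.

## Worked example

```python
from hydrotraits.synthetic import GeneratorConfig, gen_embolism_campaign, gen_pv_series
from hydrotraits import optical, vulnerability as vc
from hydrotraits.pressure_volume import extract_pv_traits
from hydrotraits.hydraulics import ssm
from hydrotraits.pipeline import default_species_params

species = {p.name: p for p in default_species_params()}
euclea = species["Euclea"]          # resistant xylem, rigid leaves

# one simulated optical-vulnerability drydown (2000 embolism events)
events, psych, meta = gen_embolism_campaign(euclea, GeneratorConfig(seed=1))
trace = optical.trace_from_events(events, psych)
fit = vc.fit_sigmoid(trace["psi_mpa"], trace["cum_pct"], n_events=meta["n_events"])
print(f"a = {fit.a:.2f} MPa^-1, P50 = {fit.b:.2f} ± {fit.b_se:.3f} MPa")

# one simulated bench-drying Pressure-Volume series
table, m = gen_pv_series(euclea, GeneratorConfig(seed=1))
traits = extract_pv_traits(table["fresh_mass_g"], table["psi_mpa"], dry_mass=m["dry_mass"])
print(f"TLP = {traits.tlp:.2f} MPa, eps = {traits.eps:.2f} MPa")
print(f"SSM = {ssm(traits.tlp, fit.b):.2f} MPa")
```

prints

```
a = -2.25 MPa^-1, P50 = -8.02 ± 0.020 MPa
TLP = -3.82 MPa, eps = 12.43 MPa
SSM = 4.20 MPa
```

i.e. the fitted curve recovers the species' true parameters (a = −2.23,
P50 = −8.02), the PV analysis recovers the turgor loss point exactly, and
the stomatal safety margin of 4.20 MPa says this species closes its stomata
more than 4 MPa before its xylem reaches 50% embolism.

A full end-to-end run (all six species, every stage, every output table):

```sh
hydrotraits pipeline --seed 0 --out out/
```

Per-stage subcommands (`simulate`, `ov`, `vc-fit`, `pv-fit`, `margins`,
`spi`, `damage-models`) operate on the same flat CSV formats; see
`hydrotraits --help`.

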