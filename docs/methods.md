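# Methods

`pelagicbarite` implements the quantitative chain used to diagnose pelagic
barite (BaSO₄) precipitation in a strongly barite-undersaturated, low-sulfate
water column: phase partitioning of particulate Ba, isotope mass balance for
the excess phase with Monte Carlo uncertainty, a minimal thermodynamic model
of particle-microenvironment saturation, and the paleo/flux arithmetic that
the empirical isotopic offset enables. This note records the models, the
parameters that matter, and the choices made where the design was open.

## Ingest and blank correction

Filter leachates arrive as per-filter amounts (nmol) with the filtered
volume (L). The blank correction subtracts, per element, the larger of the
dipped blank or the mean of the two process blanks:

    corrected = raw − max(dipped, mean(process₁, process₂))

The blank term's uncertainty (default 12% RSD, 1σ) is propagated scaled by
the magnitude of the correction actually applied, added in quadrature to the
analytical term (per-element RSD defaults: 3% for Al/Ba/Ca/Fe/Mn/P/Sr/Y,
8.5% for Cd/Ti/V, 1σ; all configurable). Negative corrected values are
**flagged, never clipped**, so downstream consumers decide. Concentrations
are amount/volume in nM, relative uncertainties combined in quadrature.
Depth is positive downward; profiles are sorted ascending at ingest. Pooled
isotope samples carry an explicit depth range and are attributed to its
midpoint. Profile CSVs are written with `%.17g` and parsed with pandas'
round-trip float converter, so write→read is bit-identical.

## Phase partitioning

Measured particulate Ba decomposes as

    pBa_XS = p[Ba] − p[Fe]·(Ba/Fe)_litho − p[P]·(Ba/P)_bio

with defaults (Ba/Fe)_litho = 2.87 mM:M and (Ba/P)_bio = 0.44 mM:M. The
ratio 2SDs are configuration (default 10% relative), not measured truth.
The three components close exactly to the measured value at every depth;
negative excess is retained and flagged, entering integrals but excluded
from isotope statistics by the f_XS > 0.2 filter. Depth-integrated excess
fractions use trapezoidal integration on the native grid — no regridding.

Organic-matter attenuation is summarized by fitting
p[P](z) = p[P]_ref (z/z_ref)^b below the p[P] maximum (shallower depth on
ties), by ordinary least squares in log–log space with a free intercept;
b is the slope and R² refers to the transformed regression. A free
intercept keeps b unbiased by noise in the single reference measurement;
the fit is exact on noiseless power laws either way. Benthic-nepheloid
samples are excluded by default. The p[P] gradient uses centered
differences on the nonuniform grid (one-sided at the ends); negative
values mean attenuation.

## Isotope mass balance and Monte Carlo

δ¹³⁸/¹³⁴Ba is per-mil versus NIST SRM 3104a. The supported pool combines
the lithogenic (+0.02 ± 0.05‰, 2SD) and organic-matter (−0.02 ± 0.08‰,
mean ± range) endmembers weighted by abundance; the excess phase follows
from two-component unmixing, δ_XS = (δ_meas − f_supp δ_supp)/f_XS.

Uncertainty is propagated by joint Monte Carlo (default 100,000 draws,
mandatory seed recorded in outputs). Gaussian perturbations use
σ = half the quoted 2SD; the bio endmember, quoted as mean ± range, is
drawn uniformly over the range. The normalizing ratios and endmember δs
are perturbed **globally per draw** (shared by all depths); measured
concentrations and δ per depth. Draws with f_XS ≤ 0 are excluded from the
δ distribution but counted, so the validity rate is auditable; depths with
more than half the draws invalid are flagged unreliable. Central values
are draw medians (the deterministic point evaluation is also emitted);
per-depth spreads are 2SD of draws, while the cross-sample mean offset
reports 2SE. The mean offset statistic is the unweighted mean of δ_XS over
samples with f_XS > 0.2, minus the dissolved δ; whether a weighted mean
would be preferable is undecidable from the available description, so the
unweighted convention is used and stated. Group comparisons (e.g.
nepheloid vs overlying particles) use a two-tailed unpaired t-test
(equal-variance by default, Welch optional); the degenerate zero-variance
equal-mean case returns p = 1 by convention.

## Saturation model

The speciation model is intentionally minimal for dilute lake water:

- ionic strength I = ½ Σ cᵢzᵢ²;
- Davies activity coefficients, log₁₀γ = −A z² (√I/(1+√I) − 0.3 I), with
  A(T) quadratic in temperature (0.4913 at 0 °C to ≈0.509 at 25 °C);
  a warning is logged above I = 0.5 mol/L;
- free-ion concentrations equal totals — **no ion pairs**;
- barite log₁₀Ksp linear in T (positive slope: solubility rises mildly
  with temperature), anchored at −9.97 at 25 °C with the slope calibrated
  so the shipped ambient preset gives Ω = 0.02 exactly at 4.3 °C
  (log₁₀Ksp(4.3 °C) = −9.9995). A naive van't Hoff slope
  (ΔH ≈ +6.35 kcal/mol) overcorrects and would put the ambient lake at
  Ω ≈ 0.04; since this model omits ion pairing, the calibration also
  absorbs that small speciation correction. The preset file carries the
  note.

The ambient preset (data/lake_superior.yaml) uses literature dilute-lake
major ions (I ≈ 1.46 × 10⁻³ mol/L, charge-balanced to ~1%), 69.7 nM Ba,
40 µM sulfate, 4.3 °C, pH 8.11. pH and carbonate chemistry are held fixed
throughout; respiration-driven CO₂ release is out of model.

The titration finds the smallest x_P (mol P remineralized per liter) at
which Ω reaches 1, releasing Ba at Ba:P = 0.44 mM:M and sulfate at S:P
between 1.0 and 2.5 M:M, in three scenarios (both ions, sulfate only,
Ba only). Each divalent ion arrives with two inert monovalent
counter-ions, so ionic strength (hence γ) evolves realistically and is
recomputed at every trial; a `freeze_gamma` mode holds γ at ambient,
which reduces the problem to a closed-form quadratic used as the test
oracle. Root finding is bracketing (geometric expansion) plus Brent's
method to 10⁻⁹ relative; results are bracket- and tolerance-insensitive
at the 10⁻⁶ level.

With γ recomputed, the both-ion scenario reaches saturation with 92.7%
(S:P = 1.0) to 95.1% (S:P = 2.5) of sulfate and 66.2–76.1% of Ba derived
from remineralization; with γ frozen the corresponding figures are
92.1–94.5% and 63.5–74.7%. The ~1-point spread between the two treatments
is the signature of the no-ion-pairing Davies substitution for a full
speciation code and should be read as the model's structural uncertainty
on these percentages. The single-ion multipliers are more sensitive
still: this model gives ≈6.6× (sulfate-only) and ≈15.4× (Ba-only) at
S:P = 1.0, whereas full-speciation calculations report 12–20× and
14–21×; the multipliers are reported and flagged, not calibrated.

## Paleo inference and budgets

Source inference: δ_source = mean(δ_barite) − Δ, uncertainties in
quadrature, with the ±-range endpoints returned. Direct arithmetic on the
rounded inputs (−0.05‰ barites, Δ = −0.41‰) gives +0.36 ± 0.09‰; accounts
working from unrounded inputs print +0.37‰ — the package reports what it
computes.

Flux arithmetic: OM-associated Ba flux = PP/(C:P)·(Ba:P); the barite
precipitation flux divides by the remineralized-source fraction of barite
Ba (0.67–0.75, the complement of the 0.25–0.33 dissolved-source fraction —
both carried explicitly); burial multiplies by preservation
(1 − 0.75 regenerated); areal fluxes use 137.327 g/mol and a configured
basin area (Lake Superior default 8.21 × 10¹⁰ m²). Ranges propagate by
evaluation at interval endpoints — deliberately order-of-magnitude, with
no distributional assumption. For the lake (PP = 1–7 × 10¹² mol C/yr,
C:P = 379) this gives 1.2–8.1 × 10⁶ mol Ba/yr OM-associated and
0.06–0.51 µg Ba cm⁻² yr⁻¹ buried; closing a 3.4 × 10⁹ mol/yr removal with
marine C:P = 106 requires 2.2–2.5 × 10¹⁵ mol C/yr.

## Synthetic stations

The generator emulates the structure the analysis assumes, with known
truth serialized beside every table: a linear epilimnion ramp in p[P] to
its maximum (default 60 nM at 18 m) and power-law decay below (default
b = −0.75); p[Fe] as a 20 nM lithogenic background plus a Gaussian
benthic-nepheloid bump (150 nM at 140 m, width 8 m); an excess-Ba layer
proportional to −dP/dz displaced 7 m below the P peak (emulating the
observed 6–8 m offset), peaking at 0.08 nM so total particulate Ba is
~0.1–0.3% of the 69.7 nM dissolved pool, as observed; p[Sr] set so the
supported phases have a lithogenic-like Ba:Sr of 1.3. Particulate Ba and
δ are assembled from the phases by exact mass balance (default δ_XS
truth −0.18‰), so the noiseless generator→analyzer loop is an identity —
the closure every exactness test relies on. Noise is multiplicative
lognormal on concentrations (default σ = 3%) and additive Gaussian on δ
(0.03‰), and the stated per-depth uncertainties equal the generating
noise, so reported intervals are interpretable.

What the generator does **not** emulate: real vertical covariance
structure, element-to-element error correlation, advection/resuspension
beyond a single Gaussian nepheloid, seasonal evolution, or any ecology.
Passing tests therefore demonstrate correctness of the estimators under
the assumed structure, not robustness to violations of it.

## Problem sizes and numerical choices

Tests run the Monte Carlo at 10⁵ draws where a 2% comparison against
closed-form propagation requires it, and at 2 × 10³ draws in the
200-seed coverage sweep, where the compared quantity is interval
coverage rather than the interval width itself; parameter-recovery
sweeps use 100 seeds, and the source-δ round trip 1000 seeded sets. The
round-trip interval is dominated by the quoted offset uncertainty
(±0.09‰) rather than set scatter, so its coverage is conservative.
Titration tolerances are 10⁻⁹ relative (asserted at 10⁻⁶); partitioning
closure is exact by construction and asserted at machine precision.

## Known limitations

- No carbonate-system, redox, or ion-pair speciation; no nucleation
  kinetics or reaction–diffusion microenvironment geometry. The titration
  bounds ion provenance at saturation; it says nothing about absolute
  rates or aggregate volumes.
- The saturation percentages carry ~1 point of structural uncertainty
  from the activity model; the single-ion multipliers are only
  order-of-magnitude.
- The endmember-ratio and endmember-δ uncertainties are configuration
  defaults and should be overridden when better constraints exist.
- Attenuation fitting assumes a single power-law limb below one maximum;
  multi-peak profiles need manual windowing.
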