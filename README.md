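# pelagicbarite

Pelagic barite (BaSO₄) precipitates in the water column inside
particle-associated microenvironments during microbial decay of organic
matter — even where the ambient water is strongly undersaturated
(Ω_barite ≪ 1). This package implements the full computational chain used
to diagnose that process in a low-sulfate lake water column and to carry
its isotopic signature into the geological record. It is aimed at
isotope biogeochemists working with particulate trace-element profiles
and Ba-isotope data.

The core quantities:

- **Excess particulate Ba** (the operational barite proxy):
  `pBa_XS = p[Ba] − p[Fe]·(Ba/Fe)_litho − p[P]·(Ba/P)_bio`,
  with defaults (Ba/Fe)_litho = 2.87 mM:M, (Ba/P)_bio = 0.44 mM:M.
- **Isotope unmixing**: with δ¹³⁸/¹³⁴Ba in ‰ vs NIST SRM 3104a,
  `δ_XS = (δ_meas − f_supp·δ_supp)/f_XS`, uncertainties from a joint
  Monte Carlo (100,000 draws) over all concentration, ratio, and
  endmember inputs; the headline statistic is the mean offset
  Δ¹³⁸/¹³⁴Ba_XS−diss over samples with f_XS > 0.2.
- **Saturation titration**: Ω_barite = γ₂²[Ba²⁺][SO₄²⁻]/Ksp(T) with
  Davies activity coefficients; remineralized organic matter releases Ba
  and sulfate (Ba:P = 0.44 mM:M, S:P = 1.0–2.5 M:M) into ambient water
  until Ω = 1, yielding the fraction of each ion in the microenvironment
  that respiration must supply.
- **Paleo/budget arithmetic**: source-δ inference
  (δ_source = δ_barite − Δ) and the production → Ba flux → burial chain.
- **Synthetic stations** with known ground truth for every stage
  (power-law p[P] attenuation, lithogenic Fe with a nepheloid maximum,
  excess Ba ∝ −dP/dz, exact isotope mass balance).

See `docs/methods.md` for model assumptions and numerical choices.

## Worked example

```sh
$ pelagicbarite synth --out station.csv --truth-out truth.json --seed 7
wrote station.csv (13 depths, seed 7)

$ pelagicbarite partition station.csv --out part.csv --window 10 60
attenuation fit: b = -0.740 (R^2 = 0.997), z_ref = 18 m
max attenuation -1.52 nM P/m at 24 m
Ba:Sr range 1.21-2.24 M:M
integrated excess fraction over (10.0, 60.0) m: 21.4%

$ pelagicbarite isotopes station.csv --n-draws 100000 --seed 7 --out iso.csv
offset = -0.38 +/- 0.10 permil (2SE, n=3); seed 7, 100000 draws
```

The synthetic station was generated with a true attenuation exponent
b = −0.75 and a true excess-phase δ of −0.18‰ against dissolved Ba at
+0.23‰ (true offset −0.41‰). At 3% concentration noise the fit recovers
b = −0.74, and the Monte Carlo unmixing recovers the offset as
−0.38 ± 0.10‰ from the three depths passing the f_XS > 0.2 filter —
truth inside the reported 2SE. `part.csv` and `iso.csv` hold the
per-depth partition and δ_XS tables; depths where most draws give
f_XS ≤ 0 are flagged unreliable rather than silently dropped.

The saturation model, from the packaged ambient Lake Superior preset
(69.7 nM Ba, 40 µM SO₄, 4.3 °C, pH 8.11):

```sh
$ pelagicbarite saturate --out sat.csv
ambient Omega_barite = 0.02
```

`sat.csv` reports that reaching Ω = 1 in the both-ion scenario requires
92.7% (S:P = 1.0) to 95.1% (S:P = 2.5) of microenvironment sulfate — and
76.1% to 66.2% of Ba — to come from respired organic matter:
undersaturation this deep makes remineralization, not ambient water, the
dominant ion source for pelagic barite.

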