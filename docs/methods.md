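# Methods

## The problem and the model

An ion chamber under-reads in high dose-per-pulse beams because ions
recombine before collection. The collection-efficiency correction `Pion`
(≥ 1 in practice) multiplies the reading to restore the lost charge. It is
measured by Boag's two-voltage technique: with readings `M*_high`,
`M*_low` at bias voltages `V_high > V_low`,

    Pion = (1 − Vr) / (M*_high/M*_low − Vr),    Vr = V_high/V_low.

The estimator depends only on the reading ratio, so it is invariant to
electrometer sensitivity and to any common rescaling. It is undefined when
the reading ratio reaches the voltage ratio; such pairs are rejected at
construction as non-physical (saturation or swapped inputs).

Continuous scans (the standard way %dd and profiles are acquired) are
taken at one voltage only and cannot carry their own `Pion` measurement.
The method implemented here decouples the two: `Pion` is measured
point-wise in static geometries, renormalized signals are formed on a
standard scale — 100 units for the 10×10 cm² SAD reading at the depth of
dose maximum, `S* = 100 M*/M*_ref` — and `Pion` is modelled per
beam-energy group as a linear function of the renormalized signal,

    Pion(S*) = m·S* + b .

Physically the line rises because a larger signal means a higher ion
density and a higher recombination probability; the intercept should be
~1 (no recombination at vanishing signal) and is fitted freely rather
than constrained, matching how the published calibrations report
intercepts slightly different from 1. A hard validity band [0.95, 1.05]
on the intercept guards against grossly unphysical fits.

The corrected signal is `S = Pion(S*)·S* = m·(S*)² + b·S*`; its inverse

    S* = (−b + sqrt(b² + 4mS)) / (2m)     (S/b when m = 0)

converts corrected tabulated data back to raw-signal form. Ratio-type
dose functions acquire a ratio of Pions when corrected, e.g.
`%dd = 100·S*·Pion(S*) / (S*_dmax·Pion(S*_dmax))`; TMR, OAR and RDF are
analogous with their own normalization points (dmax signal at isocenter,
the central-axis signal at the same depth, and the 10×10 cm² field's
signal, respectively).

## Fitting: OLS with bootstrap intervals

Calibrations are fitted by ordinary least squares (statsmodels), which
also supplies standard errors and R². Uncertainty intervals are 95%
percentile intervals from a seeded nonparametric (case-resampling)
bootstrap, 2000 resamples by default, computed with vectorized
closed-form slope/intercept arithmetic; resamples with degenerate
abscissae are dropped. Bootstrap percentile intervals were chosen over a
Bayesian credible-interval machinery because they are reproducible from a
single integer seed, dependency-light, and numerically equivalent for a
two-parameter linear model at the reporting precision used here. The
interval is widened (if ever needed) to include the point estimate so the
"interval contains estimate" invariant holds identically.

The same fit-plus-bootstrap path drives the monitor-unit-rate
independence check: MU rate changes pulse frequency, not dose per pulse,
so the slope of `Pion` vs MU rate should be credibly zero; the test
reports whether 0 lies in the slope's 95% interval.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `v_high`/`v_low` | V | 300/150 | standard two-voltage bias pair; any `V_high > V_low` accepted |
| `n_boot` | – | 2000 | bootstrap resamples; interval jitter ≪ reported precision |
| evaluation range | ref. units | [0, 120] | linear evaluation allowed there; warning beyond (extrapolation past the vetted range), hard error below 0. Corrections at depth or in penumbra need evaluation *below* the smallest fitted signal, so low-end extrapolation is silent |
| kQ table | – | user-supplied | chamber-specific protocol content, deliberately not shipped; linear interpolation only, no extrapolation |
| reporting decimals | – | 1 (%dd), 2 (relative %), 2 cm / 1 mm (widths) | matches the precision at which these quantities are clinically quoted |

Calibrations are keyed by an energy-group label; pooling energies whose
`Pion` behaviour is indistinguishable (e.g. flattened 6 and 10 MV) is done
by the caller when assembling fit input. Covariate screening (field size,
chamber) is out of scope: the published analysis found no residual
dependence once signal and energy are accounted for.

## TMR derivation from %dd

Direct TMR measurement is dose-based and rare; the package derives TMR(d)
from a fixed-SSD %dd curve by evaluating both the depth-d point and the
dmax point at source distance (SAD + d):

    TMR*(d) = [S*(d)/S*(dmax)] · ((SSD + d)/(SSD + dmax))² .

The normalization depth is the maximum of the ISL-mapped signal
`S*(d)·(SSD + d)²`, not of the raw %dd signal: the TMR's depth of maximum
sits slightly deeper than the %dd's because the fixed-SSD scan folds the
inverse-square falloff into its signals, and normalizing at the %dd
maximum would push derived TMR marginally above 1. The `Pion` correction
is applied at the *calculated* signal magnitudes
`S*calc(d) = 100·TMR*(d)·(SAD/(SAD+d))²·scatter_factor` (and the same
with TMR* = 1 for the dmax point), which is why a corrected derived TMR
differs from a corrected measured TMR: the same depth corresponds to
different signal magnitudes in the two geometries. `scatter_factor` is a
user hook for scatter effects beyond inverse square (the published worked
numbers imply a ~2–3% factor with no stated functional form); it cancels
in the TMR ratio itself and only shifts the magnitudes at which `Pion` is
evaluated.

## Numerical choices

- 50% field-width crossings use linear interpolation on the first
  bracketing sample pair moving outward from the central axis — robust to
  noise-induced re-crossings in the tail. The CAX value for OAR is the
  interpolated signal at x = 0 (FFF profiles peak on-axis, but the OAR is
  defined via the CAX, not the maximum).
- %dd and OAR are renormalized to their own maximum / CAX after
  correction; TMR and RDF are left as raw corrected ratios.
- Corrections are pointwise: no resampling, positions in cm, depth
  positive downward, crossplane signed about CAX = 0.
- Degenerate inputs fail loudly: all-zero curves, profiles not spanning
  the CAX, missing reference fields, %dd(10) outside the kQ grid,
  readings at/above the voltage-ratio limit, fits with < 3 points or
  constant abscissae.
- The quadratic signal inverse takes the non-negative root; a negative
  discriminant (possible only for m < 0) is a domain error.

## The synthetic beam generator

The generator provides ground-truth test beds, emulating the *structure*
of FFF commissioning data rather than any particular machine:

- depth dose: `S(d) ∝ (1 − e^{−βd})·e^{−μd}/(SSD + d)²` with
  (μ = 0.044 cm⁻¹, β = 2.2 cm⁻¹) for the 10 FFF-like preset and
  (μ = 0.056 cm⁻¹, β = 3.0 cm⁻¹) for the 6 FFF-like one; the depth of
  maximum is the numerical maximizer of that shape (≈1.6 / ≈1.2 cm);
- profiles: a linear FFF cone falloff inside the field rolled off through
  an erfc penumbra centred on the divergence-projected field edge;
- two-voltage pairs: the low-voltage reading is obtained by *exact
  algebraic inversion* of the Boag formula from a prescribed linear
  `Pion(S*)`, so generator and estimator form an identity on noiseless
  data. This is a deliberate self-consistency construction, not a
  recombination-physics model: it makes every pipeline stage testable
  against exact truth, at the cost of not modelling voltage-dependent
  chamber physics;
- noise: multiplicative Gaussian, independent between the two voltage
  readings; every generator is a pure function of (parameters, seed).

Passing tests on these beams therefore demonstrate the algebraic and
statistical correctness of the correction chain and the monotone
qualitative behaviour seen in measured FFF data (difference curves vanish
at dmax, peak at intermediate depth, shrink with depth for OAR; field
widths narrow by hundredths of a millimetre). They do not validate
detector volume averaging, pulse-structure effects, scatter modelling, or
any specific machine's beam data.

## Problem sizes

The test suite and acceptance script run at desk scale: depth grids of
0.2–35 cm at 2 mm spacing (175 samples), profiles at 0.5 mm spacing,
calibration fits with 60 points and 2000 bootstrap resamples, and 200
replications for coverage-style checks — sizes at which every oracle
comparison is exact or statistically stable while the whole suite runs in
seconds.

## Known limitations

- The linear `Pion(S*)` model is empirical; it is accurate over the
  fitted signal range and extrapolates linearly (with a warning beyond
  120 reference units). No Boag/Jaffé dose-per-pulse physics is modelled.
- Polarity, temperature-pressure, electrometer and humidity corrections
  are out of scope: they cancel in the signal ratios used throughout, and
  the absolute-dose entry point takes an already-corrected reading.
- The kQ chain is a linear interpolation of a user-supplied chamber
  table; no full calibration-protocol implementation, no electron beams,
  no lead-foil %dd(10)x handling.
- Crossplane profiles only; no 2-D/3-D reconstruction or penumbra
  deconvolution.
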