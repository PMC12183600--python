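# Methods

## The measurement model

The pipeline treats an HPLC-DAD injection as a linear, additive detector:
analyte *i* at concentration `C_i` (mM) contributes, at wavelength λ, a
chromatographic peak of area

    A_iλ = m_iλ · C_i,

where `m_iλ` is the response factor (area units per mM) — the observed
extinction coefficient folded with path length and injection volume. Peak
areas at one wavelength add when peaks overlap (Beer–Lambert additivity of
absorbances). Everything downstream — calibration, the indirect
co-elution step, selectivity, Faradaic efficiency — rests on that
linearity, which is why the validation battery (linearity range, R²
floor, recovery band) is the first-class citizen here.

## The synthetic-data generator

`georquant.simulate` emulates the instrument the analysis assumes:

- **Retention map**: OA 12.37, TA 13.64, GA 17.13, GCA 18.31, FA and
  GlyAld both 19.46 (the designed co-elution), DHA 20.76, glycerol
  22.46 min; optionally lactic acid at 17.88 min and the alkaline-matrix
  salt artifact at 11.38 min.
- **Peak shape**: Gaussian with σ = 0.12 min by default. That width is
  chosen so the lactic/glycolic pair is partially overlapped
  (Rs = 2Δt/(w₁+w₂) ≈ 0.94 with w = 4σ) while every validated adjacent
  pair is baseline-resolved (the closest, GA/GCA, has Rs ≈ 2.46) —
  reproducing the separation quality the method is designed around. An
  exponentially modified Gaussian is available behind the `peak_shape`
  option for tailing studies; the Gaussian default keeps closed-form
  areas available as test oracles.
- **Response factors at 205 nm** are the validated slopes of the
  8-analyte panel (167894, 34133, 9994, 7441, 6309, 12566, 17903, 30.6
  area/mM for OA, TA, GA, GCA, FA, GlyAld, DHA, glycerol). GlyAld's
  300 nm slope is not part of that table; the default of 4000 area/mM is
  a configurable placeholder and every algorithm treats it as data.
  Lactic acid is a prospective extension with no validated slope; its
  default (7000 area/mM) is set comparable to the chemically similar
  α-hydroxy acid glycolic. FA's 300 nm response defaults to 0 — the
  premise that makes the 300 nm peak attributable entirely to GlyAld.
- **Noise**: a unit-mean lognormal injection factor per analyte per
  injection (CV 0.5 % by default), shared across wavelengths because it
  models injected amount, not detector gain; additive white baseline
  noise (sd 0.02 absorbance units) and optional linear drift. These
  magnitudes put simulated repeatability RSDs in the sub-2 % band typical
  of the validated panel. Per-injection streams derive from a root seed
  by stable hashing of (analyte, level, replicate), so series are
  reproducible and order-independent.
- **Grid**: 0–30 min at 0.01 min, matching a 30-min run; a step coarser
  than σ/5 triggers a warning because trapezoidal accuracy degrades.
- **Electrolysis samples** divide cell concentrations by 1.25 (1000 µL
  aliquot + 250 µL of 0.5 M H₂SO₄ quench) and, in alkaline matrix, add
  the salt pseudo-peak. The salt's magnitude is plumbing, not science:
  only its position (0.99 min from OA, i.e. outside the ±0.15 min
  assignment window) matters.

What the generator does **not** emulate: retention-time drift between
runs, detector saturation, tailing/fronting asymmetry (unless EMG is
switched on), wavelength-dependent baselines, carry-over, and real
matrix effects beyond the salt peak. Passing tests therefore demonstrate
the *procedure* — integration, calibration algebra, the subtraction
step, charge bookkeeping — under the statistical structure the method
assumes, not robustness to instrument pathology.

## Peak processing

- **Baseline**: light Savitzky–Golay denoising (cubic, 11 points — it
  passes flat offsets and linear drift through exactly), then a
  grey-scale morphological opening (rolling minimum then maximum) with a
  2 min window, wider than any peak base (~1.2 min), then a mean filter.
  Exact on flat and linearly drifting noise-free traces in the grid
  interior; under a peak the residual baseline is below 1 % of peak
  height.
- **Detection**: `scipy.signal.find_peaks` on the denoised,
  baseline-subtracted trace. Default thresholds are 5× the default
  baseline sd for height (0.1) and 3× for prominence (0.06). Bounds go to
  the valley toward the neighbouring peak or the 5σ decay point
  (σ from the half-height width), whichever comes first; areas are
  trapezoidal over the *raw* baseline-subtracted signal, so denoising
  never biases quantification.
- **Assignment**: nearest retention time within ±0.15 min. Analytes that
  share a retention time form a co-elution cluster; a matching peak
  carries the whole group (`{FA, GlyAld}`) and no single identity. The
  merged peak is integrated **once** per wavelength — the indirect
  procedure consumes the combined area, never an attempted split. Ties
  break by distance then alphabetically; two peaks claiming one cluster
  are both flagged ambiguous rather than silently resolved.
- **Overlapped pairs** (lactic/glycolic): explicit two-Gaussian (or
  two-EMG) least squares via lmfit, run only when both species are
  declared present — no automatic overlap hunting. Components are
  reported sorted by center, so initialisation order is irrelevant;
  non-convergence returns `converged=False` with best-so-far parameters
  instead of raising, keeping batch runs alive.

## Calibration and validation statistics

Ordinary least squares of area on concentration, **through the origin by
default** because the validated response lines are intercept-free; an
intercept fit is one flag away. R² is computed against the mean-centered
total sum of squares in both modes so they are comparable.

The σ in LOD = 3.3 σ/S and LOQ = 10 σ/S is ambiguous in common usage
("standard deviation of the response"): the standard error of the slope
and the residual standard deviation are both defensible. Both are
implemented (`sigma_mode="slope_sd"` default, or `"residual_sd"`), each
curve records which was used, and reports carry the tag — neither is
canonized. Whatever σ, LOQ/LOD = 10/3.3 holds identically by
construction.

Repeatability uses the sample standard deviation (n−1); recovery
propagates replicate scatter into an sd on R. Back-calculated
concentrations below the curve's LOQ are reported but flagged, and
excluded from selectivity/FE by default; negative back-calculations clip
to zero with a flag.

## The indirect co-elution step

For a merged peak of analytes G (has a private wavelength) and F (does
not):

    C_G   from A_G,private via its private-wavelength curve
    Â_G,205 = m_G,205 · C_G (+ b if the curve carries an intercept)
    A_F,205 = A_mix,205 − Â_G,205
    C_F   from A_F,205 via F's 205 nm curve.

The additivity identity `A_mix = Â_G + A_F` holds exactly before
clipping and is asserted property-style in the tests. Because the last
step is a subtraction, a trace-level F under noise can yield a small
negative area; that clips to 0 with a flag — erroring would be wrong,
since such negatives are statistically inevitable. The error of C_F
grows with the G:F concentration ratio (the subtraction inherits G's
absolute noise), a monotonicity the test suite verifies by seeded sweep.
Through-origin prediction is the default; intercepts are honoured when
the curves carry them.

## Electrochemical accounting

Electrons per mole formed from glycerol come from oxidation-state
bookkeeping (glycerol's mean carbon oxidation state is −2/3): GlyAld 2,
DHA 2, glyceric 4, tartronic 8, glycolic 10/3, formic 8/3, oxalic 22/3.
The table is configurable (`z_overrides`) since conventions for
fractional-carbon products vary.

    FE(%)             = 100 · F · Σᵢ zᵢ·Cᵢ·V / Q,  F = 96485 C/mol
    selectivity (mole) = 100 · Cᵢ / Σⱼ Cⱼ

Selectivity defaults to the mole basis — per-product bar percentages in
this field read as composition fractions — with carbon- and
electron-weighted bases available for comparison; all three normalise to
100 exactly. Gaseous products (CO₂, O₂) are invisible to HPLC, so FE
below 100 % is reported as-is rather than renormalised. The electrolyte
volume is always an input, never a constant: it is not derivable from
chromatograms.

## Numerical choices

- Trapezoidal integration on the 0.01 min grid reproduces the analytic
  Gaussian area over ±5σ to ~6×10⁻⁷ relative (truncation-dominated);
  over partial windows convergence is second order in the step.
- Bound indices are selected with a 10⁻⁹ min tolerance so bounds that
  coincide with grid points up to float rounding include those points.
- Chromatogram files store full `repr` precision and are re-read with
  pandas' round-trip float parsing, so write→read is bit-exact.
- Report formatting: concentrations 3 decimals, percentages 2; internal
  values keep full precision.
- Degenerate inputs fail loudly and specifically: rank-deficient
  calibration designs, zero-mean RSD, non-positive theoretical
  concentrations, inverted integration bounds, unknown matrix labels and
  missing z-entries all raise with the offender named.

## Problem sizes

The validation-style computations run at the design's own scale: 5
calibration levels × 3 replicates per analyte, 5 equimolar mixture
levels × 3 injections, 3001-point chromatograms at 2 wavelengths. The
slope-bias check aggregates 100 seeded single-replicate calibrations.

## Known limitations

- The lactic-acid and salt response factors, and GlyAld's 300 nm slope,
  are stated defaults, not validated values; conclusions that depend on
  their magnitudes should treat them as free parameters.
- The pair-fit handles exactly two components; three-way overlaps are
  out of scope, as is full-spectrum unmixing across many wavelengths.
- Assignment assumes stable retention times (±0.15 min); no cross-batch
  alignment is attempted.
- FE accounting counts only quantified liquid products; it cannot
  distinguish "charge went to gas evolution" from "a product was missed".
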