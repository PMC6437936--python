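# Methods

`membranalysis` implements three quantitative pipelines for characterising
lipid model membranes — ternary DOPC/DPPC/cholesterol (23:47:30) mixtures
with liquid-ordered (l_o) / liquid-disordered (l_d) phase coexistence —
plus synthetic generators that provide ground-truth data for every stage.
This note records the models, the numerical choices, and what the
synthetic tests do and do not establish.

## SAXS: vesicle-mixture global analysis

### Model

An extruded suspension contains unilamellar vesicles (diffuse scatterers)
and residual multilamellar stacks (quasi-Bragg peaks).  The measured
intensity is the incoherent mixture

    I(q) = s [ (1 − N_UV) S(q) |F(q)|² / q² + N_UV |F(q)|² / q² ] + b,

with `N_UV` the fraction of positionally non-correlated (unilamellar)
scatterers.  `scale` and `background` are nuisance parameters: measured
intensities are in arbitrary units and capillary background subtraction
is imperfect.

**Form factor.**  The transverse electron-density contrast is a symmetric
three-Gaussian profile — headgroup Gaussians at ±z_H (width σ_H, unit
amplitude) and a chain/methyl Gaussian at the centre (relative amplitude
ρ_C < 0, width σ_C).  Its Fourier transform is analytic:

    F(q) = √(2π) [ 2 σ_H e^(−σ_H²q²/2) cos(q z_H) + ρ_C σ_C e^(−σ_C²q²/2) ].

The membrane (steric) thickness is derived as `d_B = 2 (z_H + 2 σ_H)`,
i.e. the bilayer ends two Gaussian widths beyond the headgroup centre.
This identity is enforced exactly in every fit result.

**Structure factor.**  Modified Caillé theory for a stack of N bilayers
with repeat d and bending-fluctuation parameter η:

    S(q) = N + 2 Σ_{k=1}^{N−1} (N−k) cos(kqd) e^(−(d/2π)² q² η γ_E) (πk)^(−(d/2π)² q² η),

γ_E = 0.5772… (Euler–Mascheroni).  The truncated sum can ring slightly
negative between peaks; it is floored at zero before entering the
mixture.  N is a single integer (no polydispersity in stack size).

### Fitting

Weighted least squares (weights 1/σ_I²) using bounded
Levenberg–Marquardt (lmfit/MINPACK).  The χ² surface is multimodal in
the lamellar repeat and in N, so the fit runs

* an exhaustive loop over integer N (default 1–7, plus the
  user-supplied initial N), and
* a multi-start grid per N: the initial model itself plus
  d ∈ {55, 60, 65, 70, 75, 80} Å × N_UV ∈ {0.3, 0.7}.

Every start first gets a bounded-iteration "scout" minimisation (at most
200 residual evaluations); the best eight scouted optima are then
polished to full precision.  On the synthetic regimes this two-stage
scheme reaches the same optima as polishing every start and is several
times faster.  Ties between stack sizes break toward lower reduced χ²,
then lower N.  The overall intensity scale is initialised per start by
its weighted linear projection onto the data, which makes the start grid
insensitive to the (arbitrary) intensity units.

Standard errors come from the local quadratic approximation at the
optimum; the `d_B` uncertainty propagates the z_H/σ_H covariance.
Parameters finishing on a bound are flagged, not silently accepted.
An optional q-window trim (`q_min`/`q_max`) is exposed because beam-stop
contamination at low q is common.

Default parameter bounds: z_H ∈ [5, 40] Å, σ_H ∈ [0.5, 8] Å,
ρ_C ∈ [−5, −0.01], σ_C ∈ [0.5, 12] Å, d ∈ [40, 110] Å, η ∈ [0, 1],
N_UV ∈ [0, 1], scale > 0, background ≥ 0.

### Verification

The form factor is checked against direct numerical quadrature of the
density profile (100 random parameter draws, ≤ 1e−6 relative); the
structure factor against closed-form lattice limits (S ≡ 1 for N = 1,
S = N² at the Bragg condition for η = 0) and a brute-force grid search
for the peak position.  Parameter recovery is measured on seeded
synthetic curves (below).

## DSC: van't Hoff analysis of broad endotherms

From a baseline-subtracted excess heat-capacity trace the pipeline
extracts the transition temperature Tm (temperature of maximal Cp), the
full width at half maximum T_1/2, the calorimetric enthalpy
ΔH_c = ∫Cp dT (trapezoidal), the van't Hoff enthalpy via the classic
approximation

    ΔH_vH ≈ 4 R Tm² / T_1/2        (R = 1.9872 cal mol⁻¹ K⁻¹),

and the cooperative unit CU = ΔH_vH / ΔH_c — the effective number of
lipids melting together.

Numerical choices:

* **Baseline**: a linear chord through the user-chosen anchor
  temperatures; Cp outside the window is zeroed.  Optionally each anchor
  is averaged over a small window (`anchor_window_K`) rather than read
  from a single point: a single-point anchor error on a noisy scan
  integrates into a proportional enthalpy error across the whole window.
* **Tm**: three-point parabolic refinement of the discrete maximum,
  fitted in coordinates centred on the middle point (absolute kelvin
  with millikelvin spacing loses the vertex to cancellation otherwise).
* **T_1/2**: half-maximum crossings located by linear interpolation on
  each flank.  On densely sampled noisy scans an optional
  Savitzky–Golay pre-smoothing (`smooth_window_K`, quadratic) is applied
  to the curve used for peak location and width only; the enthalpy
  integral always uses the raw trace.  The window must stay well below
  the transition width (we use 0.5 K against ~10–20 K wide peaks).
* **Replicates**: each scan is analysed independently; failing scans
  (truncated peaks) are excluded with a logged reason and the summary
  reports mean ± sample SD per quantity, with the CU spread taken over
  per-scan CU values rather than from the ratio of means.
* **Reporting**: CU rounds to the nearest integer, enthalpies to three
  significant figures.

Two analytic facts about the exact two-state model
Cp(T) = ΔH_c ΔH_vH/(R T²) · K/(1+K)², K = exp[−(ΔH_vH/R)(1/T − 1/Tm)],
are load-bearing for the tests:

* the half-maximum points sit at K = 3 ± 2√2, so the true FWHM is
  2 ln(3+2√2) R Tm²/ΔH_vH ≈ 3.5255 R Tm²/ΔH_vH — the factor-4 rule
  therefore *over-reports* ΔH_vH by 4/3.5255 ≈ 1.134.  The convention is
  kept (it is what the tabulated values use); the bias is asserted by
  the tests, not corrected.
* the 1/T² prefactor shifts the Cp maximum below the thermodynamic Tm
  by ≈ 4R²Tm³/ΔH_vH² (0.1 K for a 67 kcal/mol transition, 0.36 K at
  36 kcal/mol).  The extracted Tm is the peak temperature, as in
  standard instrument software.

## Laurdan generalized-polarization imaging

Laurdan's emission red-shifts with interfacial hydration;

    GP = (I₄₄₀ − G·I₄₉₀) / (I₄₄₀ + G·I₄₉₀)

is high in ordered, low in disordered membrane.  The instrument factor G
multiplies the red channel and is calibrated from a standard of known GP
(laurdan in DMSO) by inverting the same expression:
G = (I₄₄₀/I₄₉₀)(1 − GP_ref)/(1 + GP_ref).  GP_ref is always supplied by
configuration (default 0.207, a conventional literature value for the
DMSO standard), never hard-coded into the computation.

Pixels are masked where the corrected total intensity falls below a
user threshold; masked pixels are never divided.  GP is exactly
invariant under a common rescaling of both channels.

**Segmentation** assumes one vesicle per frame imaged at its equator
(the equatorial geometry also avoids photoselection, which is therefore
not corrected).  The ring is located from the intensity-weighted
centroid and the peak of the radial intensity profile; a frame whose
radial peak is less than 3× the median (background) intensity is
rejected as ring-free.  Within an annulus of configurable width the
pixels split into l_o/l_d at the midpoint of the two modes of the GP
histogram (64 bins, Gaussian-smoothed, σ = 2 bins); a unimodal
histogram falls back to the global median, and a fully degenerate ring
(all values tied) is split evenly so both partitions carry identical
statistics.  The higher-GP class is labelled l_o by convention.  The
time-series layer reports per-frame mean ± SD for l_o, l_d and the
whole ring as a tidy table; frames that fail segmentation keep their
row, flagged, so the series continues.

## Synthetic data

The generators draw from the forward models above with conventional
noise models per instrument class (none of which is dictated by the
measured data):

* **SAXS** — multiplicative Gaussian noise, σ_I = f·I_model with
  f = 0.01 by default (relative uncertainty roughly constant across the
  measured window); q grid 0.015–0.447 Å⁻¹ (the instrument window
  0.15–4.47 nm⁻¹), 400 points.  With f = 0 the curve equals the model
  exactly and σ_I is floored at 1e−9·I_model to stay usable as weights.
* **DSC** — exact two-state endotherm plus linear baseline plus additive
  Gaussian noise (default grid 0.01 K over Tm ± 6 FWHM; generation
  refuses grids narrower than ±5 FWHM, which would clip enthalpy).
* **GUV imaging** — an annulus of specified radius, width and mean
  counts on a dim background; an arc of the ring carries GP_lo and the
  remainder GP_ld; channels are built by inverting the GP definition
  (I₄₄₀ = S(1+GP)/2, I₄₉₀ = S(1−GP)/(2G)) with per-pixel Poisson noise.
  From a chosen frame onward both phase GPs rise by a step, emulating a
  dehydrating additive reaching the membrane.

All generators are deterministic given a seed, and each noiseless output
is exactly invertible by its analysis stage — the anchor of the recovery
tests.  Presets pin the regimes studied experimentally:

| preset | meaning |
|---|---|
| `control` | z_H 20.1 Å, σ_H 2.5 Å, ρ_C −1.2, σ_C 4 Å, d 65.8 Å, N 5, η 0.1, N_UV 0.52 (d_B = 50.2 Å) |
| `artepillin_10molpct` | z_H 19.6 Å, σ_H 2.2 Å, d 71.4 Å, N 3, η 0.15, N_UV 0.87 (d_B = 48.0 Å) |
| `dsc_control`, `dsc_artepillin_5molpct`, `dsc_artepillin_10molpct` | Tm 32.6/34.9/36.5 °C, ΔH_c 1.4/1.3/1.4 kcal/mol; the generating two-state enthalpy is the factor-4 value (75.8/54.1/41.2 kcal/mol) × 3.5255/4, so the analysis chain returns the quoted number |
| `guv_phase_step` | 128 px frames, r = 40 px, ring 5 px, l_o arc 1/3 of the ring, GP 0.45/0.05, 500 counts/px, +0.05 GP step at frame 3 of 6 |

The amplitudes ρ_C, widths σ_C, stack sizes, η, and the noise levels are
not experimentally determined for this system; they were chosen once as
values typical for phosphatidylcholine bilayers and photon-counting /
capillary-DSC instruments.

**What passing tests show — and don't.**  Synthetic recovery
demonstrates that the estimators are correct and well-conditioned under
the stated noise models.  Real curves add effects the generators omit:
instrument smearing and absolute-scale effects in SAXS, stack-size
polydispersity, scan-rate and thermal-lag distortions in DSC,
photobleaching, vesicle drift and out-of-focus light in imaging.
Agreement with the experimentally fitted values on real data is
therefore not claimed anywhere; the experiment-scale numbers that *are*
reproduced (cooperative units, Bragg positions, thinning percentage)
are arithmetic consequences of published quantities.

## Problem sizes

Defaults keep every stage desk-scale: 400-point SAXS curves (a fit takes
a few seconds through the multi-start protocol), 0.01 K thermograms
(10⁴–10⁵ points), 128-px image frames.  The recovery studies use 20
seeded SAXS curves and 6-frame GUV series.

## Known limitations

* Single-peak DSC analysis only; no multi-peak deconvolution or
  scan-rate correction.
* The SAXS model assumes symmetric bilayers and a single integer stack
  size; no resolution smearing.
* One vesicle per imaging frame; no tracking, bleaching correction or
  3-D reconstruction.
* The factor-4 van't Hoff convention is reproduced, including its ~13 %
  overestimate on exactly two-state transitions.
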