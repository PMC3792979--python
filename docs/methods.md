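# Methods

`ligandbind` analyses the standard battery of solution-spectroscopy
experiments used to characterise the binding of a small ligand to a transport
protein (the defaults target the human serum albumin / flavonoid system: a
single-tryptophan donor, 1:1 association, Sudlow-site competition). This note
records the models, the conventions, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Quench titrations

**Inner-filter correction.** A ligand that absorbs at the excitation or
emission wavelength attenuates the measured fluorescence geometrically. We
apply the standard correction for a centred 1 cm cuvette,

    F_cor = F_obs · 10^((A_ex + A_em)/2),

where `A_ex`, `A_em` are the absorbance *increments* contributed by the added
ligand. Two modes exist: scalar `A_em` at the reference emission wavelength
(used when only peak intensities are analysed, and the mode the titration CSV
schema records per point), and per-wavelength `A_em(λ)` when a full
absorbance spectrum is available (`correct_spectrum`).

**Stern-Volmer analysis.** `F0/F = 1 + K_SV [Q]` is fitted by unweighted OLS.
Quench plots of static binders curve upward at high `[Q]`, so the regression
runs over the *largest prefix* of the concentration grid (starting at
`[Q] = 0`) that passes two gates: `r² ≥ 0.995` (configurable) and a
residual sign-run check — for prefixes of six or more points, a fit whose
residual signs collapse into ≤ 3 runs (the positive-ends/negative-middle
signature of curvature) is rejected. Exact fits (residuals at numerical
noise) pass unconditionally, and if no prefix of length ≥ 3 qualifies the
full range is used with a warning. The intercept is reported, not constrained
to 1; deviations beyond 5% warn. `k_q = K_SV/τ0` uses the unquenched donor
lifetime, default `τ0 = 6.38 ns` for native albumin. A strictly decreasing
`K_SV(T)` together with `k_q` above the diffusion-controlled limit
(`10¹⁰ M⁻¹ s⁻¹`) classifies the mechanism as static.

## Binding constant and stoichiometry

The double-logarithmic model with a mass-balance free-ligand correction,

    log[(F0 − F)/F] = n·log K_a + n·log( [D_T] − (F0 − F)/F0 · [P_T] ),

is fitted by OLS; the slope is the stoichiometry `n` and
`K_a = 10^(intercept/slope)`. The defining assumption, stated prominently:
**fractional quench equals fractional occupancy** of the binding sites, so
the bound-ligand estimate is `(F0 − F)/F0 · [P_T]`. Under that assumption the
model is *exactly* self-consistent with a 1:1 equilibrium
(`θ/(1−θ) = K_a[D_free]`), which is what the recovery tests exploit. Points
with `F ≥ F0` or a non-positive corrected free-ligand concentration are
excluded with a warning; at least four usable points are required. Standard
errors of `log K_a` come from delta-method propagation of the
intercept/slope ratio; the source study prints no uncertainties, so these
are this package's convention.

## van't Hoff thermodynamics

`ln K_a` versus `1/T` (T in kelvin) by OLS: `ΔH = −R·slope`,
`ΔS = R·intercept`, both assumed temperature independent over the studied
30 K span (no ΔCp term — a non-goal). `ΔG(T) = ΔH − TΔS` is an identity by
construction. Kelvin conversion is `T = t + 273.15` by default; the
`paper_mode` switch uses `+273`, the rounding under which older printed ΔG
tables are exactly self-consistent. `R = 8.314 J mol⁻¹ K⁻¹`.

## FRET distance

Overlap integral `J = ∫F_D(λ)ε_A(λ)λ⁴dλ / ∫F_D(λ)dλ` by trapezoidal
quadrature on the union of the two wavelength grids restricted to their
overlap (linear interpolation, no smoothing); the donor normalisation uses
the donor's full support. The unit convention is `J` in M⁻¹ cm⁻¹ nm⁴ with

    R0⁶ (Å⁶) = 8.79×10⁻⁵ · κ² · n⁻⁴ · Q_D · J,

and the common printed unit M⁻¹ cm³ is accepted via the exact factor
`1 M⁻¹ cm³ = 10²⁸ M⁻¹ cm⁻¹ nm⁴`. Defaults: `κ² = 2/3` (isotropic dipole
averaging), refractive index 1.336 (dilute aqueous buffer), `Q_D = 0.118`
(native albumin). Efficiency `E = 1 − F/F0` is an explicit input
(`F_ratio`), taken at the 1:1 donor:acceptor point; the distance follows from
`r = R0((1−E)/E)^(1/6)`. Validity reporting: `0.5·R0 < r < 2·R0`, the 2–8 nm
window, and the `r > R0` consistency note for static quenching.

## Conformational metrics

- **Synchronous shifts.** Peak positions are the discrete argmax refined by a
  3-point parabola (edge maxima and degenerate curvature fall back to the
  grid point); net shift = last − first peak, negative = blue. Δλ = 15 nm
  probes tyrosine, Δλ = 60 nm tryptophan; series must share the Δλ tag.
- **EEM peaks.** Strict 8-neighbourhood local maxima; points within
  `scatter_tol` (default 5 nm) of `λ_em = λ_ex` are labelled Rayleigh, of
  `λ_em = 2λ_ex` second-order (in that priority, so the two labels are
  mutually exclusive whenever `λ_ex > 2·scatter_tol`). Remaining maxima are
  ranked by intensity (`peak1`, `peak2`, `other`). Maxima below 0.1% of the
  surface maximum are treated as numerical ripple. Trajectories across
  surfaces match peaks by nearest excitation line (10 nm tolerance); a
  missing match is a flagged gap.
- **MRE conversion.** `MRE = θ_mdeg / (10 · N_res · C_M · l_cm)`, the molar-
  concentration form; `N_res = 585` for albumin.
- **Melt analysis.** Pre-transition baseline = mean of the forward scan in a
  configurable window (default 25-40 °C); onset = first temperature beyond
  the window where the deviation exceeds `max(3×SD(window), 0.5% of
  baseline)` (the floor keeps noise-free data from triggering on rounding).
  With the default generator this rule fires at roughly 1-2% unfolded
  fraction, i.e. at the foot of the transition. Recovery = reverse-scan
  signal at the evaluation temperature (default: shared scan start) as a
  percentage of the forward-scan signal there; it is scale invariant, and
  values above 110% warn.

## Displacement analysis

Relative signal is percent of the competitor-free value with sign preserved
(induced CD bands are often negative). Loss at a requested ratio is linearly
interpolated. Site assignment uses a 50% loss threshold (configurable) with
an *all-markers* rule: a site is assigned only if every one of its markers
clears the threshold while every marker of the other site stays below it;
the per-marker loss table always accompanies the verdict so users can apply
their own rule. An optional baseline series (the competitor-protein complex
signal at the monitoring wavelength) can be subtracted before normalisation,
for markers whose band overlaps a native competitor-complex band.

## Synthetic data: what it emulates and what it does not

The generator reproduces the reference experimental design: 3 µM protein,
0-22.5 µM ligand in 1.5 µM steps, temperatures 15/25/35/45 °C, tryptophan
emission band at 336 nm on a 300-380 nm grid, maximal quench depth 0.72,
14 nm blue shift at saturation, ligand extinctions 15000/1000 M⁻¹ cm⁻¹ at
the excitation/emission wavelengths (producing a genuine inner-filter
artifact that the analysis must invert), 1% multiplicative Gaussian noise.

Two points deserve emphasis:

1. **Model-consistent mode.** The double-log estimator is exact only when
   the measured quench fraction equals occupancy. The generator's
   `quench_depth = 1` with `band_shift_at_saturation = 0` realises that mode
   (full static darkening of the bound fluorophore, no band-shift
   contamination at the fixed reference wavelength), and the recovery tests
   run in it. Notably, with `K_a ≈ 1e5 M⁻¹` the occupancy at the top of the
   default grid is ≈ 0.7, so the study-condition default `quench_depth =
   0.72` and the model-consistent mode produce similar-looking titrations.
   Under the default (depth 0.72 plus band shift), fixed-wavelength
   intensities under-report occupancy and the estimator inherits a bias of
   order `log(quench_depth)` in `log K_a` — a real feature of the method,
   not of the implementation, and the reason headline fit values are
   validated by recovery in the model-consistent mode.
2. **What passing tests do not show.** The generator draws ideal Gaussian
   bands with white multiplicative noise; real spectra add correlated
   baseline drift, scatter contamination, and photobleaching, none of which
   are simulated. Parameter-recovery results therefore demonstrate estimator
   correctness, not robustness to instrument systematics.

Equilibria are exact: the 1:1 bound fraction uses the cancellation-safe
quadratic root (`2PD/(b+√(b²−4PD))`), and the three-species competitive
equilibrium is solved by damped fixed-point iteration on free protein to a
mass-balance residual below 10⁻¹⁴ (relative). The melt generator is a
two-state logistic (default midpoint 66 °C, width 5 °C, native/denatured MRE
−16000/−5000 deg cm² dmol⁻¹, additive noise 0.3% of the unfolding
amplitude — a realistic CD noise floor chosen so single-point recovery
evaluation resolves 1%); the reverse scan is `reversibility × forward`
(refold baseline 0), making the planted reversibility the exact expected
recovery. All simulators are deterministic under a fixed seed.

## Problem sizes

Tests run on the native experimental scale throughout (16-point titrations,
4 temperatures, 14×57 EEM grids, 56-point melts); Monte-Carlo checks use 200
replicates. The whole suite completes in a few seconds.

## Known limitations

Single-site 1:1 binding only (no cooperativity, no ΔCp); κ² fixed at 2/3
rather than sampled over orientation distributions; no secondary-structure
deconvolution from far-UV CD; linear interpolation is the only resampling
performed (no smoothing or baseline correction); vendor instrument formats
are out of scope (CSV only).
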