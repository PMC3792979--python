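# ligandbind

Analysis toolkit for solution-spectroscopy studies of small-molecule binding
to transport proteins — the experiment battery routinely applied to drug or
nutraceutical candidates binding human serum albumin (HSA): fluorescence
quench titrations, van't Hoff thermodynamics, FRET distance determination,
conformational-change metrics (synchronous and 3-D fluorescence, circular
dichroism), and competitive site-marker displacement. A synthetic-data
generator with exact equilibrium ground truth makes every stage testable
without instrument data.

## Who it is for

Biophysical and pharmaceutical chemists who have titration spectra in CSV
form and want the standard derived quantities with explicit, reproducible
conventions — and method developers who need a generator of realistic quench
titrations with known parameters.

## The models

- **Stern-Volmer quenching** — after inner-filter correction
  `F_cor = F_obs·10^((A_ex+A_em)/2)`, fit `F0/F = 1 + K_SV[Q]` over an
  automatically selected linear zone; `k_q = K_SV/τ0` against the diffusion
  limit (~10¹⁰ M⁻¹ s⁻¹) and the temperature trend of `K_SV` classify the
  mechanism as static or dynamic.
- **Binding constant and stoichiometry** — the double-logarithmic regression
  `log[(F0−F)/F] = n·log K_a + n·log([D_T] − (F0−F)[P_T]/F0)`, whose
  free-ligand term is corrected by mass balance rather than assuming ligand
  excess.
- **van't Hoff decomposition** — OLS of `ln K_a` vs `1/T` gives
  `ΔH = −R·slope`, `ΔS = R·intercept`, `ΔG(T) = ΔH − TΔS`.
- **FRET** — overlap integral `J = ∫F_D ε_A λ⁴ dλ / ∫F_D dλ`, Förster radius
  `R0⁶(Å⁶) = 8.79×10⁻⁵ κ² n⁻⁴ Q_D J`, efficiency `E = 1 − F/F0`, distance
  `r = R0((1−E)/E)^(1/6)`, plus the standard validity checks.
- **Conformation** — synchronous-scan peak shifts (Δλ = 15/60 nm for
  Tyr/Trp), EEM peak picking with Rayleigh/second-order scatter labelling,
  mean residue ellipticity conversion, and thermal
  denaturation/renaturation recovery.
- **Displacement** — relative-signal curves vs competitor:protein ratio and
  a threshold rule that assigns Sudlow site I or II from marker losses.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

Analyse a four-temperature titration generated in the model-consistent mode
(quench fraction = occupancy, affinity following `ΔH = −15.48 kJ/mol`,
`ΔS = +44.06 J/mol/K`):

```python
from ligandbind import (GroundTruth, simulate_multitemp, to_kelvin,
                        vant_hoff_fit, forster_radius, donor_acceptor_distance)
from ligandbind.pipeline import analyze_binding_series, analyze_quench_series

truth = GroundTruth(quench_depth=1.0, band_shift_at_saturation=0.0,
                    noise_sd=0.0, seed=1)
by_t = simulate_multitemp(truth, delta_H=-15.48, delta_S=44.06)
k_by_t = {}
for t_c in sorted(by_t):
    series = by_t[t_c]
    sv = analyze_quench_series(series)        # Stern-Volmer
    fit = analyze_binding_series(series)      # K_a, n
    k_by_t[to_kelvin(t_c)] = fit.K_a
    print(f"{t_c:4.0f} C  K_SV = {sv.K_SV:.3e} M^-1  K_a = {fit.K_a:.3e} M^-1  n = {fit.n:.3f}")

thermo = vant_hoff_fit(k_by_t)
print(f"van't Hoff: dH = {thermo.delta_H:.2f} kJ/mol, dS = {thermo.delta_S:.2f} J/mol/K")

r0 = forster_radius(2.814e-15, j_units="cm3")  # printed overlap integral
print(f"R0 = {r0:.3f} nm, r = {donor_acceptor_distance(0.214, r0):.3f} nm")
```

prints

```
  15 C  K_SV = 1.037e+05 M^-1  K_a = 1.282e+05 M^-1  n = 1.000
  25 C  K_SV = 8.574e+04 M^-1  K_a = 1.032e+05 M^-1  n = 1.000
  35 C  K_SV = 7.164e+04 M^-1  K_a = 8.427e+04 M^-1  n = 1.000
  45 C  K_SV = 6.044e+04 M^-1  K_a = 6.969e+04 M^-1  n = 1.000
van't Hoff: dH = -15.48 kJ/mol, dS = 44.06 J/mol/K
R0 = 1.984 nm, r = 2.465 nm
```

`K_SV` falls with temperature (static quenching: the ground-state complex
dissociates on warming), `K_a` recovers the generator's affinity at each
temperature with 1:1 stoichiometry, the van't Hoff fit returns the planted
enthalpy/entropy, and the FRET chain converts a measured overlap integral
and efficiency into a donor-acceptor distance of ~2.5 nm — inside the 2-8 nm
window where energy transfer is efficient and beyond `R0`, consistent with a
static mechanism.

## Command line

The `ligandbind` CLI wraps the library: `quench`, `bind`, `fret`, `sync`,
`conf3d`, `melt`, `displace`, `simulate`, and `run` (full pipeline from a
YAML config; see `ligandbind run --help`). All stages consume the long-format
CSV schemas documented in `ligandbind/spectra.py` and emit tidy results CSVs
plus a summary.

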