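"""Association constant, stoichiometry, and van't Hoff thermodynamics.

The binding constant K_a and stoichiometry n come from the double-logarithmic
regression

    log[(F0 - F)/F] = n log K_a + n log( [D_T] - (F0 - F) [P_T] / F0 )

in which the free-ligand concentration is corrected by mass balance: the
bound-ligand estimate is the fractional quench (F0 - F)/F0 (equated with
fractional occupancy of the binding sites) times the total protein
concentration [P_T].  Unlike the naive double-log plot against total ligand,
no assumption of ligand excess is made.  The slope is n and the intercept is
n log K_a.

Temperature dependence of K_a is decomposed by the van't Hoff relation

    ln K = -dH/(R T) + dS/R

with dH and dS assumed temperature-independent over the studied range, and
dG(T) = dH - T dS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .spectra import GAS_CONSTANT, TitrationSeries, to_kelvin

__all__ = [
    "BindingFit",
    "ThermoFit",
    "fit_binding_isotherm",
    "binding_points",
    "vant_hoff_fit",
    "vant_hoff_from_celsius",
    "gibbs_free_energy",
]


@dataclass(frozen=True)
class BindingFit:
    """Double-log binding regression result at one temperature."""

    K_a: float              # M^-1
    n: float                # binding stoichiometry
    r_squared: float
    temperature: float      # Celsius
    points_used: int
    log_Ka_stderr: float = float("nan")  # OLS standard error of log10 K_a
    n_stderr: float = float("nan")

    def __post_init__(self) -> None:
        if self.K_a <= 0 or self.n <= 0:
            raise ValueError("K_a and n must be positive")


@dataclass(frozen=True)
class ThermoFit:
    """van't Hoff decomposition of the temperature dependence of K_a."""

    delta_H: float                       # kJ mol^-1
    delta_S: float                       # J mol^-1 K^-1
    delta_G_by_T: Mapping[float, float]  # K -> kJ mol^-1, dG = dH - T dS
    vant_hoff_r_squared: float
    gas_constant: float = GAS_CONSTANT   # J mol^-1 K^-1


def binding_points(series: TitrationSeries, F_values: Sequence[float]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Regression coordinates (x, y) of the double-log binding plot.

    ``F_values`` are inner-filter-corrected intensities at the reference
    wavelength, aligned with ``series.ligand_concs``; the first entry (ligand
    free) is F0.  Points with F >= F0 (no quench) or a non-positive corrected
    free-ligand concentration are excluded with a warning.
    """
    F = np.asarray(F_values, dtype=float)
    if F.size != len(series):
        raise ValueError("F_values length must match the titration grid")
    f0 = F[0]
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    xs, ys = [], []
    for dt, f in zip(series.ligand_concs[1:], F[1:]):
        if f >= f0 or f <= 0:
            continue
        quench_frac = (f0 - f) / f0
        free = dt - quench_frac * series.protein_conc  # mass balance
        if free <= 0:
            warnings.warn(
                f"corrected free-ligand concentration non-positive at [D_T]={dt:g}; "
                "point excluded", stacklevel=2,
            )
            continue
        xs.append(np.log10(free))
        ys.append(np.log10((f0 - f) / f))
    return np.asarray(xs), np.asarray(ys)


def fit_binding_isotherm(series: TitrationSeries,
                         F_values: Sequence[float]) -> BindingFit:
    """Fit K_a and n from the mass-balance-corrected double-log plot.

    OLS of log[(F0-F)/F] on log[D_free]; slope = n, intercept = n log10 K_a so
    K_a = 10**(intercept/slope).  Requires >= 4 usable points with F < F0.
    """
    x, y = binding_points(series, F_values)
    if x.size < 4:
        raise ValueError(
            f"only {x.size} usable titration points (need >= 4 with F < F0 and "
            "positive corrected free-ligand concentration)"
        )
    res = stats.linregress(x, y)
    n = float(res.slope)
    if n <= 0:
        raise ValueError("non-positive slope: no binding signal in the data")
    log_ka = float(res.intercept) / n
    # delta-method propagation of the intercept/slope ratio
    if res.intercept != 0 and np.isfinite(res.intercept_stderr):
        log_ka_se = abs(log_ka) * float(np.hypot(
            res.intercept_stderr / res.intercept, res.stderr / res.slope))
    else:
        log_ka_se = float("nan")
    return BindingFit(
        K_a=float(10.0 ** log_ka), n=n, r_squared=float(res.rvalue ** 2),
        temperature=series.temperature, points_used=int(x.size),
        log_Ka_stderr=float(log_ka_se), n_stderr=float(res.stderr),
    )


def vant_hoff_fit(K_by_T: Mapping[float, float],
                  gas_constant: float = GAS_CONSTANT) -> ThermoFit:
    """OLS of ln K_a versus 1/T (T in kelvin): dH = -R slope, dS = R intercept.

    ``K_by_T`` maps absolute temperature (K) to the association constant
    (M^-1).  dG(T) = dH - T dS is evaluated at each input temperature.
    """
    if len(K_by_T) < 2:
        raise ValueError("need K_a at >= 2 temperatures")
    temps = np.array(sorted(K_by_T), dtype=float)
    if np.any(np.diff(temps) == 0):
        raise ValueError("duplicate temperatures")
    ks = np.array([K_by_T[t] for t in temps], dtype=float)
    if np.any(ks <= 0):
        raise ValueError("association constants must be positive")
    inv_t = 1.0 / temps
    ln_k = np.log(ks)
    if len(temps) == 2:
        slope = (ln_k[1] - ln_k[0]) / (inv_t[1] - inv_t[0])
        intercept = ln_k[0] - slope * inv_t[0]
        r2 = 1.0
    else:
        res = stats.linregress(inv_t, ln_k)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue ** 2
    delta_h = -gas_constant * slope / 1000.0       # kJ mol^-1
    delta_s = gas_constant * intercept             # J mol^-1 K^-1
    dg = {float(t): gibbs_free_energy(delta_h, delta_s, float(t)) for t in temps}
    return ThermoFit(
        delta_H=float(delta_h), delta_S=float(delta_s),
        delta_G_by_T=dg, vant_hoff_r_squared=float(r2),
        gas_constant=gas_constant,
    )


def gibbs_free_energy(delta_H: float, delta_S: float, T: float) -> float:
    """dG = dH - T dS, with dH in kJ mol^-1, dS in J mol^-1 K^-1, T in kelvin.

    Returns kJ mol^-1.
    """
    if T <= 0:
        raise ValueError("absolute temperature must be positive")
    return delta_H - T * delta_S / 1000.0


def vant_hoff_from_celsius(K_by_t_celsius: Mapping[float, float],
                           paper_mode: bool = False,
                           gas_constant: float = GAS_CONSTANT) -> ThermoFit:
    """Convenience wrapper: van't Hoff fit from Celsius-keyed K_a values."""
    return vant_hoff_fit(
        {to_kelvin(t, paper_mode=paper_mode): k for t, k in K_by_t_celsius.items()},
        gas_constant=gas_constant,
    )
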