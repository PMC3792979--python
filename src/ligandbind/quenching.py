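"""Inner-filter correction and Stern-Volmer analysis of quench titrations.

The Stern-Volmer relation F0/F = 1 + K_SV [Q] is fitted by ordinary least
squares over the retained linear region (quench plots of strong binders curve
upward at high quencher concentration as static complexation saturates, so
only the linear low-concentration zone is regressed).  The bimolecular
quenching constant k_q = K_SV / tau0 against the diffusion-controlled limit
(~1e10 M^-1 s^-1) and the temperature trend of K_SV together distinguish
static from dynamic quenching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .spectra import Spectrum, TitrationSeries, intensity_at

__all__ = [
    "QuenchPoint",
    "SternVolmerResult",
    "inner_filter_correct",
    "correct_spectrum",
    "quench_points_from_series",
    "select_linear_region",
    "stern_volmer_fit",
    "bimolecular_quenching_constant",
    "classify_quenching",
    "DIFFUSION_LIMIT",
    "TAU0_HSA",
]

#: Diffusion-controlled quenching limit, M^-1 s^-1.
DIFFUSION_LIMIT = 1.0e10

#: Unquenched fluorescence lifetime of native human serum albumin, seconds.
TAU0_HSA = 6.38e-9


@dataclass(frozen=True)
class QuenchPoint:
    """One titration point reduced to intensities at the reference wavelength."""

    ligand_conc: float  # molar, [Q]
    F0: float           # unquenched intensity
    F: float            # (corrected) intensity at the same wavelength
    A_ex: float = 0.0   # absorbance increment at the excitation wavelength
    A_em: float = 0.0   # absorbance increment at the emission wavelength

    def __post_init__(self) -> None:
        if self.F0 <= 0 or self.F <= 0:
            raise ValueError("intensities must be positive")
        if self.F > self.F0 * (1 + 1e-9):
            warnings.warn(
                f"F ({self.F:g}) exceeds F0 ({self.F0:g}) at [Q]={self.ligand_conc:g}; "
                "enhancement rather than quenching",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SternVolmerResult:
    """Stern-Volmer regression summary at one temperature."""

    K_SV: float                  # M^-1
    intercept: float             # dimensionless, expected ~1
    r_squared: float
    retained_range: tuple[int, int]  # half-open [start, stop) indices used
    K_SV_stderr: float = float("nan")
    tau0: float | None = None    # s
    k_q: float | None = None     # M^-1 s^-1, K_SV / tau0 when tau0 given
    n_points: int = 0

    @property
    def exceeds_diffusion_limit(self) -> bool:
        return self.k_q is not None and self.k_q > DIFFUSION_LIMIT


def inner_filter_correct(F_obs, A_ex, A_em):
    """Correct observed fluorescence for the inner-filter effect.

    F_cor = F_obs * 10**((A_ex + A_em) / 2), the geometric-mean attenuation
    correction for a 1 cm cuvette with centred excitation/emission paths.
    ``A_ex``/``A_em`` are the absorbance *increments* caused by the added
    ligand at the excitation and emission wavelengths.  Accepts scalars or
    arrays (per-wavelength correction of a full spectrum).
    """
    A_ex = np.asarray(A_ex, dtype=float)
    A_em = np.asarray(A_em, dtype=float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValueError("absorbance increments must be non-negative")
    out = np.asarray(F_obs, dtype=float) * 10.0 ** ((A_ex + A_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def correct_spectrum(spectrum: Spectrum, A_ex: float,
                     absorbance: Spectrum | float) -> Spectrum:
    """Inner-filter-correct a full emission spectrum.

    ``absorbance`` may be a scalar A_em (peak mode) or an absorbance spectrum,
    in which case A_em is evaluated at each emission wavelength
    (per-wavelength mode, the default convention of the pipeline).
    """
    if isinstance(absorbance, Spectrum):
        a_em = np.array([intensity_at(absorbance, wl) for wl in spectrum.wavelengths])
    else:
        a_em = np.full(len(spectrum), float(absorbance))
    vals = inner_filter_correct(spectrum.values, A_ex, a_em)
    return Spectrum(spectrum.wavelengths, vals, kind=spectrum.kind, meta=dict(spectrum.meta))


def quench_points_from_series(series: TitrationSeries,
                              reference_wavelength: float | None = None,
                              correction: str = "pair") -> list[QuenchPoint]:
    """Reduce a titration series to Stern-Volmer points F0/F at one wavelength.

    The reference wavelength defaults to the emission maximum of the
    ligand-free (first) spectrum.  ``correction``: ``"pair"`` applies the
    inner-filter factor from the series' per-point (A_ex, A_em) pairs;
    ``"none"`` uses raw intensities.  The first point must be ligand-free
    ([Q] = 0); it defines F0.
    """
    if series.ligand_concs[0] != 0:
        raise ValueError("series must start at ligand concentration 0 (defines F0)")
    if correction not in ("pair", "none"):
        raise ValueError("correction must be 'pair' or 'none'")
    if correction == "pair" and series.absorbance_pairs is None:
        raise ValueError("series has no absorbance pairs; use correction='none'")
    if reference_wavelength is None:
        reference_wavelength = series.spectra[0].peak_wavelength

    intensities = []
    for i, spec in enumerate(series.spectra):
        f = intensity_at(spec, reference_wavelength)
        if correction == "pair":
            a_ex, a_em = series.absorbance_pairs[i]
            f = inner_filter_correct(f, a_ex, a_em)
        intensities.append(f)
    f0 = intensities[0]
    points = []
    for i, (q, f) in enumerate(zip(series.ligand_concs, intensities)):
        a_ex, a_em = (series.absorbance_pairs[i]
                      if series.absorbance_pairs is not None else (0.0, 0.0))
        points.append(QuenchPoint(float(q), f0, f, a_ex, a_em))
    return points


def _ols(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue ** 2, res.stderr


def _sign_runs(residuals: np.ndarray) -> int:
    """Number of sign runs among non-negligible residuals."""
    scale = np.max(np.abs(residuals)) if residuals.size else 0.0
    signs = np.sign(residuals[np.abs(residuals) > 1e-12 * max(scale, 1.0)])
    signs = signs[signs != 0]
    if signs.size == 0:
        return 0
    return int(1 + np.sum(signs[1:] != signs[:-1]))


def select_linear_region(points: Sequence[QuenchPoint],
                         r2_min: float = 0.995) -> tuple[int, int]:
    """Largest prefix of the quench series that is adequately linear.

    Scans prefixes starting at [Q] = 0 and keeps the longest one whose OLS fit
    of F0/F vs [Q] has r^2 >= ``r2_min`` and whose residuals show no
    systematic curvature (a sign-run gate: a long prefix whose residual signs
    collapse into <= 3 runs is rejected, the classic end-up/middle-down
    signature of upward curvature).  Exact fits pass unconditionally.  Falls
    back to the full range with a warning when no prefix of length >= 3
    qualifies.  Deterministic for fixed inputs.
    """
    n = len(points)
    if n < 3:
        raise ValueError("need at least 3 points")
    x = np.array([p.ligand_conc for p in points])
    y = np.array([p.F0 / p.F for p in points])

    best_stop = 0
    for stop in range(3, n + 1):
        slope, intercept, r2, _ = _ols(x[:stop], y[:stop])
        resid = y[:stop] - (slope * x[:stop] + intercept)
        # exact fit (zero residual to numerical precision) always qualifies
        exact = np.max(np.abs(resid)) <= 1e-9 * max(1.0, np.max(np.abs(y[:stop])))
        if exact:
            best_stop = stop
            continue
        if r2 < r2_min:
            continue
        if stop >= 6 and _sign_runs(resid) <= 3:
            continue
        best_stop = stop
    if best_stop < 3:
        warnings.warn(
            "no linear prefix of length >= 3 found; falling back to full range",
            stacklevel=2,
        )
        return (0, n)
    return (0, best_stop)


def stern_volmer_fit(points: Sequence[QuenchPoint],
                     tau0: float | None = None,
                     r2_min: float = 0.995,
                     auto_range: bool = True) -> SternVolmerResult:
    """Fit F0/F = intercept + K_SV [Q] over the retained linear region.

    The intercept is not constrained to 1; a deviation beyond 5% triggers a
    warning.  With ``tau0`` supplied, k_q = K_SV / tau0 is reported.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points including [Q] = 0")
    if points[0].ligand_conc != 0:
        raise ValueError("first point must be the ligand-free reference ([Q] = 0)")
    start, stop = select_linear_region(points, r2_min=r2_min) if auto_range else (0, len(points))
    x = np.array([p.ligand_conc for p in points[start:stop]])
    y = np.array([p.F0 / p.F for p in points[start:stop]])

    if np.allclose(y, y[0]):
        warnings.warn("no quenching detected (F == F0 throughout); K_SV ~ 0",
                      stacklevel=2)
        slope, intercept, r2, stderr = 0.0, float(y[0]), 1.0, 0.0
    else:
        slope, intercept, r2, stderr = _ols(x, y)
        if abs(intercept - 1.0) > 0.05:
            warnings.warn(
                f"Stern-Volmer intercept {intercept:.3f} deviates from 1 by > 5%",
                stacklevel=2,
            )
    k_q = slope / tau0 if tau0 is not None else None
    return SternVolmerResult(
        K_SV=float(slope), intercept=float(intercept), r_squared=float(r2),
        retained_range=(start, stop), K_SV_stderr=float(stderr),
        tau0=tau0, k_q=k_q, n_points=stop - start,
    )


def bimolecular_quenching_constant(K_SV: float, tau0: float) -> float:
    """k_q = K_SV / tau0 (M^-1 s^-1); tau0 is the unquenched lifetime."""
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    return K_SV / tau0


@dataclass(frozen=True)
class QuenchClassification:
    label: str                       # "static" | "dynamic" | "ambiguous"
    above_diffusion_limit: bool | None
    K_SV_by_T: Mapping[float, float] = field(default_factory=dict)


def classify_quenching(results_by_temperature: Mapping[float, SternVolmerResult],
                       diffusion_limit: float = DIFFUSION_LIMIT) -> QuenchClassification:
    """Classify the quenching mechanism from the temperature trend of K_SV.

    K_SV strictly decreasing with temperature indicates static quenching
    (ground-state complex dissociating on warming); strictly increasing
    indicates dynamic (collisional) quenching; anything else is ambiguous.
    Additionally reports whether min(k_q) exceeds the diffusion limit, the
    second static-quenching indicator.
    """
    if len(results_by_temperature) < 2:
        raise ValueError("need results at >= 2 temperatures")
    temps = sorted(results_by_temperature)
    ksv = [results_by_temperature[t].K_SV for t in temps]
    diffs = np.diff(ksv)
    if np.all(diffs < 0):
        label = "static"
    elif np.all(diffs > 0):
        label = "dynamic"
    else:
        label = "ambiguous"
    kqs = [results_by_temperature[t].k_q for t in temps]
    above = (bool(min(kqs) > diffusion_limit)
             if all(k is not None for k in kqs) else None)
    return QuenchClassification(label, above, dict(zip(temps, ksv)))
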