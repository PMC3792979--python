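"""Conformational-change metrics from synchronous, 3-D fluorescence, and CD.

Synchronous scans (constant offset Δλ between excitation and emission) report
on the tyrosine (Δλ = 15 nm) or tryptophan (Δλ = 60 nm) microenvironment:
a blue shift of the band maximum on ligand addition indicates increased
hydrophobicity around the fluorophore.  Excitation-emission matrices expose
protein peaks flanked by Rayleigh (λ_em = λ_ex) and second-order
(λ_em = 2 λ_ex) scatter ridges.  Far-UV CD ellipticity at 222 nm, converted
to mean residue ellipticity, tracks α-helical content through a thermal
denaturation/renaturation cycle; the fraction of the native signal regained
after cooling measures reversibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .spectra import EEMSurface, MeltCurve, SpectraError, Spectrum

__all__ = [
    "PeakRecord",
    "MeltAnalysis",
    "peak_wavelength",
    "synchronous_shift",
    "find_3d_peaks",
    "peak_trajectory",
    "mre_convert",
    "melt_analysis",
    "HSA_N_RESIDUES",
]

#: Residue count of the human serum albumin polypeptide chain.
HSA_N_RESIDUES = 585


@dataclass(frozen=True)
class PeakRecord:
    """One local maximum of an excitation-emission surface."""

    excitation: float  # nm
    emission: float    # nm
    intensity: float   # a.u.
    label: str         # rayleigh_a | second_order_b | peak1 | peak2 | other

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class MeltAnalysis:
    """Summary of a thermal denaturation/renaturation cycle."""

    onset_T: float | None          # Celsius; None when no transition detected
    transition_range: tuple[float, float] | None
    signal_at_start: float
    signal_at_end: float
    recovery_percent: float

    def __post_init__(self) -> None:
        if self.recovery_percent > 110:
            warnings.warn(
                f"recovery {self.recovery_percent:.1f}% exceeds 110%; "
                "check baselines", stacklevel=2,
            )


def peak_wavelength(spectrum: Spectrum) -> float:
    """Band maximum with 3-point parabolic refinement around the discrete argmax.

    Raises for a flat spectrum (no unique maximum).
    """
    vals = spectrum.values
    if np.allclose(vals, vals[0]):
        raise SpectraError("flat spectrum has no unique maximum")
    i = int(np.argmax(vals))
    wl = spectrum.wavelengths
    if i == 0 or i == len(vals) - 1:
        return float(wl[i])  # edge maximum: no parabola available
    x0, x1, x2 = wl[i - 1], wl[i], wl[i + 1]
    y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    if a >= 0:  # degenerate curvature; keep the grid point
        return float(x1)
    return float(-b / (2 * a))


def synchronous_shift(spectra: Sequence[Spectrum],
                      delta_lambda: float | None = None
                      ) -> tuple[list[float], float]:
    """Peak positions along a synchronous titration and the net shift.

    All spectra must carry the same ``delta_lambda_nm`` metadata tag (checked
    against ``delta_lambda`` when given).  Returns the refined peak wavelength
    of each spectrum and the net shift (last − first); negative = blue shift.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to measure a shift")
    tags = {s.meta.get("delta_lambda_nm") for s in spectra}
    if len(tags) > 1:
        raise ValueError(f"mixed delta-lambda tags in series: {sorted(map(str, tags))}")
    tag = tags.pop()
    if delta_lambda is not None and tag is not None and float(tag) != float(delta_lambda):
        raise ValueError(
            f"series tagged delta_lambda={tag} nm, expected {delta_lambda} nm"
        )
    peaks = [peak_wavelength(s) for s in spectra]
    return peaks, peaks[-1] - peaks[0]


def _classify_eem_point(ex: float, em: float, scatter_tol: float) -> str | None:
    if abs(em - ex) <= scatter_tol:
        return "rayleigh_a"
    if abs(em - 2.0 * ex) <= scatter_tol:
        return "second_order_b"
    return None


def find_3d_peaks(surface: EEMSurface, scatter_tol: float = 5.0,
                  min_rel_intensity: float = 1e-3) -> list[PeakRecord]:
    """Local maxima of an EEM surface, scatter ridges labelled and set aside.

    Strict 8-neighbourhood local maxima; ridge points within ``scatter_tol``
    nm of λ_em = λ_ex are labelled ``rayleigh_a`` and of λ_em = 2 λ_ex
    ``second_order_b``.  The remaining maxima are ranked by intensity and
    labelled ``peak1``, ``peak2``, then ``other``.  Maxima below
    ``min_rel_intensity`` of the global maximum are dropped (numerical
    ripple); a flat surface yields an empty list.
    """
    z = surface.intensity
    if np.allclose(z, z.flat[0]):
        return []
    # strict local maxima: exceed the max of the 8 neighbours (centre excluded)
    ring = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)
    neighbor_max = ndimage.maximum_filter(z, footprint=ring, mode="constant",
                                          cval=-np.inf)
    is_peak = z > neighbor_max
    threshold = min_rel_intensity * float(z.max())
    scatter: list[PeakRecord] = []
    genuine: list[tuple[float, float, float]] = []
    for i, j in zip(*np.nonzero(is_peak)):
        ex = float(surface.excitation_grid[i])
        em = float(surface.emission_grid[j])
        inten = float(z[i, j])
        if inten < threshold:
            continue
        label = _classify_eem_point(ex, em, scatter_tol)
        if label is not None:
            scatter.append(PeakRecord(ex, em, inten, label))
        else:
            genuine.append((ex, em, inten))
    genuine.sort(key=lambda t: -t[2])
    records = [
        PeakRecord(ex, em, inten,
                   "peak1" if k == 0 else "peak2" if k == 1 else "other")
        for k, (ex, em, inten) in enumerate(genuine)
    ]
    return records + scatter


def peak_trajectory(surfaces: Sequence[EEMSurface], scatter_tol: float = 5.0,
                    match_tol: float = 10.0) -> dict[float, list[PeakRecord | None]]:
    """Track non-scatter peaks across an ordered list of EEM surfaces.

    Peaks are matched by nearest excitation line of the first surface's
    peaks (within ``match_tol`` nm).  The result maps each reference
    excitation wavelength to the per-surface PeakRecord sequence, with None
    marking a surface in which the peak was not found (gap).
    """
    if not surfaces:
        raise ValueError("need at least one surface")
    per_surface = [
        [p for p in find_3d_peaks(s, scatter_tol=scatter_tol)
         if p.label in ("peak1", "peak2", "other")]
        for s in surfaces
    ]
    reference = per_surface[0]
    if not reference:
        raise ValueError("no non-scatter peaks in the first surface")
    traj: dict[float, list[PeakRecord | None]] = {p.excitation: [] for p in reference}
    for peaks in per_surface:
        taken: set[int] = set()
        for ref_ex in traj:
            best, best_d = None, match_tol
            for k, p in enumerate(peaks):
                d = abs(p.excitation - ref_ex)
                if k not in taken and d <= best_d:
                    best, best_d = k, d
            if best is None:
                traj[ref_ex].append(None)
                warnings.warn(
                    f"peak at excitation {ref_ex:g} nm missing in one surface",
                    stacklevel=2,
                )
            else:
                taken.add(best)
                traj[ref_ex].append(peaks[best])
    return traj


def mre_convert(theta_mdeg, path_length_cm: float, protein_conc_M: float,
                n_residues: int = HSA_N_RESIDUES):
    """Mean residue ellipticity (deg cm^2 dmol^-1) from observed millidegrees.

    MRE = θ_mdeg / (10 · n_residues · C_molar · path_cm), the molar-
    concentration form of the per-residue normalization.
    """
    if path_length_cm <= 0 or protein_conc_M <= 0 or n_residues <= 0:
        raise ValueError("path length, concentration and residue count must be positive")
    out = np.asarray(theta_mdeg, dtype=float) / (
        10.0 * n_residues * protein_conc_M * path_length_cm)
    return float(out) if out.ndim == 0 else out


def melt_analysis(forward: MeltCurve, reverse: MeltCurve,
                  baseline_window: tuple[float, float] = (25.0, 40.0),
                  evaluation_T: float | None = None) -> MeltAnalysis:
    """Onset of thermal unfolding and renaturation recovery.

    The pre-transition baseline is the mean signal of the forward scan inside
    ``baseline_window``; the onset is the first temperature beyond the window
    at which |signal − baseline| exceeds 3× the SD of the baseline segment
    (with a 0.5% relative floor so noise-free data do not trigger on rounding).
    Recovery is the reverse-scan signal at the evaluation temperature
    (default: the shared scan-start temperature) as a percentage of the
    forward-scan signal there.
    """
    f_t, f_s = forward.temperatures, forward.signal
    if f_t[0] > f_t[-1]:
        f_t, f_s = f_t[::-1], f_s[::-1]
    r_t = reverse.temperatures
    lo = max(f_t.min(), r_t.min())
    hi = min(f_t.max(), r_t.max())
    if lo > hi:
        raise SpectraError("forward and reverse scans do not overlap in temperature")
    start_T = evaluation_T if evaluation_T is not None else float(lo)

    mask = (f_t >= baseline_window[0]) & (f_t <= baseline_window[1])
    if mask.sum() < 2:
        raise SpectraError(
            f"fewer than 2 forward-scan points in baseline window {baseline_window}"
        )
    baseline = float(f_s[mask].mean())
    noise = float(f_s[mask].std(ddof=1))
    band = max(3.0 * noise, 5e-3 * abs(baseline))

    onset = None
    after = f_t > baseline_window[1]
    dev = np.abs(f_s - baseline)
    hits = np.nonzero(after & (dev > band))[0]
    if hits.size:
        onset = float(f_t[hits[0]])
        onset_range = (onset, float(f_t[min(hits[-1], len(f_t) - 1)]))
    else:
        onset_range = None
        warnings.warn("no thermal transition detected (signal stays within the "
                      "baseline noise band)", stacklevel=2)

    fwd_start = forward.at(start_T)
    rev_start = reverse.at(start_T)
    if fwd_start == 0:
        raise SpectraError("forward signal at the evaluation temperature is zero")
    recovery = 100.0 * rev_start / fwd_start
    return MeltAnalysis(
        onset_T=onset, transition_range=onset_range,
        signal_at_start=float(fwd_start), signal_at_end=float(f_s[-1]),
        recovery_percent=float(recovery),
    )
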