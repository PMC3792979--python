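"""Domain types, unit conventions, and CSV readers/writers for spectral data.

All wavelengths are nanometres, concentrations molar, temperatures degrees
Celsius at the package boundary.  Thermodynamic routines convert to kelvin
internally (see :func:`to_kelvin`).  The single on-disk format is long-format
CSV, UTF-8, with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "TitrationSeries",
    "EEMSurface",
    "MeltCurve",
    "SpectraError",
    "ParseError",
    "to_kelvin",
    "intensity_at",
    "read_series",
    "write_series",
    "read_eem",
    "write_eem",
    "read_melt",
    "write_melt",
    "union_grid",
]

#: Recognised spectrum kinds.
SPECTRUM_KINDS = ("emission", "absorbance", "cd", "synchronous")

#: Celsius -> kelvin offsets.  ``paper_mode`` uses the rounded 273 offset that
#: older spectroscopy tables were computed with; the default is exact.
KELVIN_OFFSET_EXACT = 273.15
KELVIN_OFFSET_ROUNDED = 273.0

#: Gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314


class SpectraError(ValueError):
    """Invalid spectral data (invariant violation)."""


class ParseError(SpectraError):
    """Malformed on-disk spectral file."""


def to_kelvin(temperature_c: float, paper_mode: bool = False) -> float:
    """Convert Celsius to kelvin.

    ``paper_mode=True`` uses T = t + 273 (the convention under which published
    ΔG tables computed from ΔH − TΔS round consistently); default is +273.15.
    """
    offset = KELVIN_OFFSET_ROUNDED if paper_mode else KELVIN_OFFSET_EXACT
    return float(temperature_c) + offset


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """A 1-D spectrum: a strictly increasing wavelength grid with values.

    Parameters
    ----------
    wavelengths :
        Grid in nm, strictly increasing, length >= 2.
    values :
        Signal values, same length.  Units depend on ``kind``: fluorescence in
        arbitrary units, absorbance dimensionless, CD in millidegrees.
    kind :
        One of ``emission``, ``absorbance``, ``cd``, ``synchronous``.
    meta :
        Free-form annotations, e.g. ``{"excitation_nm": 280, "delta_lambda_nm":
        60, "temperature_C": 25.0}``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "emission"
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in SPECTRUM_KINDS:
            raise SpectraError(
                f"unknown spectrum kind {self.kind!r}; expected one of {SPECTRUM_KINDS}"
            )
        if wl.ndim != 1 or wl.size < 2:
            raise SpectraError("wavelength grid must be 1-D with at least 2 points")
        if vals.shape != wl.shape:
            raise SpectraError(
                f"values length {vals.size} does not match wavelengths length {wl.size}"
            )
        if not np.all(np.diff(wl) > 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise SpectraError("non-finite wavelength or value")
        if self.kind in ("emission", "absorbance") and np.any(vals < 0):
            raise SpectraError(f"{self.kind} values must be non-negative")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def peak_wavelength(self) -> float:
        """Wavelength of the discrete maximum."""
        return float(self.wavelengths[int(np.argmax(self.values))])


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered ligand titration: one spectrum per ligand concentration."""

    protein_conc: float          # molar, [P_T]
    ligand_concs: np.ndarray     # molar, [D_T] grid, ascending, first may be 0
    temperature: float           # Celsius
    spectra: tuple[Spectrum, ...]
    #: optional per-point (A_ex, A_em) absorbance increments for inner-filter
    #: inversion; same length as ``ligand_concs`` when present.
    absorbance_pairs: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        lig = np.asarray(self.ligand_concs, dtype=float)
        object.__setattr__(self, "ligand_concs", lig)
        object.__setattr__(self, "spectra", tuple(self.spectra))
        if self.protein_conc <= 0:
            raise SpectraError("protein concentration must be positive")
        if np.any(lig < 0):
            raise SpectraError("ligand concentrations must be non-negative")
        if not np.all(np.diff(lig) > 0):
            raise SpectraError("ligand concentrations must be strictly increasing")
        if len(self.spectra) != lig.size:
            raise SpectraError(
                f"{len(self.spectra)} spectra for {lig.size} ligand concentrations"
            )
        if self.absorbance_pairs is not None:
            pairs = tuple((float(a), float(b)) for a, b in self.absorbance_pairs)
            object.__setattr__(self, "absorbance_pairs", pairs)
            if len(pairs) != lig.size:
                raise SpectraError("absorbance_pairs length mismatch")

    def __len__(self) -> int:
        return int(self.ligand_concs.size)

    def __iter__(self) -> Iterator[tuple[float, Spectrum]]:
        return iter(zip(self.ligand_concs, self.spectra))


@dataclass(frozen=True)
class EEMSurface:
    """Excitation-emission matrix: intensity indexed [excitation][emission]."""

    excitation_grid: np.ndarray
    emission_grid: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation_grid, dtype=float)
        em = np.asarray(self.emission_grid, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "excitation_grid", ex)
        object.__setattr__(self, "emission_grid", em)
        object.__setattr__(self, "intensity", z)
        for name, grid in (("excitation", ex), ("emission", em)):
            if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
                raise SpectraError(f"{name} grid must be 1-D strictly increasing")
        if z.shape != (ex.size, em.size):
            raise SpectraError(
                f"intensity shape {z.shape} does not match grids ({ex.size}, {em.size})"
            )


@dataclass(frozen=True)
class MeltCurve:
    """Thermal scan of mean residue ellipticity at 222 nm."""

    temperatures: np.ndarray   # Celsius, strictly monotone in scan direction
    signal: np.ndarray         # MRE222, deg cm^2 dmol^-1
    direction: str = "forward"  # "forward" (heating) or "reverse" (cooling)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", s)
        if self.direction not in ("forward", "reverse"):
            raise SpectraError("direction must be 'forward' or 'reverse'")
        if t.ndim != 1 or t.size < 2 or s.shape != t.shape:
            raise SpectraError("temperatures/signal must be 1-D, same length >= 2")
        d = np.diff(t)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise SpectraError("temperatures must be strictly monotone")

    def at(self, temperature_c: float) -> float:
        """Signal linearly interpolated at ``temperature_c``."""
        t, s = self.temperatures, self.signal
        if t[0] > t[-1]:
            t, s = t[::-1], s[::-1]
        if not (t[0] <= temperature_c <= t[-1]):
            raise SpectraError(
                f"temperature {temperature_c} outside scan range [{t[0]}, {t[-1]}]"
            )
        return float(np.interp(temperature_c, t, s))


# ---------------------------------------------------------------------------
# Interpolation helpers
# ---------------------------------------------------------------------------

def intensity_at(spectrum: Spectrum, wavelength: float) -> float:
    """Signal at ``wavelength`` by linear interpolation; exact at grid points.

    Raises :class:`SpectraError` for a wavelength outside the grid range.
    """
    wl = spectrum.wavelengths
    if not (wl[0] <= wavelength <= wl[-1]):
        raise SpectraError(
            f"wavelength {wavelength} nm outside grid range [{wl[0]}, {wl[-1]}] nm"
        )
    return float(np.interp(wavelength, wl, spectrum.values))


def union_grid(a: Spectrum, b: Spectrum) -> np.ndarray:
    """Union of both wavelength grids restricted to the overlap interval.

    Cross-spectrum arithmetic interpolates both spectra onto this grid so the
    effective resolution is that of the finer spectrum.  Empty if the supports
    do not overlap.
    """
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if lo > hi:
        return np.empty(0)
    grid = np.union1d(a.wavelengths, b.wavelengths)
    return grid[(grid >= lo) & (grid <= hi)]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_SERIES_COLUMNS = [
    "series_id", "kind", "temperature_C", "protein_conc_M",
    "ligand_conc_M", "wavelength_nm", "value",
]


def write_series(series: TitrationSeries, path, series_id: str = "series") -> None:
    """Write a titration series as long-format CSV (inverse of read_series)."""
    rows = []
    has_abs = series.absorbance_pairs is not None
    for i, (dt, spec) in enumerate(series):
        for wl, val in zip(spec.wavelengths, spec.values):
            row = {
                "series_id": series_id,
                "kind": spec.kind,
                "temperature_C": series.temperature,
                "protein_conc_M": series.protein_conc,
                "ligand_conc_M": dt,
                "wavelength_nm": wl,
                "value": val,
            }
            if has_abs:
                row["A_ex"], row["A_em"] = series.absorbance_pairs[i]
            rows.append(row)
    df = pd.DataFrame(rows)
    if not np.all(np.isfinite(df["value"].to_numpy())):
        raise SpectraError("refusing to write non-finite signal values")
    df.to_csv(path, index=False, float_format="%.17g")


def read_series(path, series_id: str | None = None) -> TitrationSeries:
    """Read a long-format titration CSV into a validated TitrationSeries.

    Expected columns: ``series_id, kind, temperature_C, protein_conc_M,
    ligand_conc_M, wavelength_nm, value`` with optional ``A_ex, A_em`` repeated
    on every row of a titration point.
    """
    df = pd.read_csv(path)
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if series_id is not None:
        df = df[df["series_id"] == series_id]
        if df.empty:
            raise ParseError(f"{path}: no rows with series_id {series_id!r}")
    elif df["series_id"].nunique() > 1:
        raise ParseError(
            f"{path}: multiple series present {sorted(df['series_id'].unique())}; "
            "pass series_id"
        )
    has_abs = "A_ex" in df.columns and "A_em" in df.columns

    temperature = float(df["temperature_C"].iloc[0])
    protein = float(df["protein_conc_M"].iloc[0])
    kind = str(df["kind"].iloc[0])

    spectra: list[Spectrum] = []
    ligands: list[float] = []
    pairs: list[tuple[float, float]] = []
    for dt, grp in df.groupby("ligand_conc_M", sort=True):
        wl = grp["wavelength_nm"].to_numpy(dtype=float)
        vals = grp["value"].to_numpy(dtype=float)
        if not np.all(np.diff(wl) > 0):
            bad = int(np.flatnonzero(np.diff(wl) <= 0)[0])
            raise ParseError(
                f"{path}: non-increasing wavelength at ligand_conc_M={dt}, "
                f"row index {grp.index[bad + 1]}"
            )
        meta = {"temperature_C": temperature}
        try:
            spectra.append(Spectrum(wl, vals, kind=kind, meta=meta))
        except SpectraError as err:
            raise ParseError(f"{path}: ligand_conc_M={dt}: {err}") from err
        ligands.append(float(dt))
        if has_abs:
            pairs.append((float(grp["A_ex"].iloc[0]), float(grp["A_em"].iloc[0])))
    try:
        return TitrationSeries(
            protein_conc=protein,
            ligand_concs=np.asarray(ligands),
            temperature=temperature,
            spectra=tuple(spectra),
            absorbance_pairs=tuple(pairs) if has_abs else None,
        )
    except SpectraError as err:
        raise ParseError(f"{path}: {err}") from err


def write_eem(surface: EEMSurface, path) -> None:
    """Write an excitation-emission matrix as tidy CSV."""
    ex, em = np.meshgrid(surface.excitation_grid, surface.emission_grid, indexing="ij")
    pd.DataFrame({
        "excitation_nm": ex.ravel(),
        "emission_nm": em.ravel(),
        "value": surface.intensity.ravel(),
    }).to_csv(path, index=False, float_format="%.17g")


def read_eem(path) -> EEMSurface:
    """Read a tidy EEM CSV (columns excitation_nm, emission_nm, value)."""
    df = pd.read_csv(path)
    for col in ("excitation_nm", "emission_nm", "value"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    ex = np.unique(df["excitation_nm"].to_numpy(dtype=float))
    em = np.unique(df["emission_nm"].to_numpy(dtype=float))
    pivot = df.pivot_table(index="excitation_nm", columns="emission_nm", values="value")
    if pivot.isna().any().any():
        raise ParseError(f"{path}: EEM grid is not complete (missing cells)")
    try:
        return EEMSurface(ex, em, pivot.to_numpy(dtype=float))
    except SpectraError as err:
        raise ParseError(f"{path}: {err}") from err


def write_melt(curves: Sequence[MeltCurve], path) -> None:
    """Write melt curves as tidy CSV (direction, temperature_C, mre222)."""
    frames = [
        pd.DataFrame({
            "direction": c.direction,
            "temperature_C": c.temperatures,
            "mre222": c.signal,
        })
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_melt(path) -> dict[str, MeltCurve]:
    """Read a melt CSV into a dict keyed by scan direction."""
    df = pd.read_csv(path)
    for col in ("direction", "temperature_C", "mre222"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    out: dict[str, MeltCurve] = {}
    for direction, grp in df.groupby("direction"):
        try:
            out[str(direction)] = MeltCurve(
                grp["temperature_C"].to_numpy(dtype=float),
                grp["mre222"].to_numpy(dtype=float),
                direction=str(direction),
            )
        except SpectraError as err:
            raise ParseError(f"{path}: direction={direction}: {err}") from err
    return out
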