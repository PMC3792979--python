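"""Site-marker displacement analysis for serum-albumin binding-site assignment.

A marker ligand with a known binding site (Sudlow site I: warfarin,
bilirubin; site II: diazepam, ketoprofen) produces an induced optical signal
when bound.  Titrating the marker-protein complex with a competitor and
following the signal relative to its competitor-free value quantifies
displacement; a competitor that strips every marker of one site while leaving
the other site's markers in place is assigned that site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DisplacementSeries",
    "SiteAssignment",
    "relative_signal",
    "displacement_at_ratio",
    "assign_site",
]


@dataclass(frozen=True)
class DisplacementSeries:
    """Marker signal versus competitor:protein molar ratio."""

    marker: str                 # e.g. "warfarin"
    site: str                   # "I" or "II" (the marker's known site)
    signal_wavelength: float    # nm
    molar_ratios: np.ndarray    # competitor/protein, ascending from 0
    signals: np.ndarray         # raw induced signal (sign preserved)
    #: optional competitor-protein complex baseline at the same ratios, to be
    #: subtracted before normalization (handles markers whose monitoring
    #: wavelength overlaps a native competitor-complex band)
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.molar_ratios, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "molar_ratios", r)
        object.__setattr__(self, "signals", s)
        if self.site not in ("I", "II"):
            raise ValueError("site must be 'I' or 'II'")
        if r.ndim != 1 or r.size < 2 or s.shape != r.shape:
            raise ValueError("ratios/signals must be 1-D, same length >= 2")
        if r[0] != 0:
            raise ValueError("molar ratio grid must start at 0 (competitor-free)")
        if not np.all(np.diff(r) > 0):
            raise ValueError("molar ratios must be strictly increasing")
        if self.baseline is not None:
            b = np.asarray(self.baseline, dtype=float)
            object.__setattr__(self, "baseline", b)
            if b.shape != r.shape:
                raise ValueError("baseline length mismatch")

    @property
    def relative_percent(self) -> np.ndarray:
        return relative_signal(self.corrected_signals)

    @property
    def corrected_signals(self) -> np.ndarray:
        if self.baseline is None:
            return self.signals
        return self.signals - self.baseline


def relative_signal(signals: Sequence[float]) -> np.ndarray:
    """Percent signal relative to the competitor-free (first) point.

    The sign of the raw signal is preserved: a negative induced CD band that
    halves in magnitude still reads 50%.
    """
    s = np.asarray(signals, dtype=float)
    if s.ndim != 1 or s.size < 1:
        raise ValueError("signals must be a non-empty 1-D sequence")
    if s[0] == 0:
        raise ValueError("signal at ratio 0 is zero; cannot normalize")
    return 100.0 * s / s[0]


def displacement_at_ratio(series: DisplacementSeries, ratio: float) -> float:
    """Percent loss of the marker signal at a competitor:protein ratio.

    Linear interpolation of the relative-signal curve; 100 − relative%.
    """
    r = series.molar_ratios
    if not (r[0] <= ratio <= r[-1]):
        raise ValueError(f"ratio {ratio} outside measured range [{r[0]}, {r[-1]}]")
    rel = float(np.interp(ratio, r, series.relative_percent))
    return 100.0 - rel


@dataclass(frozen=True)
class SiteAssignment:
    """Verdict plus the per-marker loss table backing it."""

    verdict: str                          # "site I" | "site II" | "both" | "indeterminate"
    losses: dict[str, tuple[str, float]]  # marker -> (site, max % loss)
    threshold: float
    at_ratio: float


def assign_site(siteI_series: Sequence[DisplacementSeries],
                siteII_series: Sequence[DisplacementSeries],
                displacement_threshold: float = 50.0,
                at_ratio: float | None = None) -> SiteAssignment:
    """Assign the competitor's binding site from marker displacement losses.

    A site is assigned when every one of its markers loses more than
    ``displacement_threshold`` percent of signal (at the common maximum ratio,
    or ``at_ratio``) while every marker of the other site stays below the
    threshold; "both" when both sites clear it, "indeterminate" otherwise.
    """
    if not siteI_series or not siteII_series:
        raise ValueError("need at least one marker series per site")
    every = list(siteI_series) + list(siteII_series)
    common_max = min(s.molar_ratios[-1] for s in every)
    ratio = at_ratio if at_ratio is not None else float(common_max)
    if ratio > common_max:
        raise ValueError(
            f"requested ratio {ratio} exceeds common maximum {common_max}")
    losses = {
        s.marker: (s.site, displacement_at_ratio(s, ratio)) for s in every
    }
    site1_all = all(loss > displacement_threshold
                    for _, (site, loss) in losses.items() if site == "I")
    site2_all = all(loss > displacement_threshold
                    for _, (site, loss) in losses.items() if site == "II")
    site1_none = all(loss <= displacement_threshold
                     for _, (site, loss) in losses.items() if site == "I")
    site2_none = all(loss <= displacement_threshold
                     for _, (site, loss) in losses.items() if site == "II")
    if site1_all and site2_all:
        verdict = "both"
    elif site1_all and site2_none:
        verdict = "site I"
    elif site2_all and site1_none:
        verdict = "site II"
    else:
        verdict = "indeterminate"
    return SiteAssignment(verdict=verdict, losses=losses,
                          threshold=displacement_threshold, at_ratio=ratio)
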