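"""Shared fixtures: exactly solvable synthetic inputs with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from ligandbind import GroundTruth, QuenchPoint, Spectrum, simulate_titration


@pytest.fixture
def exact_truth() -> GroundTruth:
    """Model-consistent generator: quench fraction equals occupancy, no band
    shift at the reference wavelength, no noise, no inner-filter attenuation.
    Under these conditions the double-log binding regression is exact."""
    return GroundTruth(
        K_a=1.03e5, P_T=3.0e-6, quench_depth=1.0,
        band_shift_at_saturation=0.0, eps_ex=0.0, eps_em=0.0,
        noise_sd=0.0, seed=7,
    )


@pytest.fixture
def paper_like_truth() -> GroundTruth:
    """Study-condition generator defaults: 3 uM protein, 0-22.5 uM ligand,
    72% maximal quench depth, 14 nm blue shift, inner-filter attenuation."""
    return GroundTruth(seed=11)


@pytest.fixture
def exact_series(exact_truth):
    return simulate_titration(exact_truth)


def sv_points(K_SV: float, F0: float = 1000.0,
              q_grid: np.ndarray | None = None) -> list[QuenchPoint]:
    """Quench points generated exactly from F = F0 / (1 + K_SV [Q])."""
    if q_grid is None:
        q_grid = np.arange(16) * 1.5e-6
    return [QuenchPoint(float(q), F0, F0 / (1.0 + K_SV * q)) for q in q_grid]


def gaussian_spectrum(center: float, sigma: float, amplitude: float,
                      grid: np.ndarray, kind: str = "emission",
                      **meta) -> Spectrum:
    vals = amplitude * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return Spectrum(grid, vals, kind=kind, meta=meta)
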