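"""Synchronous shifts, EEM peak picking, MRE conversion, melt analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligandbind import (MeltCurve, SpectraError, Spectrum, find_3d_peaks,
                        melt_analysis, mre_convert, peak_trajectory,
                        peak_wavelength, simulate_eem, simulate_melt,
                        synchronous_shift)

from conftest import gaussian_spectrum


GRID = np.arange(310.0, 370.5, 0.5)


class TestSynchronousShift:
    def test_identical_spectra_no_shift(self):
        spectra = [gaussian_spectrum(340, 10, 100, GRID, kind="synchronous",
                                     delta_lambda_nm=60) for _ in range(5)]
        peaks, shift = synchronous_shift(spectra, delta_lambda=60)
        assert shift == pytest.approx(0.0, abs=1e-9)

    def test_planted_blue_shift_recovered(self):
        # Gaussian translated -5 nm across the series (tryptophan channel)
        centers = np.linspace(340.0, 335.0, 6)
        spectra = [gaussian_spectrum(c, 10, 100, GRID, kind="synchronous",
                                     delta_lambda_nm=60) for c in centers]
        peaks, shift = synchronous_shift(spectra, delta_lambda=60)
        assert shift == pytest.approx(-5.0, abs=0.1)

    def test_fixed_center_tyrosine_channel_unaltered(self):
        # amplitude falls but the center stays: shift 0
        amps = np.linspace(100, 40, 6)
        spectra = [gaussian_spectrum(298, 8, a, np.arange(280.0, 320.5, 0.5),
                                     kind="synchronous", delta_lambda_nm=15)
                   for a in amps]
        peaks, shift = synchronous_shift(spectra, delta_lambda=15)
        assert shift == pytest.approx(0.0, abs=0.1)

    def test_parabolic_refinement_beats_grid_resolution(self):
        coarse = np.arange(310.0, 370.0, 2.0)  # 2 nm steps
        spec = gaussian_spectrum(336.7, 10, 100, coarse)
        assert peak_wavelength(spec) == pytest.approx(336.7, abs=0.1)

    def test_flat_spectrum_rejected(self):
        flat = Spectrum(GRID, np.ones_like(GRID))
        with pytest.raises(SpectraError, match="flat"):
            peak_wavelength(flat)

    def test_mixed_delta_lambda_tags_rejected(self):
        a = gaussian_spectrum(340, 10, 100, GRID, delta_lambda_nm=60)
        b = gaussian_spectrum(340, 10, 100, GRID, delta_lambda_nm=15)
        with pytest.raises(ValueError, match="mixed"):
            synchronous_shift([a, b])


class TestFind3DPeaks:
    def test_planted_peaks_recovered_ridge_labelled(self):
        surf = simulate_eem(seed=1)
        records = find_3d_peaks(surf, scatter_tol=5.0)
        genuine = [r for r in records if r.label in ("peak1", "peak2")]
        assert len(genuine) == 2
        top = {r.label: r for r in genuine}
        # native positions: 280/335 and 235/330, grids are 10 and 5 nm
        assert top["peak1"].excitation == pytest.approx(280, abs=10)
        assert top["peak1"].emission == pytest.approx(335, abs=5)
        assert top["peak2"].excitation == pytest.approx(235, abs=10)
        assert top["peak2"].emission == pytest.approx(330, abs=5)
        labels = {r.label for r in records}
        assert "rayleigh_a" in labels or "second_order_b" in labels

    def test_flat_surface_yields_no_peaks(self):
        from ligandbind import EEMSurface
        ex, em = np.arange(220, 351, 10.0), np.arange(220, 501, 5.0)
        surf = EEMSurface(ex, em, np.full((ex.size, em.size), 7.0))
        assert find_3d_peaks(surf) == []

    def test_single_off_diagonal_spike(self):
        from ligandbind import EEMSurface
        ex, em = np.arange(220, 351, 10.0), np.arange(220, 501, 5.0)
        z = np.zeros((ex.size, em.size))
        z[6, 23] = 100.0  # ex=280, em=335: off both scatter lines
        surf = EEMSurface(ex, em, z)
        records = find_3d_peaks(surf)
        assert len(records) == 1
        assert records[0].label == "peak1"

    def test_scatter_labels_mutually_exclusive(self):
        # a point cannot be both Rayleigh and second-order when ex > 2*tol
        surf = simulate_eem(seed=2)
        records = find_3d_peaks(surf, scatter_tol=5.0)
        for r in records:
            if r.excitation > 10.0:
                assert not (abs(r.emission - r.excitation) <= 5.0
                            and abs(r.emission - 2 * r.excitation) <= 5.0)


class TestPeakTrajectory:
    def test_planted_intensity_sequence_reproduced(self):
        intensities = [683.0, 581.0, 448.0, 390.0]
        surfaces = [
            simulate_eem(peaks=((280.0, 335.0 - i, a, 8.0, 12.0),
                                (235.0, 330.0 - i, a * 0.53, 8.0, 12.0)),
                         seed=3)
            for i, a in enumerate(intensities)
        ]
        traj = peak_trajectory(surfaces)
        series = traj[280.0]
        assert all(rec is not None for rec in series)
        got = [rec.intensity for rec in series]
        np.testing.assert_allclose(got, intensities, rtol=0.05)

    def test_identical_surfaces_constant_trajectory(self):
        surf = simulate_eem(seed=4)
        traj = peak_trajectory([surf, surf, surf])
        for series in traj.values():
            vals = [r.intensity for r in series]
            assert vals[0] == vals[1] == vals[2]

    def test_missing_peak_flagged_as_gap(self):
        with_peaks = simulate_eem(seed=5)
        without = simulate_eem(peaks=((280.0, 335.0, 683.0, 8.0, 12.0),),
                               seed=5)
        with pytest.warns(UserWarning, match="missing"):
            traj = peak_trajectory([with_peaks, without])
        gaps = [series[1] is None for series in traj.values()]
        assert any(gaps)


class TestMREConvert:
    def test_direct_evaluation(self):
        # -30 mdeg, 0.1 cm, 3 uM, 585 residues
        assert mre_convert(-30.0, 0.1, 3e-6, 585) == pytest.approx(
            -30.0 / (10 * 585 * 3e-6 * 0.1))
        assert mre_convert(-30.0, 0.1, 3e-6, 585) == pytest.approx(-17094, rel=1e-4)

    def test_zero_theta(self):
        assert mre_convert(0.0, 0.1, 3e-6) == 0.0

    @given(theta=st.floats(-100, 100), scale=st.floats(0.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_linearity_and_inverse_scalings(self, theta, scale):
        base = mre_convert(theta, 0.1, 3e-6, 585)
        assert mre_convert(scale * theta, 0.1, 3e-6, 585) == pytest.approx(
            scale * base, rel=1e-12, abs=1e-12)
        assert mre_convert(theta, scale * 0.1, 3e-6, 585) == pytest.approx(
            base / scale, rel=1e-12, abs=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            mre_convert(-30.0, 0.0, 3e-6)
        with pytest.raises(ValueError):
            mre_convert(-30.0, 0.1, -1e-6)


class TestMeltAnalysis:
    def test_full_reversibility_recovers_hundred_percent(self):
        fwd, rev = simulate_melt(reversibility=1.0, noise_sd=0.0, seed=0)
        res = melt_analysis(fwd, rev)
        assert res.recovery_percent == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("reversibility", [0.87, 0.55])
    def test_partial_recovery_and_onset_band(self, reversibility):
        fwd, rev = simulate_melt(reversibility=reversibility, seed=2)
        res = melt_analysis(fwd, rev)
        assert res.recovery_percent == pytest.approx(
            100.0 * reversibility, abs=1.0)
        assert res.onset_T is not None
        assert 45.0 <= res.onset_T <= 50.0

    def test_flat_curve_onset_undefined(self):
        t = np.arange(25.0, 80.5, 1.0)
        flat = MeltCurve(t, np.full_like(t, -16000.0), direction="forward")
        rev = MeltCurve(t[::-1], np.full_like(t, -16000.0), direction="reverse")
        with pytest.warns(UserWarning, match="no thermal transition"):
            res = melt_analysis(flat, rev)
        assert res.onset_T is None
        assert res.recovery_percent == pytest.approx(100.0)

    def test_recovery_scale_invariance(self):
        fwd, rev = simulate_melt(reversibility=0.87, seed=3)
        res1 = melt_analysis(fwd, rev)
        fwd2 = MeltCurve(fwd.temperatures, 3.7 * fwd.signal, "forward")
        rev2 = MeltCurve(rev.temperatures, 3.7 * rev.signal, "reverse")
        res2 = melt_analysis(fwd2, rev2)
        assert res2.recovery_percent == pytest.approx(
            res1.recovery_percent, rel=1e-12)

    def test_disjoint_scans_rejected(self):
        t1 = np.arange(25.0, 50.0, 1.0)
        t2 = np.arange(60.0, 80.0, 1.0)
        fwd = MeltCurve(t1, np.linspace(-16000, -15000, t1.size), "forward")
        rev = MeltCurve(t2[::-1], np.linspace(-9000, -8000, t2.size), "reverse")
        with pytest.raises(SpectraError, match="do not overlap"):
            melt_analysis(fwd, rev)
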