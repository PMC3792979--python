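"""Generator correctness: exact equilibria against independent oracles,
determinism, and end-to-end parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ligandbind import (GAS_CONSTANT, GroundTruth, competitive_equilibrium,
                        equilibrium_1to1, simulate_melt, simulate_multitemp,
                        simulate_titration, to_kelvin, vant_hoff_fit)
from ligandbind.pipeline import analyze_binding_series, analyze_quench_series


def bisect_equilibrium(P_T, D_T, K_a, tol=1e-18):
    """Independent oracle: bisection on the mass-balance residual
    K_a (P_T - x)(D_T - x) - x = 0 over x in [0, min(P_T, D_T)]."""
    lo, hi = 0.0, min(P_T, D_T)
    def resid(x):
        return K_a * (P_T - x) * (D_T - x) - x
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def grid_search_free_protein(P_T, M_T, C_T, K_M, K_C, levels=12, width=None):
    """Independent oracle: iteratively refined grid search over free protein
    of the three-species mass balance."""
    lo, hi = 0.0, P_T
    for _ in range(levels):
        grid = np.linspace(lo, hi, 201)
        resid = np.abs(grid * (1 + K_M * M_T / (1 + K_M * grid)
                               + K_C * C_T / (1 + K_C * grid)) - P_T)
        i = int(np.argmin(resid))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
    return grid[i]


class TestEquilibrium1to1:
    def test_zero_ligand_zero_complex(self):
        assert equilibrium_1to1(3e-6, 0.0, 1e5) == 0.0

    def test_infinite_affinity_limit(self):
        # K_a -> inf: bound -> min(P_T, D_T)
        assert equilibrium_1to1(3e-6, 10e-6, 1e18) == pytest.approx(
            3e-6, rel=1e-9)
        assert equilibrium_1to1(10e-6, 3e-6, 1e18) == pytest.approx(
            3e-6, rel=1e-9)

    @pytest.mark.parametrize("k_a", np.logspace(2, 12, 11))
    def test_agrees_with_bisection_oracle(self, k_a):
        p_t, d_t = 3e-6, 9e-6
        ours = equilibrium_1to1(p_t, d_t, float(k_a))
        oracle = bisect_equilibrium(p_t, d_t, float(k_a))
        assert ours == pytest.approx(oracle, abs=1e-12 * min(p_t, d_t) + 1e-18)

    @given(p=st.floats(1e-8, 1e-3), d=st.floats(0.0, 1e-3),
           logk=st.floats(2, 10))
    @settings(max_examples=100, deadline=None)
    def test_mass_balance_residual_property(self, p, d, logk):
        k = 10.0 ** logk
        x = equilibrium_1to1(p, d, k)
        resid = k * (p - x) * (d - x) - x
        assert abs(resid) <= 1e-10 * max(x, k * p * d, 1e-30)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_1to1(-1e-6, 1e-6, 1e5)


class TestCompetitiveEquilibrium:
    @pytest.mark.parametrize("k_c", [1e4, 1e5, 1e6, 1e7])
    def test_matches_grid_search_oracle(self, k_c):
        p_t, m_t, c_t, k_m = 1e-5, 1e-5, 4e-5, 1e6
        sol = competitive_equilibrium(p_t, m_t, c_t, k_m, k_c)
        oracle = grid_search_free_protein(p_t, m_t, c_t, k_m, k_c)
        assert sol["P_free"] == pytest.approx(oracle, rel=1e-6, abs=1e-13)
        # tight mass-balance check on the fixed-point solution itself
        resid = sol["P_free"] + sol["PM"] + sol["PC"] - p_t
        assert abs(resid) <= 1e-8 * p_t

    def test_species_conservation(self):
        sol = competitive_equilibrium(1e-5, 1e-5, 2e-5, 1e6, 5e5)
        assert sol["M_free"] + sol["PM"] == pytest.approx(1e-5, rel=1e-9)
        assert sol["C_free"] + sol["PC"] == pytest.approx(2e-5, rel=1e-9)

    def test_no_competitor_reduces_to_binary(self):
        sol = competitive_equilibrium(1e-5, 1e-5, 0.0, 1e6, 1e6)
        assert sol["PM"] == pytest.approx(
            equilibrium_1to1(1e-5, 1e-5, 1e6), rel=1e-9)


class TestDeterminism:
    def test_titration_bit_identical_for_fixed_seed(self):
        t1 = simulate_titration(GroundTruth(seed=123))
        t2 = simulate_titration(GroundTruth(seed=123))
        for a, b in zip(t1.spectra, t2.spectra):
            np.testing.assert_array_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        t1 = simulate_titration(GroundTruth(seed=1))
        t2 = simulate_titration(GroundTruth(seed=2))
        assert not np.array_equal(t1.spectra[1].values, t2.spectra[1].values)

    def test_melt_deterministic(self):
        f1, r1 = simulate_melt(seed=5)
        f2, r2 = simulate_melt(seed=5)
        np.testing.assert_array_equal(f1.signal, f2.signal)
        np.testing.assert_array_equal(r1.signal, r2.signal)


class TestGeneratorShapes:
    def test_zero_quench_depth_flat_intensity(self):
        truth = GroundTruth(quench_depth=0.0, band_shift_at_saturation=0.0,
                            eps_ex=0.0, eps_em=0.0, noise_sd=0.0)
        series = simulate_titration(truth)
        peaks = [s.values.max() for s in series.spectra]
        np.testing.assert_allclose(peaks, peaks[0], rtol=1e-12)

    def test_ka_decreases_with_temperature_for_negative_enthalpy(self):
        truth = GroundTruth(noise_sd=0.0)
        by_t = simulate_multitemp(truth, delta_H=-15.48, delta_S=44.06)
        # occupancy at a fixed ligand concentration falls with temperature
        mids = []
        for t in sorted(by_t):
            series = by_t[t]
            f0 = series.spectra[0].values.max()
            f = series.spectra[8].values.max()
            mids.append(f / f0)
        assert np.all(np.diff(mids) > 0)  # less quench = weaker binding

    def test_zero_enthalpy_identical_affinity(self):
        truth = GroundTruth(quench_depth=1.0, band_shift_at_saturation=0.0,
                            eps_ex=0.0, eps_em=0.0, noise_sd=0.0)
        by_t = simulate_multitemp(truth, delta_H=0.0, delta_S=44.06)
        quenches = [s.spectra[8].values.max() / s.spectra[0].values.max()
                    for s in by_t.values()]
        np.testing.assert_allclose(quenches, quenches[0], rtol=1e-9)


class TestEndToEndRoundTrips:
    def test_pipeline_recovers_ka_from_zero_noise_series(self, exact_series,
                                                         exact_truth):
        fit = analyze_binding_series(exact_series, correction="none")
        assert fit.K_a == pytest.approx(exact_truth.K_a, rel=0.01)

    def test_multitemp_recovers_vant_hoff_parameters(self):
        dh_true, ds_true = -15.48, 44.06
        truth = GroundTruth(quench_depth=1.0, band_shift_at_saturation=0.0,
                            eps_ex=0.0, eps_em=0.0, noise_sd=0.0)
        by_t = simulate_multitemp(truth, delta_H=dh_true, delta_S=ds_true)
        k_by_t = {}
        for t_c, series in by_t.items():
            fit = analyze_binding_series(series, correction="none")
            k_by_t[to_kelvin(t_c)] = fit.K_a
        thermo = vant_hoff_fit(k_by_t)
        assert thermo.delta_H == pytest.approx(dh_true, rel=0.02)
        assert thermo.delta_S == pytest.approx(ds_true, rel=0.02)

    def test_stern_volmer_on_simulated_series_with_inner_filter(self):
        # attenuated observations plus recorded pairs: K_SV close to the
        # initial-slope value K_a of the generating equilibrium
        truth = GroundTruth(K_a=8.6e4, quench_depth=1.0,
                            band_shift_at_saturation=0.0, noise_sd=0.0, seed=1)
        series = simulate_titration(truth)
        res = analyze_quench_series(series, correction="pair")
        # for full static quench of a 1:1 complex the initial S-V slope is
        # K_a (1 - theta corrections shrink it); retain loose agreement
        assert res.K_SV == pytest.approx(8.6e4, rel=0.25)
        assert res.K_SV > 0
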