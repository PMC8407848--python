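"""Measured transfer function and the per-frequency (n, kappa) grid scan."""

import numpy as np
import pytest

from thzhybrid import (
    PulseSpec,
    RetrievalGrid,
    Spectrum,
    SyntheticScene,
    bone_on_glass,
    measured_H,
    model_error,
    retrieve_nk,
    synthesize_waveforms,
    thickness_limit_study,
    transfer_function,
)

THZ2 = 2 * np.pi * 1e12
BAND = (0.3e12, 1.0e12)


@pytest.fixture(scope="module")
def aligned_pair(pulse, stack100):
    """Reference plane at the sample plane: H is the pure etalon response."""
    return synthesize_waveforms(SyntheticScene(stack100), pulse)


class TestMeasuredH:
    def test_sample_equal_reference_gives_unity(self, pulse, stack100):
        _, r = synthesize_waveforms(SyntheticScene(stack100), pulse)
        h = measured_H(r, r, BAND)
        np.testing.assert_allclose(h.value, 1.0, atol=1e-12)

    def test_matches_forward_model_within_windowing_error(self, aligned_pair, stack100):
        s, r = aligned_pair
        h = measured_H(s, r, BAND)
        expected = transfer_function(stack100, h.omega, 100e-6)
        np.testing.assert_allclose(h.value, expected, rtol=1e-3)

    def test_amplitude_scaling_is_linear_phase_unchanged(self, aligned_pair):
        s, r = aligned_pair
        h1 = measured_H(s, r, BAND)
        s2 = type(s)(s.time, 0.5 * s.amplitude)
        h2 = measured_H(s2, r, BAND)
        np.testing.assert_allclose(np.abs(h2.value), 0.5 * np.abs(h1.value), rtol=1e-12)
        np.testing.assert_allclose(np.angle(h2.value), np.angle(h1.value), atol=1e-12)

    def test_mismatched_time_grids_rejected(self, aligned_pair):
        s, r = aligned_pair
        shifted = type(r)(r.time + 1e-12, r.amplitude)
        with pytest.raises(ValueError, match="time grid"):
            measured_H(s, shifted, BAND)

    def test_vanishing_reference_rejected(self, aligned_pair):
        # a carrier-free envelope has no spectral support in the upper band
        s, r = aligned_pair
        t = r.time
        bump = type(r)(t, np.exp(-((t - 15e-12) ** 2) / (2 * (2e-12) ** 2)))
        with pytest.raises(ValueError, match="reference magnitude"):
            measured_H(s, bump, BAND, window="rect")

    def test_corrected_phase_substitution(self, aligned_pair):
        s, r = aligned_pair
        h = measured_H(s, r, BAND)
        target = np.linspace(0.0, 1.0, h.omega.size)
        h2 = measured_H(s, r, BAND, corrected_phase=target)
        np.testing.assert_allclose(np.angle(h2.value), np.angle(np.exp(1j * target)))
        np.testing.assert_allclose(np.abs(h2.value), np.abs(h.value))


class TestModelError:
    def test_generating_values_have_vanishing_error(self, stack100):
        omega = np.linspace(0.3, 1.0, 20) * THZ2
        h = transfer_function(stack100, omega, 100e-6)
        for i in (0, 9, 19):
            assert model_error(h[i], 1.8, 0.08, omega[i], stack100, 100e-6) < 1e-6

    def test_error_is_nonnegative_and_zero_only_at_match(self, stack100):
        omega = 0.5 * THZ2
        h = transfer_function(stack100, np.array([omega]), 100e-6)[0]
        assert model_error(h, 2.0, 0.2, omega, stack100, 100e-6) > 0
        assert model_error(h, 1.8, 0.08, omega, stack100, 100e-6) == pytest.approx(0, abs=1e-12)

    def test_weight_swap_symmetry(self, stack100):
        # equal amplitude and phase mismatch: swapping the weights is a no-op
        omega = 0.5 * THZ2
        h_m = 0.5 * np.exp(0.3j)
        h_g = model_error(h_m, 1.8, 0.08, omega, stack100, 100e-6, 1.0, 2.0)
        # symmetric construction: compare weights on a synthetic pair with
        # |d_amp| == |d_phase|
        d = 0.1
        e12 = np.sqrt(1.0 * d**2 + 2.0 * d**2)
        e21 = np.sqrt(2.0 * d**2 + 1.0 * d**2)
        assert e12 == e21
        assert h_g >= 0


class TestRetrieveNK:
    def test_round_trip_recovers_generating_values_everywhere(self, aligned_pair, stack100):
        s, r = aligned_pair
        h = measured_H(s, r, BAND)
        res = retrieve_nk(h, stack100, 100e-6)
        assert np.max(np.abs(res.n - 1.8)) < 0.02
        assert np.max(np.abs(res.kappa - 0.08)) < 0.01

    @pytest.mark.filterwarnings("ignore:.*grid boundary.*")
    def test_air_gap_recovered_as_unity_index(self, pulse):
        # kappa = 0 sits on the physical edge of the grid, so the boundary
        # flag fires by construction; the recovery itself is the check
        stack = bone_on_glass(50e-6, n_bone=1.0 + 1e-12, kappa_bone=0.0)
        s, r = synthesize_waveforms(SyntheticScene(stack), pulse)
        h = measured_H(s, r, BAND)
        grid = RetrievalGrid(n_values=np.arange(0.9, 1.5, 0.01),
                             kappa_values=np.arange(0.0, 0.2, 0.005))
        res = retrieve_nk(h, stack, 50e-6, grid)
        assert np.max(np.abs(res.n - 1.0)) <= 0.01 / 25 + 1e-9
        assert np.max(res.kappa) <= 0.005 / 25 + 1e-9

    def test_submicron_layer_same_tolerances(self, pulse):
        stack = bone_on_glass(0.1e-6)
        s, r = synthesize_waveforms(SyntheticScene(stack), pulse)
        h = measured_H(s, r, BAND)
        res = retrieve_nk(h, stack, 0.1e-6)
        assert np.max(np.abs(res.n - 1.8)) < 0.02
        assert np.max(np.abs(res.kappa - 0.08)) < 0.01

    def test_scan_stage_equals_brute_force_argmin(self, aligned_pair, stack100):
        s, r = aligned_pair
        h = measured_H(s, r, BAND)
        grid = RetrievalGrid(n_values=np.linspace(1.6, 2.0, 5),
                             kappa_values=np.linspace(0.0, 0.2, 5),
                             refine_levels=0)
        res = retrieve_nk(h, stack100, 100e-6, grid, tie_tol=0.0)
        for i in range(0, h.omega.size, 7):
            errs = np.array([
                [model_error(h.value[i], n, k, h.omega[i], stack100, 100e-6)
                 for k in grid.kappa_values]
                for n in grid.n_values
            ])
            jn, jk = np.unravel_index(np.argmin(errs), errs.shape)
            assert res.n[i] == grid.n_values[jn]
            assert res.kappa[i] == grid.kappa_values[jk]

    def test_denser_grid_never_worsens_residual(self, aligned_pair, stack100):
        s, r = aligned_pair
        h = measured_H(s, r, BAND)
        h = Spectrum(h.omega[::8], h.value[::8])
        coarse = RetrievalGrid(n_values=np.arange(1.0, 4.0, 0.02),
                               kappa_values=np.arange(0.0, 1.0, 0.01))
        dense = RetrievalGrid(n_values=np.arange(1.0, 4.0, 0.01),
                              kappa_values=np.arange(0.0, 1.0, 0.005))
        r1 = retrieve_nk(h, stack100, 100e-6, coarse)
        r2 = retrieve_nk(h, stack100, 100e-6, dense)
        assert np.all(r2.residual <= r1.residual + 1e-12)

    def test_no_oscillating_artefacts(self, aligned_pair, stack100):
        # retrieved curves must be free of the etalon ripple: no
        # inter-frequency jump beyond 10x the final grid resolution
        s, r = aligned_pair
        h = measured_H(s, r, BAND)
        res = retrieve_nk(h, stack100, 100e-6)
        final_dn = 0.01 / 5**2
        final_dk = 0.005 / 5**2
        assert np.max(np.abs(np.diff(res.n))) <= 10 * final_dn
        assert np.max(np.abs(np.diff(res.kappa))) <= 10 * final_dk

    def test_boundary_minimum_flagged(self, aligned_pair, stack100):
        s, r = aligned_pair
        h = measured_H(s, r, BAND)
        grid = RetrievalGrid(n_values=np.linspace(2.5, 4.0, 16),
                             kappa_values=np.linspace(0.3, 1.0, 8),
                             refine_levels=0)
        with pytest.warns(UserWarning, match="boundary"):
            res = retrieve_nk(h, stack100, 100e-6, grid)
        assert res.boundary_flag.any()

    def test_nonpositive_thickness_rejected(self, aligned_pair, stack100):
        s, r = aligned_pair
        h = measured_H(s, r, BAND)
        with pytest.raises(ValueError, match="thickness"):
            retrieve_nk(h, stack100, 0.0)


class TestThicknessLimit:
    def test_infinite_tolerance_passes_trivially(self, pulse):
        res = thickness_limit_study(bone_on_glass, pulse,
                                    np.array([10e-6, 1e-6]), tolerance=np.inf)
        assert res.smallest_passing == pytest.approx(1e-6)

    def test_recovery_down_to_tenth_micron(self, pulse):
        res = thickness_limit_study(bone_on_glass, pulse,
                                    np.array([100e-6, 1e-6, 0.1e-6]), tolerance=0.05)
        assert res.passed.all()
        assert res.smallest_passing <= 0.1e-6

    def test_noise_only_shrinks_the_passing_set(self, pulse):
        grid = np.array([100e-6, 10e-6, 1e-6])
        clean = thickness_limit_study(bone_on_glass, pulse, grid, tolerance=0.05)
        noisy = thickness_limit_study(bone_on_glass, pulse, grid, tolerance=0.05,
                                      noise_rms=2e-3, seed=7)
        assert np.all(clean.passed | ~noisy.passed)

    def test_increasing_grid_rejected(self, pulse):
        with pytest.raises(ValueError, match="decreasing"):
            thickness_limit_study(bone_on_glass, pulse, np.array([1e-6, 10e-6]))
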