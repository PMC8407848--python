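"""Singly-subtractive Kramers-Kronig transforms and plane-offset retrieval."""

import warnings

import numpy as np
import pytest

from thzhybrid import (
    KKSettings,
    Spectrum,
    SyntheticScene,
    bone_on_glass,
    consistency_error,
    offset_to_thickness,
    pv_integral,
    retrieve_phase_offset,
    synthesize_waveforms,
)
from thzhybrid.core import C_LIGHT, PhaseOffsetResult
from thzhybrid.kk import SSKKOperator, _single_pole_pv
from thzhybrid.pipeline import analysis_transfer_function

THZ2 = 2 * np.pi * 1e12
BAND = (0.3e12, 1.0e12)
ANALYSIS = (0.1e12, 1.6e12)


def _pure_delay_spectrum(delta_L, f_lo=0.1, f_hi=1.6, n=181):
    """Transfer function of a bare reference displaced by delta_L: unit
    amplitude, pure ramp phase (the cleanest offset fixture)."""
    omega = np.linspace(f_lo, f_hi, n) * THZ2
    h = np.exp(1j * 2 * omega * delta_L / C_LIGHT)
    return Spectrum(omega, h, band=(0.3 * THZ2, 1.0 * THZ2))


class TestPVIntegral:
    def test_constant_integrand_cancels_on_wide_grid(self):
        grid = np.linspace(0.0, 40.0, 12001) * THZ2
        val = pv_integral(grid, np.full(grid.size, 3.0), 0.6 * THZ2, 0.9 * THZ2)
        assert abs(val) < 1e-3 * 3.0

    def test_singular_factor_cancellation(self):
        # f = (w'^2 - w^2) g(w') has a removable pole at w: the PV integral
        # must equal the ordinary integral of g / (w'^2 - w1^2)
        grid = np.linspace(0.05, 10.0, 4001) * THZ2
        w, w1 = 3.0 * THZ2, 7.0 * THZ2
        g = np.exp(-((grid - 2 * THZ2) / THZ2) ** 2)
        f = (grid**2 - w**2) * g
        val = pv_integral(grid, f, w, w1)
        # direct quadrature of g/(w'^2 - w1^2) with its own pole at w1
        expected = _single_pole_pv(grid, g, w1)
        assert val == pytest.approx(expected, rel=1e-6)

    def test_lorentzian_matches_brute_force_quadrature(self):
        mu, sig = 1.1 * THZ2, 0.4 * THZ2
        f = lambda x: 1.0 / (1.0 + ((x - mu) / sig) ** 2)
        grid = np.linspace(0.01, 20.0, 8001) * THZ2
        w, w1 = 0.8 * THZ2, 1.6 * THZ2
        val = pv_integral(grid, f(grid), w, w1)
        # brute force: 10x finer grid, symmetric exclusion around each pole
        fine = np.linspace(0.01, 20.0, 80001) * THZ2
        h = fine[1] - fine[0]
        keep = (np.abs(fine - w) > 3.5 * h) & (np.abs(fine - w1) > 3.5 * h)
        integrand = f(fine[keep]) / ((fine[keep] ** 2 - w**2) * (fine[keep] ** 2 - w1**2))
        brute = np.trapezoid(integrand, fine[keep])
        assert val == pytest.approx(brute, rel=1e-4)

    def test_rejects_poles_outside_grid(self):
        grid = np.linspace(0.3, 1.0, 101) * THZ2
        with pytest.raises(ValueError, match="outside"):
            pv_integral(grid, np.ones(101), 2.0 * THZ2, 0.5 * THZ2)


class TestSSKKTransforms:
    def test_flat_amplitude_gives_zero_phase(self):
        omega = np.linspace(0.3, 1.0, 85) * THZ2
        op = SSKKOperator(omega)
        theta = op.phase_from_lnamp(np.full(85, np.log(0.4)), theta_anchor=0.0)
        assert np.max(np.abs(theta)) < 1e-3

    def test_zero_phase_gives_constant_lnamp(self):
        omega = np.linspace(0.3, 1.0, 85) * THZ2
        op = SSKKOperator(omega)
        ln = op.lnamp_from_phase(np.zeros(85), lnamp_anchor=-0.5)
        np.testing.assert_allclose(ln, -0.5, atol=1e-12)

    def test_lorentz_oscillator_phase_recovered(self, lorentz_band):
        omega, r = lorentz_band
        op = SSKKOperator(omega)
        theta_true = np.unwrap(np.angle(r))
        theta_kk = op.phase_from_lnamp(np.log(np.abs(r)), theta_true[op.i1])
        central = slice(omega.size // 4, 3 * omega.size // 4)
        assert np.max(np.abs(theta_kk - theta_true)[central]) < 0.05

    def test_lorentz_oscillator_lnamp_recovered(self, lorentz_band):
        omega, r = lorentz_band
        op = SSKKOperator(omega)
        ln_true = np.log(np.abs(r))
        ln_kk = op.lnamp_from_phase(np.unwrap(np.angle(r)), ln_true[op.i1])
        central = slice(omega.size // 4, 3 * omega.size // 4)
        assert np.max(np.abs(ln_kk - ln_true)[central]) < 0.05

    def test_anchor_choice_barely_moves_the_phase(self, lorentz_band):
        omega, r = lorentz_band
        lnamp = np.log(np.abs(r))
        theta_true = np.unwrap(np.angle(r))
        central = slice(omega.size // 4, 3 * omega.size // 4)
        outputs = []
        for f1 in (0.8, 1.5, 2.2):
            op = SSKKOperator(omega, KKSettings(omega1=f1 * THZ2))
            outputs.append(op.phase_from_lnamp(lnamp, theta_true[op.i1])[central])
        assert np.max(np.abs(outputs[0] - outputs[1])) < 0.02
        assert np.max(np.abs(outputs[0] - outputs[2])) < 0.02

    def test_round_trip_on_self_consistent_data(self, lorentz_band):
        omega, r = lorentz_band
        op = SSKKOperator(omega)
        theta_kk = op.phase_from_lnamp(np.log(np.abs(r)), np.unwrap(np.angle(r))[op.i1])
        ln_back = op.lnamp_from_phase(theta_kk, np.log(np.abs(r))[op.i1])
        central = slice(omega.size // 4, 3 * omega.size // 4)
        assert np.max(np.abs(ln_back - np.log(np.abs(r)))[central]) < 0.1

    def test_edge_anchor_warns(self):
        omega = np.linspace(0.3, 1.0, 85) * THZ2
        with pytest.warns(UserWarning, match="band edge"):
            SSKKOperator(omega, KKSettings(omega1=0.3 * THZ2))


class TestConsistencyError:
    def test_causal_pair_scores_low(self, lorentz_band):
        omega, r = lorentz_band
        e = consistency_error(omega, np.log(np.abs(r)), np.unwrap(np.angle(r)))
        assert e < 0.05

    def test_ramp_corruption_scores_higher(self, lorentz_band):
        omega, r = lorentz_band
        lnamp = np.log(np.abs(r))
        theta = np.unwrap(np.angle(r))
        e0 = consistency_error(omega, lnamp, theta)
        e1 = consistency_error(omega, lnamp, theta + omega * 2 * 200e-6 / C_LIGHT)
        assert e1 > e0

    def test_degenerate_band_rejected(self):
        omega = np.linspace(0.3, 0.31, 3) * THZ2
        with pytest.raises(ValueError, match="degenerate|at least"):
            consistency_error(omega, np.zeros(3), np.zeros(3))


class TestRetrievePhaseOffset:
    def test_zero_offset_recovered_exactly(self):
        res = retrieve_phase_offset(_pure_delay_spectrum(0.0))
        step = 2e-3 / 255  # coarsest candidate spacing
        assert abs(res.delta_L) <= step

    def test_pure_delay_offset_recovered(self):
        res = retrieve_phase_offset(_pure_delay_spectrum(200e-6))
        assert res.delta_L == pytest.approx(200e-6, abs=0.1e-6)

    def test_thick_sample_offset_recovered_within_two_microns(self, thick_pair):
        s, r = thick_pair
        h = analysis_transfer_function(s, r, BAND, ANALYSIS)
        res = retrieve_phase_offset(h)
        assert res.delta_L == pytest.approx(200e-6, abs=2e-6)

    def test_converges_within_ten_iterations(self, thick_pair):
        s, r = thick_pair
        h = analysis_transfer_function(s, r, BAND, ANALYSIS)
        res = retrieve_phase_offset(h)
        assert res.converged and res.iterations <= 10

    def test_history_is_non_increasing(self, thick_pair):
        s, r = thick_pair
        h = analysis_transfer_function(s, r, BAND, ANALYSIS)
        res = retrieve_phase_offset(h)
        hist = np.asarray(res.consistency_history)
        assert np.all(np.diff(hist) <= 1e-15)

    def test_true_offset_is_the_global_minimum_of_the_scan(self, thick_pair):
        s, r = thick_pair
        h = analysis_transfer_function(s, r, BAND, ANALYSIS)
        settings = KKSettings()
        op = SSKKOperator(h.omega, settings, band=h.band)
        lnamp = np.log(np.abs(h.value))
        theta = np.unwrap(np.angle(h.value))
        cands = np.linspace(-1e-3, 1e-3, 256)
        ramps = 2 * h.omega[None, :] / C_LIGHT * cands[:, None]
        scores = op.consistency_errors(lnamp, theta[None, :] - ramps)
        best = cands[np.argmin(scores)]
        assert abs(best - 200e-6) <= (cands[1] - cands[0])

    def test_recovery_is_anchor_independent(self, thick_pair):
        s, r = thick_pair
        h = analysis_transfer_function(s, r, BAND, ANALYSIS)
        recovered = [
            retrieve_phase_offset(h, KKSettings(omega1=f1 * THZ2)).delta_L
            for f1 in (0.4, 0.65, 0.9)
        ]
        assert np.ptp(recovered) < 2e-6

    def test_offset_outside_candidate_range_warns(self):
        spec = _pure_delay_spectrum(1.5e-3)
        with pytest.warns(UserWarning, match="too narrow"):
            res = retrieve_phase_offset(spec, KKSettings(max_iterations=2))
        assert res.boundary_warning

    def test_non_convergence_is_flagged_not_raised(self, thick_pair):
        s, r = thick_pair
        h = analysis_transfer_function(s, r, BAND, ANALYSIS)
        res = retrieve_phase_offset(h, KKSettings(max_iterations=1))
        assert not res.converged


class TestOffsetToThickness:
    @staticmethod
    def _result(dl):
        omega = np.linspace(0.3, 1.0, 10) * THZ2
        return PhaseOffsetResult(
            delta_L=dl, omega=omega, delta_theta=np.zeros(10),
            corrected_phase=np.zeros(10), iterations=1, consistency_history=[0.0],
        )

    def test_offset_maps_identically_to_thickness(self):
        assert offset_to_thickness(self._result(100e-6)) == pytest.approx(100e-6)

    def test_zero_offset_flags_no_sample_layer(self):
        with pytest.warns(UserWarning, match="no sample layer"):
            assert offset_to_thickness(self._result(0.0)) == 0.0

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            offset_to_thickness(self._result(-5e-6))

    def test_round_trip_thickness_on_standard_stack(self, pair100):
        s, r = pair100
        h = analysis_transfer_function(s, r, BAND, ANALYSIS)
        res = retrieve_phase_offset(h)
        assert offset_to_thickness(res) == pytest.approx(100e-6, abs=2e-6)
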