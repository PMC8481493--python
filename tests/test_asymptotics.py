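"""Pole/zero ladder, closed-form peak expressions and the Bode skeleton."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytoeis import (
    CircuitParameters,
    FrequencyGrid,
    ValidationError,
    asymptotic_bode,
    corner_frequencies,
    evaluate_impedance,
    min_phase,
    omega4,
    omega6,
    peak_frequency,
    phi4,
    phi6,
    skeleton_magnitude_db,
    z5_magnitude,
)
from phytoeis.asymptotics import _bilinear_min_phase_deg

from conftest import dense_log_omega


class TestCornerFrequencies:
    def test_first_pole_matches_direct_arithmetic(self):
        """w12 = 1/(C_dl (R_s+R_ct+R_1)) for R_s=1, R_ct=100, R_1=10, C_dl=1e-3."""
        params = CircuitParameters(R_s=1.0, R_ct=100.0, C_dl=1e-3, R_1=10.0, C_1=1e-9)
        ladder = corner_frequencies(params, warn=False)
        assert ladder.omega_12 == pytest.approx(1.0 / (1e-3 * 111.0), rel=1e-12)
        assert ladder.omega_12 == pytest.approx(9.009, rel=1e-3)

    def test_plateaus_are_the_resistive_levels(self, reference_params):
        ladder = corner_frequencies(reference_params)
        p = reference_params
        r_par = p.R_1 * p.R / (p.R_1 + p.R)
        assert ladder.plateau_1 == pytest.approx(p.R_s + p.R_ct + p.R_1)
        assert ladder.plateau_3 == pytest.approx(p.R_s + p.R_1)
        assert ladder.plateau_5 == pytest.approx(p.R_s + r_par)
        assert ladder.plateau_7 == pytest.approx(p.R_s)
        assert np.all(np.diff(ladder.corners()) > 0)

    def test_scale_covariance_of_ladder(self, reference_params):
        """Scaling R by 7 and C by 1/7 fixes every corner, scales plateaus by 7."""
        ladder = corner_frequencies(reference_params)
        scaled = corner_frequencies(reference_params.scaled(7.0))
        np.testing.assert_allclose(scaled.corners(), ladder.corners(), rtol=1e-12)
        for name in ("plateau_1", "plateau_3", "plateau_5", "plateau_7"):
            assert getattr(scaled, name) == pytest.approx(7.0 * getattr(ladder, name))

    def test_corners_match_numeric_3db_crossings(self, extreme_separation_params):
        """With >=3-decade separations each corner sits within a factor 1.05 of
        the frequency where the exact |Z| is 3 dB off the adjacent plateau."""
        params = extreme_separation_params
        ladder = corner_frequencies(params)
        w = dense_log_omega(ladder.omega_12 / 1e3, ladder.omega_67 * 1e3, per_decade=400)
        mag = evaluate_impedance(params, FrequencyGrid(w / (2 * np.pi))).magnitude
        # |Z| is strictly decreasing, so each level crosses exactly once
        log_mag, log_w = np.log10(mag)[::-1], np.log10(w)[::-1]
        sqrt2 = math.sqrt(2.0)
        targets = {
            "omega_12": ladder.plateau_1 / sqrt2,
            "omega_23": ladder.plateau_3 * sqrt2,
            "omega_34": ladder.plateau_3 / sqrt2,
            "omega_45": ladder.plateau_5 * sqrt2,
            "omega_56": ladder.plateau_5 / sqrt2,
            "omega_67": ladder.plateau_7 * sqrt2,
        }
        for name, level in targets.items():
            w_cross = 10.0 ** np.interp(math.log10(level), log_mag, log_w)
            ratio = w_cross / getattr(ladder, name)
            assert 1 / 1.05 < ratio < 1.05, f"{name}: 3 dB crossing off by {ratio:.3f}x"

    def test_medium_only_ladder_marks_cell_entries_undefined(self):
        params = CircuitParameters(R_s=2.0, R_ct=5e3, C_dl=2e-6, R_1=80.0, C_1=5e-12)
        ladder = corner_frequencies(params, warn=False)
        assert ladder.omega_34 is None and ladder.omega_45 is None
        assert ladder.plateau_5 is None
        assert ladder.omega_56 == pytest.approx(1.0 / (5e-12 * 82.0))

    def test_cpe_exponent_rejected(self, reference_params):
        params = CircuitParameters(
            R_s=10, R_ct=2e4, C_dl=5e-6, R_1=500, C_1=2e-12, R=1000.0, C=2e-9, alpha_dl=0.9
        )
        with pytest.raises(ValidationError, match="alpha"):
            corner_frequencies(params)

    def test_crowded_dispersions_flagged(self):
        """Dispersions closer than ~2.5 decades clear the well-separated flag."""
        params = CircuitParameters(
            R_s=10, R_ct=2e4, C_dl=5e-6, R_1=500, C_1=2e-12, R=1000.0, C=2e-7
        )
        with pytest.warns(UserWarning, match="decades"):
            ladder = corner_frequencies(params)
        assert not ladder.well_separated


class TestBilinearPhase:
    def test_degenerate_dispersion_has_zero_phase(self):
        assert min_phase(5.0, 5.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_ratio_peak_depth(self):
        """arctan(sqrt(0.5)) - arctan(sqrt(2)) = -19.47 deg."""
        assert min_phase(1.0, 2.0) == pytest.approx(-19.47122063, abs=1e-6)

    def test_extreme_ratio_approaches_quarter_turn(self):
        assert min_phase(1e-12, 1.0) == pytest.approx(-90.0, abs=1e-3)

    def test_pole_above_zero_is_a_contract_violation(self):
        with pytest.raises(ValidationError):
            min_phase(2.0, 1.0)

    def test_magnitude_symmetric_under_argument_swap(self):
        assert _bilinear_min_phase_deg(3.0, 70.0) == pytest.approx(
            -_bilinear_min_phase_deg(70.0, 3.0)
        )

    def test_peak_frequency_is_geometric_mean(self):
        assert peak_frequency(1.0, 1.0) == pytest.approx(1.0)
        assert peak_frequency(10.0, 1000.0) == pytest.approx(100.0)

    def test_peak_location_and_depth_match_brute_force(self):
        """Grid argmin of the bilinear phase lands on sqrt(wp*wz) at min_phase."""
        wp, wz = 100.0, 4.0e4
        w = dense_log_omega(wp / 1e3, wz * 1e3, per_decade=2000)
        h = (1 + 1j * w / wz) / (1 + 1j * w / wp)
        i = np.argmin(np.angle(h))
        assert w[i] == pytest.approx(peak_frequency(wp, wz), rel=1e-3)
        assert math.degrees(np.angle(h[i])) == pytest.approx(min_phase(wp, wz), abs=1e-4)


class TestClosedFormPeaks:
    def test_phi4_bounds(self):
        """phi4 = -19.47 deg at k = 1 (the ~-20 deg bound for R >= R_1),
        -> -90 deg as k -> 0 and -> 0 as k -> infinity."""
        assert phi4(1.0) == pytest.approx(-19.47122063, abs=1e-6)
        assert phi4(1e-9) == pytest.approx(-90.0, abs=0.01)
        assert phi4(1e12) == pytest.approx(0.0, abs=1e-4)

    def test_phi6_bounds(self):
        """phi6 = -74.06 deg at k = 1, p = 0.01; limits 0 and -90 in p."""
        assert phi6(1.0, 0.01) == pytest.approx(-74.05763139, abs=1e-6)
        assert phi6(1.0, 1e12) == pytest.approx(0.0, abs=1e-4)
        assert phi6(1.0, 1e-12) == pytest.approx(-90.0, abs=0.01)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(k=st.floats(1e-6, 1e6), factor=st.floats(1.01, 10.0))
    def test_phi4_strictly_increasing_in_k(self, k, factor):
        assert phi4(k * factor) > phi4(k)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(k=st.floats(1e-3, 1e3), p=st.floats(1e-6, 1e3), factor=st.floats(1.01, 10.0))
    def test_phi6_strictly_increasing_in_p(self, k, p, factor):
        assert phi6(k, p * factor) > phi6(k, p)

    def test_omega4_example_and_ladder_identity(self):
        """omega4(C=1,R1=1,k=1) = 1/sqrt(2); equals the geometric mean of the
        region-4 pole 1/(C(R+R1)) and zero 1/(CR) across a k grid."""
        assert omega4(1.0, 1.0, 1.0) == pytest.approx(1.0 / math.sqrt(2.0), rel=1e-12)
        c, r_1 = 3e-9, 120.0
        for k in np.logspace(-2, 2, 9):
            r = k * r_1
            expected = peak_frequency(1.0 / (c * (r + r_1)), 1.0 / (c * r))
            assert omega4(c, r_1, k) == pytest.approx(expected, rel=1e-12)

    def test_omega6_example_and_ladder_identity(self):
        """omega6(C1=1,R1=1,k=1,p=0.01) = 14.00; equals the geometric mean of
        1/(C1(Rs+R1||R)) and 1/(C1 Rs)."""
        assert omega6(1.0, 1.0, 1.0, 0.01) == pytest.approx(14.00280084, rel=1e-8)
        c_1, r_1 = 4e-12, 250.0
        for k, p in [(0.5, 0.004), (2.0, 0.02), (8.0, 0.1)]:
            r_s, r = p * r_1, k * r_1
            r_par = r_1 * r / (r_1 + r)
            expected = peak_frequency(1.0 / (c_1 * (r_s + r_par)), 1.0 / (c_1 * r_s))
            assert omega6(c_1, r_1, k, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("p_ratio", [0.02, 0.15, 0.5])
    def test_exact_dispersion_pairs_track_numeric_peaks_at_any_p(self, p_ratio):
        """The exact region-4/6 pole-zero pairs locate the numeric peaks even
        when R_s is an appreciable fraction of R_1, where the published
        small-p peak formulas drift."""
        from phytoeis import region4_pole_zero, region6_pole_zero

        r_1 = 300.0
        params = CircuitParameters(
            R_s=p_ratio * r_1, R_ct=3e4, C_dl=5e-6, R_1=r_1, C_1=1e-12,
            R=2.0 * r_1, C=1e-9,
        )
        spectrum = evaluate_impedance(
            params, FrequencyGrid.log_spaced(1e-2, 1e13, 60)
        )
        from phytoeis import find_phase_peaks

        peaks = find_phase_peaks(spectrum)
        for pair in (region4_pole_zero(params), region6_pole_zero(params)):
            f_exact = peak_frequency(*pair) / (2 * math.pi)
            depth_exact = min_phase(*pair)
            peak = min(peaks, key=lambda pk: abs(math.log10(pk.f_peak / f_exact)))
            assert peak.f_peak == pytest.approx(f_exact, rel=0.05)
            assert peak.phi_min == pytest.approx(depth_exact, abs=0.5)

    def test_omega6_matches_numeric_region6_minimum(self, reference_params):
        """Analytic region-6 peak frequency within 10% of the exact circuit's."""
        p = reference_params
        k, pr = p.R / p.R_1, p.R_s / p.R_1
        w6 = omega6(p.C_1, p.R_1, k, pr)
        w = dense_log_omega(w6 / 1e3, w6 * 1e3, per_decade=500)
        spectrum = evaluate_impedance(p, FrequencyGrid(w / (2 * np.pi)))
        w_min = w[np.argmin(spectrum.phase_deg)]
        assert w_min == pytest.approx(w6, rel=0.10)

    def test_z5_magnitude_example_and_monotonicity(self):
        assert z5_magnitude(100.0, 1.0, 0.01) == pytest.approx(51.0, rel=1e-12)
        assert z5_magnitude(100.0, 1e9, 1e-9) == pytest.approx(100.0, rel=1e-6)
        assert z5_magnitude(100.0, 2.0, 0.01) > z5_magnitude(100.0, 1.0, 0.01)
        assert z5_magnitude(100.0, 1.0, 0.02) > z5_magnitude(100.0, 1.0, 0.01)

    @pytest.mark.parametrize("scale_c", [1e-3, 1.0, 1e3])
    def test_peak_depths_independent_of_capacitances(self, scale_c):
        """Numerically detected phi4/phi6 depths are unmoved while C and C_1
        sweep 6 orders of magnitude (only the peak frequencies shift)."""
        from phytoeis import find_phase_peaks, metrics_from_params

        params = CircuitParameters(
            R_s=10.0, R_ct=2e4, C_dl=5e-6, R_1=500.0,
            C_1=2e-12 * scale_c, R=1000.0, C=2e-9 * scale_c,
        )
        m = metrics_from_params(params)
        assert m.phi4 == pytest.approx(phi4(2.0), abs=1e-12)
        assert m.phi6 == pytest.approx(phi6(2.0, 0.02), abs=1e-12)
        ladder = corner_frequencies(params, warn=False)
        if ladder.well_separated:
            grid = FrequencyGrid.log_spaced(4e-3 / scale_c, 2e13, 25)
            peaks = find_phase_peaks(evaluate_impedance(params, grid))
            nearest_f6 = min(peaks, key=lambda pk: abs(math.log10(pk.f_peak / m.f6)))
            assert nearest_f6.phi_min == pytest.approx(m.phi6, abs=1.5)


class TestAsymptoticBode:
    def test_seven_segments_with_alternating_slopes(self, reference_params):
        segments = asymptotic_bode(reference_params)
        assert [s.region for s in segments] == [1, 2, 3, 4, 5, 6, 7]
        assert [s.slope_db_per_decade for s in segments] == [0, -20, 0, -20, 0, -20, 0]
        ladder = corner_frequencies(reference_params)
        assert segments[0].mag_db_start == pytest.approx(20 * math.log10(ladder.plateau_1))
        # breakpoints are the ladder corners
        two_pi = 2 * math.pi
        np.testing.assert_allclose(
            [s.f_stop_hz for s in segments[:-1]],
            np.array(ladder.corners()) / two_pi,
            rtol=1e-12,
        )

    def test_region2_slope_rejoins_the_next_plateau_exactly(self, reference_params):
        """The -20 dB/dec region-2 (and region-6) drop lands exactly on the
        following plateau: the corner ratio equals the plateau ratio."""
        segments = {s.region: s for s in asymptotic_bode(reference_params)}
        assert segments[2].mag_db_stop == pytest.approx(segments[3].mag_db_start, abs=1e-9)
        assert segments[6].mag_db_stop == pytest.approx(segments[7].mag_db_start, abs=1e-9)

    def test_skeleton_tracks_exact_magnitude(self, extreme_separation_params):
        """Skeleton vs exact 20 log10|Z|: within 3.1 dB at corners, 0.5 dB at
        region midpoints, for >=3-decade separations."""
        params = extreme_separation_params
        segments = asymptotic_bode(params)
        ladder = corner_frequencies(params)
        corners_hz = np.array(ladder.corners()) / (2 * math.pi)
        mids_hz = np.array(
            [math.sqrt(s.f_start_hz * s.f_stop_hz) for s in segments]
        )
        for f_set, tol in ((corners_hz, 3.1), (mids_hz, 0.5)):
            exact = 20 * np.log10(
                evaluate_impedance(params, FrequencyGrid(f_set)).magnitude
            )
            skel = skeleton_magnitude_db(segments, f_set)
            assert np.max(np.abs(skel - exact)) <= tol

    def test_medium_only_circuit_merges_cell_regions(self):
        params = CircuitParameters(R_s=2.0, R_ct=5e3, C_dl=2e-6, R_1=80.0, C_1=5e-12)
        segments = asymptotic_bode(params)
        assert [s.region for s in segments] == [1, 2, 3, 6, 7]

    def test_analytic_region4_peak_matches_numeric_spectrum(self, reference_params):
        """(f4, phi4) from the closed forms agrees with the numerically located
        region-4 phase minimum of the exact circuit (>=2.5-decade separation)."""
        from phytoeis import find_phase_peaks, metrics_from_params

        m = metrics_from_params(reference_params)
        grid = FrequencyGrid.log_spaced(1.0, 1e12, 40)
        peaks = find_phase_peaks(evaluate_impedance(reference_params, grid))
        region4 = min(peaks, key=lambda pk: abs(math.log10(pk.f_peak / m.f4)))
        assert region4.phi_min == pytest.approx(m.phi4, abs=1.5)
        assert region4.f_peak == pytest.approx(m.f4, rel=0.15)
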