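"""Spool mechanical model and spherical geometric model."""

import math

import numpy as np
import pytest

from nucspool.spool import (SpoolGeometry, WrapState, annotate_high_force,
                            annotate_low_force, calibrate_sphere_radius,
                            chord_length, end_state_deficit,
                            rotation_alignment_extension, sphere_bp_from_delta_x,
                            sphere_bp_remaining_from_offset, sphere_chord,
                            sphere_delta_x, with_calibrated_sphere, wrap_path,
                            wrap_tangent)
from nucspool.wlc import WLCParams, bp_from_delta_extension, wlc_extension, \
    wlc_relative_extension


class TestWrapPath:
    def test_full_wrap_spans_594_degrees(self, geometry):
        assert math.degrees(geometry.theta(147)) == pytest.approx(594.0)

    def test_path_arc_length_matches_helix_formula(self, geometry):
        pts = wrap_path(geometry, n_points=20001)
        arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        per_turn = math.hypot(2 * math.pi * geometry.superhelix_radius,
                              geometry.superhelix_pitch)
        assert arc == pytest.approx(per_turn * geometry.total_turns, rel=1e-3)

    def test_entry_exit_tangents_not_parallel_and_linkers_cross(self, geometry):
        t_in = wrap_tangent(geometry, 0)
        t_out = wrap_tangent(geometry, 147)
        cos = float(np.dot(t_in, t_out))
        assert abs(cos) < 0.99      # non-parallel
        # straight linker rays leave the entry (backward) and exit (forward);
        # in the plane normal to the superhelix axis their projections
        # intersect at positive ray parameters: the linkers cross
        p_in = wrap_path(geometry, 0, 0, 2)[0][:2]
        p_out = wrap_path(geometry, 147, 147, 2)[0][:2]
        d_in = -t_in[:2]
        d_out = t_out[:2]
        a = np.column_stack([d_in, -d_out])
        s, r = np.linalg.solve(a, p_out - p_in)
        assert s > 0 and r > 0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SpoolGeometry(superhelix_radius=-1)


class TestWrapState:
    def test_bp_conservation_enforced(self):
        WrapState(120, 27, 0)
        with pytest.raises(ValueError):
            WrapState(120, 20, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            WrapState(150, -3, 0)


class TestRotationAlignment:
    def test_already_aligned_contributes_nothing(self, geometry):
        before = WrapState(147, orientation="aligned")
        after = WrapState(147, orientation="aligned")
        assert rotation_alignment_extension(before, after, geometry) == 0.0

    def test_initial_rotation_of_full_wrap_is_8_1_nm(self, geometry):
        # reorientation from the zero-force crossed-linker pose to the
        # force-aligned pose, before any base pairs are released
        before = WrapState(147, orientation="crossed")
        after = WrapState(147, orientation="aligned")
        dx = rotation_alignment_extension(before, after, geometry)
        assert dx == pytest.approx(8.1, abs=0.3)

    def test_residual_rotation_during_unwrapping_is_3_2_nm(self, geometry):
        before = WrapState(147, orientation="aligned")
        after = WrapState(120, 27, 0, orientation="aligned")
        dx = rotation_alignment_extension(before, after, geometry)
        assert dx == pytest.approx(3.2, abs=0.3)

    def test_unreachable_end_orientation_raises(self, geometry):
        with pytest.raises(ValueError):
            rotation_alignment_extension(WrapState(147),
                                         WrapState(147, orientation="crossed"),
                                         geometry)


class TestLowForcePathway:
    def test_total_change_is_about_20_nm(self, geometry, wlc):
        path = annotate_low_force(geometry, wlc, force=4.0)
        assert path.total_nm == pytest.approx(20.0, abs=0.4)

    def test_120_bp_remain_wrapped_at_state_5(self, geometry, wlc):
        path = annotate_low_force(geometry, wlc)
        assert path.remaining_bp == 120
        assert path.rows[-1]["bp_wrapped"] == 120

    def test_decomposition_sums_to_total(self, geometry, wlc):
        path = annotate_low_force(geometry, wlc)
        assert path.total_nm == pytest.approx(
            path.total_rotation_nm + path.total_unwrap_nm, abs=1e-9)

    def test_zero_release_leaves_pure_rotation(self, geometry, wlc):
        # with no DNA released the pathway reduces to the rotation terms
        g0 = SpoolGeometry(low_force_release_bp=0)
        path = annotate_low_force(g0, wlc)
        assert path.total_unwrap_nm == 0.0
        assert path.total_nm == pytest.approx(path.total_rotation_nm)

    def test_state_labels_strictly_increasing(self, geometry, wlc):
        path = annotate_low_force(geometry, wlc)
        labels = [r["state"] for r in path.rows]
        assert labels == sorted(set(labels))


class TestHighForcePathway:
    def test_24_5_nm_rip_releases_about_76_bp(self, geometry, wlc):
        path = annotate_high_force(geometry, wlc, force=30.4, delta_x=24.5)
        assert path.released_bp == pytest.approx(76, abs=5)

    def test_remaining_wrap_is_about_43_bp(self, geometry, wlc):
        path = annotate_high_force(geometry, wlc)
        assert path.remaining_bp == pytest.approx(43, abs=5)

    def test_bp_conserved_across_the_rip(self, geometry, wlc):
        path = annotate_high_force(geometry, wlc)
        assert path.released_bp + path.remaining_bp == 120

    def test_rip_rotation_is_extension_neutral_in_the_chord_model(self, geometry):
        # the ~180 deg rotation maps chord(120) to chord(43): near-zero change
        assert abs(chord_length(geometry, 43)
                   - chord_length(geometry, 120)) < 0.5

    def test_end_state_deficit_is_6_2_nm(self, geometry, wlc):
        assert end_state_deficit(43, 30.4, geometry, wlc) == pytest.approx(
            6.2, abs=0.3)

    def test_oversized_delta_x_rejected(self, geometry, wlc):
        with pytest.raises(ValueError):
            annotate_high_force(geometry, wlc, delta_x=60.0)


@pytest.fixture(scope="module")
def cal(geometry, wlc):
    return with_calibrated_sphere(geometry, wlc)


class TestSphereModel:
    def test_calibration_matches_frozen_default(self, geometry, wlc):
        r = calibrate_sphere_radius(geometry, wlc)
        assert r == pytest.approx(geometry.effective_sphere_radius, abs=1e-3)

    def test_consistency_triple_pins_the_chord(self, cal, wlc):
        # chord of the 43-bp end state = WLC extension of 43 bp minus 6.2 nm
        chord = sphere_chord(cal, 43)
        assert chord == pytest.approx(
            wlc_extension(30.4, 43 * wlc.rise_per_bp, wlc) - 6.2, abs=1e-6)

    def test_24_5_nm_rip_corresponds_to_74_bp(self, cal, wlc):
        est = sphere_bp_from_delta_x(24.5, 30.4, cal, wlc)
        assert est.value == pytest.approx(74, abs=5)
        assert est.sigma == pytest.approx(5, abs=1)

    def test_agrees_with_exhaustive_integer_search(self, cal, wlc):
        # independent oracle: brute-force over all integer bp counts with a
        # directly-written prediction formula
        u = wlc_relative_extension(30.4, wlc)
        r = cal.effective_sphere_radius

        def chord(m):
            return 2 * r * abs(math.sin(m * 0.34 / (2 * r)))

        target = 24.5
        preds = [(n, abs(n * 0.34 * u + chord(120 - n) - chord(120) - target))
                 for n in range(0, 121)]
        oracle = min(preds, key=lambda p: p[1])[0]
        assert sphere_bp_from_delta_x(target, 30.4, cal, wlc).value == oracle

    def test_offset_2_3_nm_means_30_bp_remaining(self, cal, wlc):
        est = sphere_bp_remaining_from_offset(2.3, 30.4, cal, wlc)
        assert est.value == pytest.approx(30, abs=3)

    def test_offset_6_nm_means_about_40_bp_remaining(self, cal, wlc):
        # the tetrasome end state: ~6 nm deficit <-> ~40 bp still wrapped
        est = sphere_bp_remaining_from_offset(6.0, 30.4, cal, wlc)
        assert est.value == pytest.approx(40, abs=3)

    def test_zero_offset_means_zero_bp(self, cal, wlc):
        assert sphere_bp_remaining_from_offset(0.0, 30.4, cal, wlc).value == 0

    def test_zero_radius_limit_reduces_to_naive_inversion(self, wlc):
        tiny = SpoolGeometry(effective_sphere_radius=1e-9)
        est = sphere_bp_from_delta_x(24.5, 30.4, tiny, wlc)
        assert est.value == round(bp_from_delta_extension(24.5, 30.4, wlc))

    @pytest.mark.parametrize("n", list(range(10, 141, 10)))
    def test_mutual_consistency_of_forward_and_inverse(self, n, cal, wlc):
        u = wlc_relative_extension(30.4, wlc)
        offset = n * wlc.rise_per_bp * u - sphere_chord(cal, n)
        assert sphere_bp_remaining_from_offset(offset, 30.4, cal, wlc).value == n

    def test_out_of_range_inputs_rejected(self, cal, wlc):
        with pytest.raises(ValueError):
            sphere_bp_from_delta_x(80.0, 30.4, cal, wlc)
        with pytest.raises(ValueError):
            sphere_bp_remaining_from_offset(60.0, 30.4, cal, wlc)

    def test_delta_x_prediction_decomposes(self, cal, wlc):
        # chord bookkeeping: released WLC contour plus chord change
        u = wlc_relative_extension(30.4, wlc)
        for n in (20, 74):
            expected = (n * 0.34 * u + sphere_chord(cal, 120 - n)
                        - sphere_chord(cal, 120))
            assert sphere_delta_x(n, 30.4, cal, wlc) == pytest.approx(expected)
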