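"""Phantom construction, sequence timing, Bloch evolution and series simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aslmoco import (AcquisitionSpec, MotionTrace, apply_rigid, bgs_attenuation_map,
                     build_phantom, fourstep_motion, longitudinal_evolution,
                     simulate_asl_series, sms_slice_times)
from aslmoco.phantom_sim import LABEL_GM, T1_GM_MS


def piecewise_mz(m0, t1, events, t_query):
    """Independent stepwise closed-form evaluation of the relaxation recursion."""
    mz, t_prev = m0, None
    for t, kind in events:
        if t_prev is not None:
            e = np.exp(-(t - t_prev) / t1)
            mz = m0 * (1 - e) + mz * e
        mz = 0.0 if kind == "saturate" else -mz
        t_prev = t
    e = np.exp(-(t_query - t_prev) / t1)
    return m0 * (1 - e) + mz * e


class TestBuildPhantom:
    def test_mask_symmetric_and_perfusion_left_only(self):
        ph = build_phantom((64, 64, 18), seed=1)
        assert np.array_equal(ph.mask, ph.mask[::-1])
        assert np.all(ph.perfusion_dm[32:] == 0)
        assert np.any(ph.perfusion_dm[:32] > 0)

    def test_deterministic_for_fixed_seed(self):
        a = build_phantom(seed=4)
        b = build_phantom(seed=4)
        assert np.array_equal(a.m0, b.m0) and np.array_equal(a.t1, b.t1)
        assert not np.array_equal(a.m0, build_phantom(seed=5).m0)

    def test_grey_matter_t1_is_1200ms(self):
        ph = build_phantom(seed=0)
        assert np.all(ph.t1[ph.labels == LABEL_GM] == T1_GM_MS) and T1_GM_MS == 1200.0

    @pytest.mark.parametrize("shape,vox", [((8, 64, 18), (3, 3, 7)),
                                           ((64, 64, 18), (3, -1, 7)),
                                           ((64, 64), (3, 3, 7))])
    def test_invalid_geometry_rejected(self, shape, vox):
        with pytest.raises(ValueError):
            build_phantom(shape, vox)


class TestSliceTimes:
    def test_sms_grouping_18_slices_factor_3(self):
        acq = AcquisitionSpec(n_slices=18, sms_factor=3, inter_excitation_ms=30)
        t = sms_slice_times(acq)
        assert t[0] == t[6] == t[12] == 0.0
        assert t[5] == t[11] == t[17] == 150.0
        # exactly sms_factor slices per excitation time
        _, counts = np.unique(t, return_counts=True)
        assert np.all(counts == 3) and counts.size == 6

    def test_degenerate_single_band(self):
        acq = AcquisitionSpec(n_slices=18, sms_factor=1)
        assert np.array_equal(sms_slice_times(acq), 30.0 * np.arange(18))

    def test_indivisible_slice_count_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(n_slices=17, sms_factor=3)


class TestLongitudinalEvolution:
    def test_equilibrium_fixed_point(self):
        assert longitudinal_evolution(1.0, 1200.0, [], 5000.0) == 1.0

    def test_full_recovery_after_saturation(self):
        mz = longitudinal_evolution(2.0, 1200.0, [(0.0, "saturate")], 1e8)
        assert mz == pytest.approx(2.0, abs=1e-12)

    def test_matches_independent_piecewise_evaluation(self):
        events = [(0.0, "saturate"), (1860.0, "invert"), (3150.0, "invert")]
        got = longitudinal_evolution(1.0, 1200.0, events, 3600.0)
        assert got == pytest.approx(piecewise_mz(1.0, 1200.0, events, 3600.0), abs=1e-12)
        assert got == pytest.approx(0.045, abs=5e-4)

    @settings(deadline=None, max_examples=50)
    @given(t1=st.floats(100, 5000), ti1=st.floats(100, 2000), dti=st.floats(50, 1500),
           dt=st.floats(0, 2000))
    def test_bounded_by_equilibrium(self, t1, ti1, dti, dt):
        events = [(0.0, "saturate"), (ti1, "invert"), (ti1 + dti, "invert")]
        mz = longitudinal_evolution(1.0, t1, events, ti1 + dti + dt)
        assert -1.0 <= mz <= 1.0

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(ValueError):
            longitudinal_evolution(1.0, 0.0, [], 10.0)


class TestAttenuationMap:
    def test_unity_without_preparation_pulses(self, phantom64):
        acq = AcquisitionSpec(bgs_inversion_times_ms=(), saturation_time_ms=None)
        assert np.all(bgs_attenuation_map(phantom64, acq) == 1.0)

    def test_gm_factor_slice0_matches_bloch_oracle(self, phantom64, acq20):
        attn = bgs_attenuation_map(phantom64, acq20)
        gm = phantom64.labels == LABEL_GM
        events = [(0.0, "saturate"), (1860.0, "invert"), (3150.0, "invert")]
        for z, t_query in [(6, 3600.0), (11, 3750.0)]:
            sel = gm[:, :, z]
            expect = piecewise_mz(1.0, 1200.0, events, t_query)
            assert attn[:, :, z][sel] == pytest.approx(expect, abs=1e-12)

    def test_profile_periodic_with_largest_contrast_at_group_boundary(self, phantom64, acq20):
        attn = bgs_attenuation_map(phantom64, acq20)
        gm = phantom64.labels == LABEL_GM
        per_slice = np.array([attn[:, :, z][gm[:, :, z]].mean() if gm[:, :, z].any()
                              else np.nan for z in range(18)])
        valid = ~np.isnan(per_slice)
        # same excitation group -> identical GM factor (period n_slices/sms_factor)
        for z in range(12):
            if valid[z] and valid[z + 6]:
                assert per_slice[z] == pytest.approx(per_slice[z + 6], abs=1e-12)
        # exhaustive adjacent-slice comparison: maximum contrast at group boundary
        diffs = {z: abs(per_slice[z + 1] - per_slice[z]) for z in range(17)
                 if valid[z] and valid[z + 1]}
        assert max(diffs, key=diffs.get) in (5, 11)
        assert np.all(np.abs(attn) <= 1.0)

    def test_monotone_recovery_between_groups(self, phantom64, acq20):
        attn = bgs_attenuation_map(phantom64, acq20)
        gm = phantom64.labels == LABEL_GM
        z0 = 6  # first slice of a full group run with GM present
        vals = [attn[:, :, z][gm[:, :, z]].mean() for z in range(z0, z0 + 6)]
        assert np.all(np.diff(vals) > 0)


class TestFourstepMotion:
    def test_plateau_values_match_pattern(self):
        tr = fourstep_motion("tz", 4.2, 8.4, 60)
        assert set(np.unique(tr.params[:, 2])) == {4.2, -4.2, 8.4, -8.4}
        assert np.all(tr.params[:, [0, 1, 3, 4, 5]] == 0)

    def test_zero_magnitudes_give_zero_trace(self):
        assert np.all(fourstep_motion("ty", 0, 0, 8).params == 0)

    def test_rotation_extremes(self):
        tr = fourstep_motion("rx", 3, 6, 60)
        assert tr.params[:, 3].max() == 6.0 and tr.params[:, 3].min() == -6.0

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            fourstep_motion("qq", 1, 2, 8)
        with pytest.raises(ValueError):
            fourstep_motion("tx", 1, 2, 10)


class TestApplyRigid:
    def test_identity_is_exact(self, phantom_small):
        out = apply_rigid(phantom_small.m0, np.zeros(6), phantom_small.voxel_size)
        assert np.array_equal(out, phantom_small.m0)

    def test_integer_voxel_translation_of_impulse(self):
        vol = np.zeros((16, 16, 8))
        vol[8, 8, 4] = 1.0
        out = apply_rigid(vol, [3.0, -6.0, 7.0, 0, 0, 0], (3.0, 3.0, 7.0))
        assert out[9, 6, 5] == pytest.approx(1.0, abs=1e-9)
        assert np.sum(out) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_inverse_composition(self, phantom_small):
        from scipy import ndimage

        vox = phantom_small.voxel_size
        fwd = apply_rigid(phantom_small.m0, [0, 0, 0, 3.0, 0, 0], vox, interp="spline")
        back = apply_rigid(fwd, [0, 0, 0, -3.0, 0, 0], vox, interp="spline")
        interior = ndimage.binary_erosion(phantom_small.mask, iterations=2)
        dev = np.abs(back - phantom_small.m0)[interior].max()
        assert dev < 0.02 * np.ptp(phantom_small.m0)

    def test_unknown_interpolation_rejected(self, phantom_small):
        with pytest.raises(ValueError):
            apply_rigid(phantom_small.m0, np.zeros(6), phantom_small.voxel_size,
                        interp="sinc")


class TestSimulateSeries:
    def test_conservation_without_bgs_motion_perfusion(self, phantom_small, acq_small):
        s = simulate_asl_series(phantom_small, acq_small, with_bgs=False,
                                include_perfusion=False)
        for d in range(acq_small.n_dynamics):
            assert np.array_equal(s.data[..., d], phantom_small.m0)

    def test_control_label_alternation_and_right_hemisphere_null(self, phantom_small, acq_small):
        s = simulate_asl_series(phantom_small, acq_small, with_bgs=True)
        assert list(s.condition_labels[:4]) == ["control", "label", "control", "label"]
        # no perfusion simulated on the right: control - label vanishes there
        right = slice(phantom_small.shape[0] // 2, None)
        diff = s.data[right, :, :, 0] - s.data[right, :, :, 1]
        assert np.abs(diff).max() == 0.0
        left_diff = s.data[:16, :, :, 0] - s.data[:16, :, :, 1]
        assert left_diff.max() > 0

    def test_ground_truth_roundtrip(self, phantom_small, acq_small):
        from aslmoco import reslice_with_trace
        from scipy import ndimage

        motion = fourstep_motion("tz", 4.2, 8.4, acq_small.n_dynamics)
        moved = simulate_asl_series(phantom_small, acq_small, motion, with_bgs=False,
                                    include_perfusion=False, interp="spline")
        restored = reslice_with_trace(moved.data, motion, phantom_small.voxel_size,
                                      interp="spline")
        interior = ndimage.binary_erosion(phantom_small.mask, iterations=3)
        rng = np.ptp(phantom_small.m0)
        for d in range(acq_small.n_dynamics):
            dev = np.abs(restored[..., d] - phantom_small.m0)[interior].max()
            assert dev < 0.02 * rng

    def test_seven_series_simulation_design(self, phantom_small, acq_small):
        n = acq_small.n_dynamics
        series = [simulate_asl_series(phantom_small, acq_small)]  # untouched
        for axis in ("tx", "ty", "tz", "rx", "ry", "rz"):
            motion = fourstep_motion(axis, 4.2, 8.4, n) if axis.startswith("t") \
                else fourstep_motion(axis, 3, 6, n)
            series.append(simulate_asl_series(phantom_small, acq_small, motion))
        assert len(series) == 7
        assert all(s.data.shape[3] == n for s in series)

    def test_mismatched_motion_length_rejected(self, phantom_small, acq_small):
        with pytest.raises(ValueError):
            simulate_asl_series(phantom_small, acq_small, MotionTrace.zeros(5))
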