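"""Measurement simulation and profile reconstruction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beamvalid import (
    ChamberModel,
    ElectrometerLog,
    FieldSize,
    NoiseModel,
    center_profile,
    dose_at,
    emit_delivery_schedule,
    normalize_profile,
    reconstruct_profile,
    sample_lateral_curve,
    simulate_scan,
    stitch_scans,
)
from beamvalid.curves import Curve
from beamvalid.protocol import ScanSegment


def crossline_segment(start=-9.0, end=9.0, fs=10, depth=10.0, offset=0.0):
    return ScanSegment(axis="crossline", field_size=FieldSize.square(fs),
                       depth_cm=depth, window_start_cm=start, window_end_cm=end,
                       speed_cm_s=0.15, sampling_interval_s=0.3,
                       tank_offset_cm=offset)


POINT_CHAMBER = ChamberModel(size_cm=0.0, leakage_nA=0.0)


class TestSimulateScan:
    def test_sample_count_at_300ms(self, beam):
        sched = emit_delivery_schedule(crossline_segment())
        log = simulate_scan(sched, beam, NoiseModel.none(), seed=0)
        assert len(log.times_s) == 401  # 120 s / 0.3 s + 1

    def test_noiseless_point_chamber_reads_model_dose(self, beam):
        seg = crossline_segment(start=-4.0, end=4.0)
        sched = emit_delivery_schedule(seg)
        log = simulate_scan(sched, beam, NoiseModel.none(), POINT_CHAMBER, seed=0)
        curve = reconstruct_profile(log, sched, POINT_CHAMBER)
        expected = dose_at(curve.positions, np.zeros_like(curve.positions),
                           10.0, seg.field_size, beam)
        ratio = POINT_CHAMBER.field_current_nA / POINT_CHAMBER.ref_current_nA
        assert np.allclose(curve.values, ratio * expected, rtol=1e-12, atol=0)

    def test_seed_determinism(self, beam):
        sched = emit_delivery_schedule(crossline_segment())
        noise = NoiseModel(sigma_rel=0.01)
        a = simulate_scan(sched, beam, noise, seed=42)
        b = simulate_scan(sched, beam, noise, seed=42)
        c = simulate_scan(sched, beam, noise, seed=43)
        assert np.array_equal(a.field_nA, b.field_nA)
        assert not np.array_equal(a.field_nA, c.field_nA)
        assert a.seed == 42

    def test_log_csv_round_trip(self, beam, tmp_path):
        sched = emit_delivery_schedule(crossline_segment())
        log = simulate_scan(sched, beam, NoiseModel(sigma_rel=0.002), seed=7)
        path = tmp_path / "log.csv"
        log.to_csv(path)
        back = ElectrometerLog.from_csv(path)
        assert back.segment == log.segment
        assert back.seed == 7
        assert np.array_equal(back.field_nA, log.field_nA)


class TestReconstructProfile:
    def test_zero_noise_round_trip_within_tolerance(self, beam):
        # full chain on one segment: deviation from the model stays below
        # 0.3% of the central-axis value
        seg = crossline_segment(start=-8.0, end=8.0)
        sched = emit_delivery_schedule(seg)
        chamber = ChamberModel()
        log = simulate_scan(sched, beam, NoiseModel.none(), chamber, seed=0)
        curve = reconstruct_profile(log, sched, chamber)
        from beamvalid.beam import box_averaged_dose

        model = box_averaged_dose(curve.positions,
                                  np.zeros_like(curve.positions),
                                  np.full_like(curve.positions, 10.0),
                                  seg.field_size, beam, edge_cm=chamber.size_cm)
        scale = chamber.field_current_nA / chamber.ref_current_nA
        cax = scale * box_averaged_dose(0.0, 0.0, 10.0, seg.field_size, beam,
                                        edge_cm=chamber.size_cm)
        assert np.abs(curve.values - scale * model).max() / cax < 0.003

    def test_tank_offset_restored(self, beam):
        seg = crossline_segment(start=0.5, end=19.5, fs=28, offset=9.5)
        sched = emit_delivery_schedule(seg)
        log = simulate_scan(sched, beam, NoiseModel.none(), seed=0)
        curve = reconstruct_profile(log, sched)
        assert curve.lo == pytest.approx(0.5, abs=0.05)
        assert curve.hi == pytest.approx(19.5, abs=0.05)

    def test_epom_shift_on_depth_scan(self, beam):
        seg = ScanSegment(axis="depth", field_size=FieldSize.square(10),
                          depth_cm=None, window_start_cm=30.0, window_end_cm=0.0,
                          speed_cm_s=0.25, sampling_interval_s=0.1)
        sched = emit_delivery_schedule(seg)
        chamber = ChamberModel(epom_shift_cm=0.18)
        log = simulate_scan(sched, beam, NoiseModel.none(), chamber, seed=0)
        curve = reconstruct_profile(log, sched, chamber)
        # the sample recorded with the chamber centre at 10.00 cm is
        # reported at 9.82 cm
        assert np.min(np.abs(curve.positions - 9.82)) < 1e-9
        assert curve.lo == pytest.approx(-0.18)

    def test_diagonal_positions_scale_with_sqrt2(self, beam):
        seg = ScanSegment(axis="diagonal", field_size=FieldSize.square(28),
                          depth_cm=10.0, window_start_cm=-8.0, window_end_cm=8.0,
                          speed_cm_s=0.2 * math.sqrt(2.0),
                          sampling_interval_s=0.3)
        sched = emit_delivery_schedule(seg)
        log = simulate_scan(sched, beam, NoiseModel.none(), seed=0)
        curve = reconstruct_profile(log, sched)
        # couch trajectory has x = y; radial position is sqrt(2) x
        t = np.interp(curve.positions, [-8.0, 8.0], [0.0, seg.duration_s])
        x_single = np.interp(t, sched.times_s, sched.couch_x_cm)
        assert np.allclose(curve.positions, np.sqrt(2.0) * x_single, atol=1e-9)

    def test_mismatched_segment_rejected(self, beam):
        sched_a = emit_delivery_schedule(crossline_segment())
        sched_b = emit_delivery_schedule(crossline_segment(fs=20))
        log = simulate_scan(sched_a, beam, NoiseModel.none(), seed=0)
        with pytest.raises(ValueError, match="different segments"):
            reconstruct_profile(log, sched_b)


def _measured_curve(beam, start, end, fs=20, seed=0, noise=None):
    seg = crossline_segment(start=start, end=end, fs=fs)
    sched = emit_delivery_schedule(seg)
    log = simulate_scan(sched, beam, noise or NoiseModel.none(), seed=seed)
    return reconstruct_profile(log, sched)


class TestStitchScans:
    def test_split_then_stitch_reproduces_full_scan(self, beam):
        full = _measured_curve(beam, -10.0, 10.0)
        # the electrometer quantizes scan ends to the sample grid, so the
        # realized overlap is just under the nominal 1 cm
        left = _measured_curve(beam, -10.0, 0.5)
        right = _measured_curve(beam, -0.5, 10.0)
        merged = stitch_scans(left, right, overlap_cm=0.9)
        resampled = np.interp(full.positions, merged.positions, merged.values)
        assert np.abs(resampled - full.values).max() / full.values.max() < 1e-3

    def test_identical_overlapping_curves_unchanged(self, beam):
        a = _measured_curve(beam, -10.0, 2.0)
        b = _measured_curve(beam, -2.0, 10.0)
        merged = stitch_scans(a, b, overlap_cm=1.0)
        assert np.allclose(merged.interp(a.positions), a.values, atol=1e-9)
        assert np.allclose(merged.interp(b.positions), b.values, atol=1e-9)

    def test_global_gain_mismatch_leaves_no_seam(self, beam):
        a = _measured_curve(beam, -10.0, 0.5)
        b = _measured_curve(beam, -0.5, 10.0)
        b = b.with_values(b.values * 1.02)
        merged = stitch_scans(a, b, overlap_cm=0.9)
        steps = np.abs(np.diff(merged.values))
        # no jump anywhere larger than the physical inter-sample change
        smooth = np.abs(np.diff(
            np.interp(merged.positions, a.positions, a.values)))
        assert steps.max() < smooth.max() * 1.5 + 1e-6

    def test_order_insensitive(self, beam):
        a = _measured_curve(beam, -10.0, 0.5)
        b = _measured_curve(beam, -0.5, 10.0)
        ab = stitch_scans(a, b, overlap_cm=0.9)
        ba = stitch_scans(b, a, overlap_cm=0.9)
        assert np.allclose(ab.values, ba.values, atol=1e-9)
        assert np.array_equal(ab.positions, ba.positions)

    def test_insufficient_overlap_rejected(self, beam):
        a = _measured_curve(beam, -10.0, 0.0)
        b = _measured_curve(beam, 0.2, 10.0)
        with pytest.raises(ValueError, match="overlap"):
            stitch_scans(a, b, overlap_cm=1.0)

    def test_metadata_mismatch_rejected(self, beam):
        a = _measured_curve(beam, -10.0, 0.5, fs=20)
        b = _measured_curve(beam, -0.5, 10.0, fs=28)
        with pytest.raises(ValueError, match="metadata"):
            stitch_scans(a, b, overlap_cm=1.0)


class TestCenterProfile:
    def test_mirrored_tps_curve_shift_exactly_zero(self, beam):
        curve = sample_lateral_curve(beam, FieldSize.square(10), 10.0, 14.5)
        _, shift = center_profile(curve)
        assert shift == 0.0

    def test_symmetric_measured_profile_shift_negligible(self, beam):
        curve = _measured_curve(beam, -10.0, 10.0)
        _, shift = center_profile(curve)
        assert abs(shift) < 2e-4  # sub-micrometre, limited by sample quantization

    def test_known_translation_recovered(self, beam):
        curve = _measured_curve(beam, -10.0, 10.0)
        moved = curve.with_positions(curve.positions + 0.2)
        centered, shift = center_profile(moved)
        assert shift == pytest.approx(0.2, abs=0.005)  # within 0.05 mm
        assert np.allclose(centered.positions, curve.positions, atol=0.005)

    def test_flat_curve_rejected(self):
        flat = Curve(axis="crossline", depth_cm=10.0,
                     field_size=FieldSize.square(10),
                     positions=np.linspace(-5, 5, 11),
                     values=np.full(11, 2.0), provenance="measured")
        with pytest.raises(ValueError, match="50%"):
            center_profile(flat)


class TestNormalizeProfile:
    def test_lateral_cax_three_point_mean(self):
        curve = Curve(axis="crossline", depth_cm=10.0,
                      field_size=FieldSize.square(10),
                      positions=np.array([-1.0, 0.0, 1.0, 2.0]),
                      values=np.array([1.01, 1.00, 0.99, 0.5]),
                      provenance="measured")
        out = normalize_profile(curve)
        assert np.mean(out.values[:3]) == pytest.approx(100.0)

    def test_depth_max_is_exactly_100(self, beam):
        from beamvalid import sample_depth_curve

        out = normalize_profile(sample_depth_curve(beam, FieldSize.square(10)))
        assert out.values.max() == 100.0

    @given(scale=st.floats(0.1, 10.0))
    def test_idempotent_and_scale_invariant(self, beam, scale):
        curve = sample_lateral_curve(beam, FieldSize.square(10), 10.0, 14.5)
        once = normalize_profile(curve.with_values(curve.values * scale))
        twice = normalize_profile(once)
        assert np.allclose(once.values, normalize_profile(curve).values,
                           rtol=1e-12)
        assert np.array_equal(once.values, twice.values)

    def test_non_positive_normalizer_rejected(self):
        curve = Curve(axis="crossline", depth_cm=10.0,
                      field_size=FieldSize.square(10),
                      positions=np.array([-1.0, 0.0, 1.0]),
                      values=np.array([0.0, 0.0, 0.0]), provenance="measured")
        with pytest.raises(ValueError):
            normalize_profile(curve)
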