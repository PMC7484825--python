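"""Protocol builder: segment planning, timing, schedules, checksums."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beamvalid import (
    FieldSize,
    ProtocolError,
    build_default_protocol,
    emit_delivery_schedule,
    estimate_scan_time,
    imaging_gantry_angle,
    plan_lateral_scan,
    protocol_time_summary,
    schedule_from_xml,
    verify_schedule_checksum,
)
from beamvalid.protocol import ProtocolConfig, ScanSegment, scan_time_min


class TestBuildDefaultProtocol:
    def test_default_request_yields_75_segments(self, paper_protocol_config):
        assert len(build_default_protocol(paper_protocol_config)) == 75

    def test_dropping_diagonals_removes_exactly_10(self, paper_protocol_config):
        import dataclasses

        no_diag = dataclasses.replace(
            paper_protocol_config, axes=("depth", "inline", "crossline"))
        assert len(build_default_protocol(no_diag)) == 65

    def test_degenerate_single_scan_request(self):
        cfg = ProtocolConfig(field_sizes_cm=(10.0,), profile_depths_cm=(10.0,),
                             axes=("crossline",), diagonal_field_sizes_cm=())
        protocol = build_default_protocol(cfg)
        assert len(protocol) == 1
        assert protocol.segments[0].tank_offset_cm == 0.0

    def test_crossline_20x20_split_at_every_depth(self, paper_protocol_config):
        protocol = build_default_protocol(paper_protocol_config)
        segs = [s for s in protocol.segments
                if s.axis == "crossline" and s.field_size.x_cm == 20.0]
        assert len(segs) == 10  # 2 offset scans x 5 depths

    def test_ordering_depth_inline_crossline_diagonal(self, paper_protocol_config):
        protocol = build_default_protocol(paper_protocol_config)
        order = {"depth": 0, "inline": 1, "crossline": 2, "diagonal": 3}
        ranks = [order[s.axis] for s in protocol.segments]
        assert ranks == sorted(ranks)

    def test_depth_beyond_tank_rejected(self, paper_protocol_config):
        import dataclasses

        bad = dataclasses.replace(paper_protocol_config, depth_scan_range_cm=40.0)
        with pytest.raises(ProtocolError, match="tank"):
            build_default_protocol(bad)

    def test_empty_request_rejected(self):
        with pytest.raises(ProtocolError):
            build_default_protocol(ProtocolConfig(field_sizes_cm=()))


class TestPlanLateralScan:
    def test_offset_scan_reaches_plus_19_5(self):
        segs = plan_lateral_scan(FieldSize.square(28), 10.0, "crossline",
                                 range_limit_cm=20.0, offset_cm=9.5,
                                 overlap_cm=1.0, margin_cm=2.5)
        assert len(segs) == 2
        assert segs[0].window_start_cm == pytest.approx(19.5)
        assert segs[0].window_end_cm == pytest.approx(-0.5)
        assert segs[1].window_start_cm == pytest.approx(0.5)
        assert segs[1].window_end_cm == pytest.approx(-19.5)

    def test_exact_fit_single_centered_segment(self):
        # 6 cm field at 10 cm depth projects to 6 cm; 6 cm margins -> 18 cm
        (seg,) = plan_lateral_scan(FieldSize.square(6), 10.0, "crossline",
                                   range_limit_cm=18.0, offset_cm=9.5,
                                   overlap_cm=1.0, margin_cm=6.0)
        assert seg.window_start_cm == pytest.approx(-9.0)
        assert seg.window_end_cm == pytest.approx(9.0)

    def test_split_union_is_contiguous_interval(self):
        segs = plan_lateral_scan(FieldSize.square(28), 30.0, "crossline",
                                 range_limit_cm=20.0, offset_cm=9.5,
                                 overlap_cm=1.0, margin_cm=2.5)
        lo = min(s.window_lo for s in segs)
        hi = max(s.window_hi for s in segs)
        # windows [-19.5, 0.5] and [-0.5, 19.5]: union is one 39 cm interval
        assert hi - lo == pytest.approx(39.0)
        assert segs[0].window_lo < segs[1].window_hi  # they genuinely overlap

    def test_uncoverable_window_rejected(self):
        with pytest.raises(ProtocolError, match="uncoverable"):
            plan_lateral_scan(FieldSize.square(28), 30.0, "crossline",
                              range_limit_cm=20.0, offset_cm=9.5,
                              overlap_cm=1.0, margin_cm=10.0)

    @given(side=st.floats(2.0, 28.0), depth=st.floats(0.0, 30.0),
           margin=st.floats(0.0, 4.0))
    def test_windows_symmetric_and_overlap_exact(self, side, depth, margin):
        try:
            segs = plan_lateral_scan(FieldSize.square(side), depth, "crossline",
                                     range_limit_cm=20.0, offset_cm=9.5,
                                     overlap_cm=1.0, margin_cm=margin)
        except ProtocolError:
            return  # uncoverable request, correctly rejected
        if len(segs) == 1:
            assert segs[0].window_lo == pytest.approx(-segs[0].window_hi)
        else:
            a, b = segs
            assert a.window_lo == pytest.approx(-b.window_hi)
            assert a.window_hi == pytest.approx(-b.window_lo)
            overlap = min(a.window_hi, b.window_hi) - max(a.window_lo, b.window_lo)
            assert overlap == pytest.approx(1.0)


class TestScanTiming:
    def test_depth_scan_takes_two_minutes(self):
        seg = ScanSegment(axis="depth", field_size=FieldSize.square(10),
                          depth_cm=None, window_start_cm=30.0, window_end_cm=0.0,
                          speed_cm_s=0.25, sampling_interval_s=0.1)
        assert estimate_scan_time(seg) == pytest.approx(2.00)

    def test_zero_length_window_takes_no_time(self):
        assert scan_time_min(0.0, 0.15) == 0.0

    def test_45_cm_inline_scan_duration(self):
        assert scan_time_min(45.0, 0.15) == pytest.approx(5.00)

    def test_summary_reproduces_published_scan_counts(self, paper_protocol_config):
        protocol = build_default_protocol(paper_protocol_config)
        df, totals = protocol_time_summary(protocol, paper_protocol_config)
        assert df["n_scans"].tolist() == [5, 5, 5, 5, 5, 5, 5, 5, 5, 10, 10, 10]
        assert totals["overall_min"] == pytest.approx(
            totals["scanning_min"] + 60.0)

    def test_summary_buffers_match_offset_rule(self, paper_protocol_config):
        # 1 min settling, +2 min whenever the tank is shifted
        protocol = build_default_protocol(paper_protocol_config)
        df, _ = protocol_time_summary(protocol, paper_protocol_config)
        by_type = dict(zip(zip(df["scan_type"], df["field_size"]), df["buffer_min"]))
        assert by_type[("crossline", "6x6")] == 1.0
        assert by_type[("crossline", "28x28")] == 3.0
        assert by_type[("diagonal", "28x28")] == 3.0
        assert by_type[("depth", "ALL")] == 0.0


class TestDeliverySchedule:
    def _crossline_segment(self):
        return ScanSegment(axis="crossline", field_size=FieldSize.square(10),
                           depth_cm=10.0, window_start_cm=-9.0,
                           window_end_cm=9.0, speed_cm_s=0.15,
                           sampling_interval_s=0.3)

    def test_traversal_duration(self):
        sched = emit_delivery_schedule(self._crossline_segment())
        assert sched.times_s[-1] == pytest.approx(120.0)
        assert sched.beam_on.all()

    def test_implied_speed_constant(self):
        sched = emit_delivery_schedule(self._crossline_segment())
        speeds = np.abs(np.diff(sched.couch_x_cm) / np.diff(sched.times_s))
        assert np.allclose(speeds, 0.15, atol=1e-9)

    def test_diagonal_along_path_speed(self):
        seg = ScanSegment(axis="diagonal", field_size=FieldSize.square(28),
                          depth_cm=10.0, window_start_cm=12.5,
                          window_end_cm=-12.5,
                          speed_cm_s=0.2 * math.sqrt(2.0),
                          sampling_interval_s=0.3, tank_offset_cm=12.0)
        assert seg.speed_cm_s == pytest.approx(0.283, abs=5e-4)
        sched = emit_delivery_schedule(seg)
        # each couch axis moves at the 0.2 cm/s component speed
        vx = np.abs(np.diff(sched.couch_x_cm) / np.diff(sched.times_s))
        assert np.allclose(vx, 0.2, atol=1e-9)
        assert np.array_equal(sched.couch_x_cm, sched.couch_y_cm)

    def test_xml_round_trip_is_identity(self, tmp_path):
        sched = emit_delivery_schedule(self._crossline_segment())
        path = tmp_path / "scan.xml"
        sched.write(path)
        assert schedule_from_xml(path) == sched

    def test_checksum_stable_and_tamper_evident(self, tmp_path):
        sched = emit_delivery_schedule(self._crossline_segment())
        assert sched.checksum == sched.checksum
        path = tmp_path / "scan.xml"
        sched.write(path)
        assert verify_schedule_checksum(path)
        text = path.read_text().replace('couch_x_cm="-9.0"', 'couch_x_cm="-9.1"')
        assert not verify_schedule_checksum(text)


class TestImagingGantryAngle:
    @pytest.mark.parametrize("ssd,expected,tol", [
        (90.0, 84.3, 0.05),        # published setting
        (100.0, 90.0, 1e-12),      # isocenter at the surface
        (95.0, 87.1376, 1e-3),     # 90 - atan(0.05) in degrees
    ])
    def test_angles(self, ssd, expected, tol):
        assert imaging_gantry_angle(ssd, 100.0) == pytest.approx(expected, abs=tol)

    def test_isocenter_above_water_rejected(self):
        with pytest.raises(ValueError):
            imaging_gantry_angle(105.0, 100.0)
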