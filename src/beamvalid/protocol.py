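"""Scan-protocol construction for a bore-limited ring-gantry linac.

A validation request (field sizes, depths, axes, per-axis scan settings) is
expanded into an executable protocol of continuous couch-driven scans.  The
enclosed ~100 cm bore limits couch travel across it, so wide crossline and
diagonal profiles are split into two offset scans that overlap by a
configured length and are stitched after measurement; the longitudinal
(inline) direction is unrestricted.  Each segment can be emitted as a
couch-position-vs-time delivery schedule (a generic XML dialect with a
SHA-256 integrity checksum) and the whole protocol summarized as a
per-row scan-time table.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .beam import FieldSize

__all__ = [
    "ProtocolError",
    "ScanAxisConfig",
    "ProtocolConfig",
    "ScanSegment",
    "ScanProtocol",
    "DeliverySchedule",
    "plan_lateral_scan",
    "build_default_protocol",
    "estimate_scan_time",
    "scan_time_min",
    "protocol_time_summary",
    "emit_delivery_schedule",
    "schedule_from_xml",
    "verify_schedule_checksum",
    "imaging_gantry_angle",
]

LATERAL_AXES = ("crossline", "inline", "diagonal")


class ProtocolError(ValueError):
    """A validation request that cannot be turned into an executable scan."""


@dataclass(frozen=True)
class ScanAxisConfig:
    """Per-axis scan settings.

    speed_cm_s is the along-path couch speed; for diagonal scans the two
    couch axes each move at speed/sqrt(2).  range_limit_cm is the longest
    single continuous scan achievable along this axis; margin_cm is the
    scan extension beyond the projected field edge on each side;
    offset_cm is the along-axis tank-platform offset used for split scans.
    """

    speed_cm_s: float
    sampling_interval_s: float
    range_limit_cm: float
    margin_cm: float = 0.0
    offset_cm: float = 0.0
    buffer_min: float = 1.0
    shifted_buffer_min: float = 3.0


def _default_axis_configs() -> dict[str, ScanAxisConfig]:
    # Scan speeds and sampling rates of the published protocol: laterals at
    # 1.5 mm/s / 300 ms, diagonals at 2 mm/s per couch axis (2.83 mm/s along
    # the path), depth at 2.5 mm/s / 100 ms.  The bore limits only the
    # lateral direction (~20 cm range, 9.5 cm platform offset); the
    # diagonal along-path limit is 18*sqrt(2) = 25.46 cm.
    return {
        "depth": ScanAxisConfig(0.25, 0.1, 30.0, buffer_min=0.0),
        "inline": ScanAxisConfig(0.15, 0.3, 45.0, margin_cm=5.5),
        "crossline": ScanAxisConfig(0.15, 0.3, 20.0, margin_cm=2.5, offset_cm=9.5),
        "diagonal": ScanAxisConfig(
            0.2 * math.sqrt(2.0), 0.3, 25.46, margin_cm=2.5, offset_cm=12.0,
            buffer_min=3.0,
        ),
    }


@dataclass(frozen=True)
class ProtocolConfig:
    """Validation request: what to scan and with which machine settings."""

    field_sizes_cm: tuple = (6.0, 8.0, 10.0, 20.0, 28.0)
    profile_depths_cm: tuple = (1.3, 5.0, 10.0, 20.0, 30.0)
    axes: tuple = ("depth", "inline", "crossline", "diagonal")
    diagonal_field_sizes_cm: tuple = (28.0,)
    ssd_cm: float = 90.0
    sad_cm: float = 100.0
    depth_scan_range_cm: float = 30.0
    overlap_cm: float = 1.0
    tank_depth_cm: float = 37.0
    setup_min: float = 30.0
    takedown_min: float = 30.0
    axis_configs: dict = field(default_factory=_default_axis_configs)

    def axis_config(self, axis: str) -> ScanAxisConfig:
        try:
            return self.axis_configs[axis]
        except KeyError:
            raise ProtocolError(f"no scan settings configured for axis {axis!r}") from None


@dataclass(frozen=True)
class ScanSegment:
    """One continuous scan: axis, window, speed, sampling, tank offset.

    window_start/window_end are isocenter-relative along-axis coordinates
    (depth coordinates for depth scans); the scan runs from start to end,
    so start > end means the couch travels in the negative direction.
    """

    axis: str
    field_size: FieldSize
    depth_cm: float | None
    window_start_cm: float
    window_end_cm: float
    speed_cm_s: float
    sampling_interval_s: float
    tank_offset_cm: float = 0.0
    buffer_min: float = 0.0

    def __post_init__(self) -> None:
        if self.window_start_cm == self.window_end_cm:
            raise ValueError("scan window must have nonzero length")
        if self.speed_cm_s <= 0:
            raise ValueError("scan speed must be positive")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")
        if self.axis == "depth" and self.depth_cm is not None:
            raise ValueError("depth segments carry no depth_cm")

    @property
    def length_cm(self) -> float:
        return abs(self.window_end_cm - self.window_start_cm)

    @property
    def duration_s(self) -> float:
        return self.length_cm / self.speed_cm_s

    @property
    def window_lo(self) -> float:
        return min(self.window_start_cm, self.window_end_cm)

    @property
    def window_hi(self) -> float:
        return max(self.window_start_cm, self.window_end_cm)

    @property
    def group_key(self) -> tuple:
        d = None if self.depth_cm is None else round(float(self.depth_cm), 3)
        return (self.axis, self.field_size.label(), d)


@dataclass(frozen=True)
class ScanProtocol:
    segments: tuple
    ssd_cm: float = 90.0
    sad_cm: float = 100.0

    def __len__(self) -> int:
        return len(self.segments)

    def groups(self) -> dict:
        """Segments grouped by (axis, field size, depth), insertion-ordered."""
        out: dict[tuple, list[ScanSegment]] = {}
        for seg in self.segments:
            out.setdefault(seg.group_key, []).append(seg)
        return out


# ---------------------------------------------------------------------------
# planning


def required_window_cm(field_size: FieldSize, depth_cm: float, axis: str,
                       margin_cm: float, ssd_cm: float = 90.0,
                       sad_cm: float = 100.0) -> float:
    """Along-axis window needed to cover the projected field plus margins.

    The field edge projects to (side/2)*(ssd+d)/sad at depth d.  For
    diagonal scans the radial reach of the crossline window is used: the
    corner-to-corner diagonal of a large square field exceeds any
    bore-feasible coverage, and radial positions are what the diagonal
    curve is compared on.
    """
    side = field_size.y_cm if axis == "inline" else field_size.x_cm
    projected = side * (ssd_cm + depth_cm) / sad_cm
    return projected + 2.0 * margin_cm


def plan_lateral_scan(field_size: FieldSize, depth_cm: float, axis: str,
                      range_limit_cm: float, offset_cm: float,
                      overlap_cm: float, margin_cm: float, *,
                      speed_cm_s: float = 0.15, sampling_interval_s: float = 0.3,
                      ssd_cm: float = 90.0, sad_cm: float = 100.0,
                      buffer_min: float = 1.0,
                      shifted_buffer_min: float = 3.0) -> list[ScanSegment]:
    """Plan one lateral profile as one centered scan or a split pair.

    If the required window fits within ``range_limit_cm`` a single centered
    segment is returned.  Otherwise two segments are planned at tank
    offsets +-``offset_cm``, each of length ``2*offset + overlap`` so their
    windows overlap by exactly ``overlap_cm`` and their union is contiguous
    and symmetric about the axis.
    """
    if range_limit_cm <= 0:
        raise ProtocolError("range limit must be positive")
    w = required_window_cm(field_size, depth_cm, axis, margin_cm, ssd_cm, sad_cm)
    common = dict(
        axis=axis, field_size=field_size, depth_cm=depth_cm,
        speed_cm_s=speed_cm_s, sampling_interval_s=sampling_interval_s,
    )
    if w <= range_limit_cm + 1e-9:
        half = w / 2.0
        return [ScanSegment(window_start_cm=-half, window_end_cm=half,
                            tank_offset_cm=0.0, buffer_min=buffer_min, **common)]

    if offset_cm <= 0:
        raise ProtocolError(
            f"{axis} window of {w:.2f} cm exceeds the {range_limit_cm:g} cm "
            "single-scan range and no tank offset is configured"
        )
    seg_len = 2.0 * offset_cm + overlap_cm
    if seg_len > range_limit_cm + 1e-9:
        raise ProtocolError(
            f"split-scan length {seg_len:.2f} cm (2*offset + overlap) exceeds "
            f"the {range_limit_cm:g} cm range limit for axis {axis!r}"
        )
    coverage = 2.0 * offset_cm + seg_len
    if w > coverage + 1e-9:
        raise ProtocolError(
            f"required {axis} window {w:.2f} cm is uncoverable: two offset "
            f"scans reach only {coverage:.2f} cm"
        )
    half = seg_len / 2.0
    pos = ScanSegment(window_start_cm=offset_cm + half,
                      window_end_cm=offset_cm - half,
                      tank_offset_cm=offset_cm,
                      buffer_min=shifted_buffer_min, **common)
    neg = ScanSegment(window_start_cm=-offset_cm + half,
                      window_end_cm=-offset_cm - half,
                      tank_offset_cm=-offset_cm,
                      buffer_min=shifted_buffer_min, **common)
    return [pos, neg]


def build_default_protocol(config: ProtocolConfig) -> ScanProtocol:
    """Expand a validation request into the full ordered scan protocol.

    Ordering is deterministic: depth scans first, then inline, crossline
    and diagonal profiles, each sorted by field size then depth.  With the
    default request this yields 75 segments.
    """
    if not config.field_sizes_cm or not config.axes:
        raise ProtocolError("empty validation request")
    max_depth = max(
        [config.depth_scan_range_cm if "depth" in config.axes else 0.0]
        + ([max(config.profile_depths_cm)] if config.profile_depths_cm and
           any(a in config.axes for a in LATERAL_AXES) else [])
    )
    if max_depth > config.tank_depth_cm:
        raise ProtocolError(
            f"requested depth {max_depth:g} cm exceeds the {config.tank_depth_cm:g} cm tank"
        )

    segments: list[ScanSegment] = []
    sizes = sorted(config.field_sizes_cm)
    depths = sorted(config.profile_depths_cm)

    if "depth" in config.axes:
        ax = config.axis_config("depth")
        for fs in sizes:
            segments.append(ScanSegment(
                axis="depth", field_size=FieldSize.square(fs), depth_cm=None,
                window_start_cm=config.depth_scan_range_cm, window_end_cm=0.0,
                speed_cm_s=ax.speed_cm_s, sampling_interval_s=ax.sampling_interval_s,
                buffer_min=ax.buffer_min,
            ))

    for axis in ("inline", "crossline", "diagonal"):
        if axis not in config.axes:
            continue
        ax = config.axis_config(axis)
        axis_sizes = sorted(config.diagonal_field_sizes_cm) if axis == "diagonal" else sizes
        for fs in axis_sizes:
            for d in depths:
                segments.extend(plan_lateral_scan(
                    FieldSize.square(fs), d, axis,
                    range_limit_cm=ax.range_limit_cm, offset_cm=ax.offset_cm,
                    overlap_cm=config.overlap_cm, margin_cm=ax.margin_cm,
                    speed_cm_s=ax.speed_cm_s,
                    sampling_interval_s=ax.sampling_interval_s,
                    ssd_cm=config.ssd_cm, sad_cm=config.sad_cm,
                    buffer_min=ax.buffer_min, shifted_buffer_min=ax.shifted_buffer_min,
                ))

    return ScanProtocol(segments=tuple(segments), ssd_cm=config.ssd_cm,
                        sad_cm=config.sad_cm)


# ---------------------------------------------------------------------------
# timing


def scan_time_min(length_cm: float, speed_cm_s: float) -> float:
    """Scan duration in minutes (|window| / speed / 60)."""
    if speed_cm_s <= 0:
        raise ValueError("speed must be positive")
    return length_cm / speed_cm_s / 60.0


def estimate_scan_time(segment: ScanSegment) -> float:
    """Duration of one segment in minutes, excluding the settling buffer."""
    return scan_time_min(segment.length_cm, segment.speed_cm_s)


def protocol_time_summary(protocol: ScanProtocol,
                          config: ProtocolConfig | None = None):
    """Per-row scan-time table plus totals.

    Rows mirror the published accounting: one row per (scan type, field
    size) -- all depth scans share one "ALL" row -- with the per-scan time,
    the between-scan buffer, the number of scans and the row total
    (time-per-scan x number of scans; buffers are tallied separately).
    Returns ``(DataFrame, totals_dict)``.
    """
    rows = []
    order = {"depth": 0, "inline": 1, "crossline": 2, "diagonal": 3}
    grouped: dict[tuple, list[ScanSegment]] = {}
    for seg in protocol.segments:
        key = (order[seg.axis], seg.axis,
               "ALL" if seg.axis == "depth" else seg.field_size.label())
        grouped.setdefault(key, []).append(seg)
    for (_, axis, fs_label), segs in sorted(grouped.items(), key=lambda kv: (
            kv[0][0], 0 if kv[0][2] == "ALL" else FieldSize.from_label(kv[0][2]).x_cm)):
        times = [estimate_scan_time(s) for s in segs]
        rows.append({
            "scan_type": axis,
            "scan_length_cm": round(float(np.mean([s.length_cm for s in segs])), 2),
            "scan_speed_cm_s": round(segs[0].speed_cm_s, 4),
            "buffer_min": segs[0].buffer_min,
            "field_size": fs_label,
            "time_per_scan_min": round(float(np.mean(times)), 2),
            "n_scans": len(segs),
            "total_min": round(float(np.sum(times)), 2),
        })
    df = pd.DataFrame(rows)
    scanning = float(df["total_min"].sum()) if rows else 0.0
    setup = config.setup_min if config else 0.0
    takedown = config.takedown_min if config else 0.0
    totals = {
        "scanning_min": round(scanning, 2),
        "buffer_min": round(float(sum(s.buffer_min for s in protocol.segments)), 2),
        "setup_min": setup,
        "takedown_min": takedown,
        "overall_min": round(scanning + setup + takedown, 2),
    }
    return df, totals


# ---------------------------------------------------------------------------
# delivery schedules


@dataclass(frozen=True, eq=False)
class DeliverySchedule:
    """Couch-position-vs-time waypoints for one scan segment.

    The machine-facing artifact: strictly increasing times, one waypoint
    per second plus the endpoints, constant implied speed equal to the
    segment's scan speed, beam on throughout the traversal.
    """

    segment: ScanSegment
    times_s: np.ndarray
    couch_x_cm: np.ndarray
    couch_y_cm: np.ndarray
    couch_z_cm: np.ndarray
    beam_on: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        for name in ("couch_x_cm", "couch_y_cm", "couch_z_cm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "beam_on", np.asarray(self.beam_on, dtype=bool))
        if not np.all(np.diff(t) > 0):
            raise ValueError("waypoint times must be strictly increasing")

    def __eq__(self, other) -> bool:
        if not isinstance(other, DeliverySchedule):
            return NotImplemented
        return self.segment == other.segment and all(
            np.array_equal(getattr(self, n), getattr(other, n))
            for n in ("times_s", "couch_x_cm", "couch_y_cm", "couch_z_cm", "beam_on")
        )

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1])

    # -- XML -------------------------------------------------------------
    def _body_element(self) -> ET.Element:
        seg = self.segment
        root = ET.Element("DeliverySchedule", version="1.0")
        attrs = {
            "axis": seg.axis,
            "field_x_cm": repr(float(seg.field_size.x_cm)),
            "field_y_cm": repr(float(seg.field_size.y_cm)),
            "depth_cm": "-" if seg.depth_cm is None else repr(float(seg.depth_cm)),
            "window_start_cm": repr(float(seg.window_start_cm)),
            "window_end_cm": repr(float(seg.window_end_cm)),
            "speed_cm_s": repr(float(seg.speed_cm_s)),
            "sampling_interval_s": repr(float(seg.sampling_interval_s)),
            "tank_offset_cm": repr(float(seg.tank_offset_cm)),
            "buffer_min": repr(float(seg.buffer_min)),
        }
        ET.SubElement(root, "Segment", attrs)
        wps = ET.SubElement(root, "Waypoints")
        for t, x, y, z, on in zip(self.times_s, self.couch_x_cm, self.couch_y_cm,
                                  self.couch_z_cm, self.beam_on):
            ET.SubElement(wps, "Waypoint", {
                "time_s": repr(float(t)), "couch_x_cm": repr(float(x)),
                "couch_y_cm": repr(float(y)), "couch_z_cm": repr(float(z)),
                "beam_on": "true" if on else "false",
            })
        return root

    @property
    def checksum(self) -> str:
        """SHA-256 hex digest of the canonical schedule body."""
        body = ET.tostring(self._body_element(), encoding="utf-8")
        return hashlib.sha256(body).hexdigest()

    def to_xml_bytes(self) -> bytes:
        root = self._body_element()
        root.set("checksum", self.checksum)
        return ET.tostring(root, encoding="utf-8", xml_declaration=True)

    def write(self, path: str | Path) -> str:
        """Write the XML file; returns the recorded checksum."""
        Path(path).write_bytes(self.to_xml_bytes())
        return self.checksum


def schedule_from_xml(source: bytes | str | Path) -> DeliverySchedule:
    """Parse a schedule XML file (bytes, XML text, or path)."""
    if isinstance(source, bytes):
        text = source.decode("utf-8")
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        text = source
    else:
        text = Path(source).read_text()
    root = ET.fromstring(text)
    seg_el = root.find("Segment")
    if seg_el is None:
        raise ValueError("schedule XML missing Segment element")
    a = seg_el.attrib
    seg = ScanSegment(
        axis=a["axis"],
        field_size=FieldSize(float(a["field_x_cm"]), float(a["field_y_cm"])),
        depth_cm=None if a["depth_cm"] == "-" else float(a["depth_cm"]),
        window_start_cm=float(a["window_start_cm"]),
        window_end_cm=float(a["window_end_cm"]),
        speed_cm_s=float(a["speed_cm_s"]),
        sampling_interval_s=float(a["sampling_interval_s"]),
        tank_offset_cm=float(a["tank_offset_cm"]),
        buffer_min=float(a["buffer_min"]),
    )
    wps = root.find("Waypoints")
    rows = [(float(w.get("time_s")), float(w.get("couch_x_cm")),
             float(w.get("couch_y_cm")), float(w.get("couch_z_cm")),
             w.get("beam_on") == "true") for w in wps]
    t, x, y, z, on = (np.asarray(col) for col in zip(*rows))
    return DeliverySchedule(segment=seg, times_s=t, couch_x_cm=x,
                            couch_y_cm=y, couch_z_cm=z, beam_on=on)


def verify_schedule_checksum(source: bytes | str | Path) -> bool:
    """True iff the stored checksum matches the schedule body."""
    if isinstance(source, bytes):
        text = source.decode("utf-8")
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        text = source
    else:
        text = Path(source).read_text()
    stored = ET.fromstring(text).get("checksum")
    return stored is not None and stored == schedule_from_xml(text).checksum


def emit_delivery_schedule(segment: ScanSegment,
                           waypoint_cadence_s: float = 1.0) -> DeliverySchedule:
    """Turn a segment into a couch trajectory.

    Waypoints are emitted at a fixed cadence plus the exact endpoint; couch
    motion is linear from window start to window end at the segment speed.
    The couch coordinate is the scan coordinate minus the tank offset (the
    offset platform carries the detector the rest of the way); diagonal
    scans split the along-path coordinate equally between couch x and y.
    """
    seg = segment
    total = seg.duration_s
    t = np.arange(0.0, total, waypoint_cadence_s)
    if total - t[-1] > 1e-9:
        t = np.append(t, total)
    direction = 1.0 if seg.window_end_cm > seg.window_start_cm else -1.0
    pos = seg.window_start_cm + direction * seg.speed_cm_s * t
    pos[-1] = seg.window_end_cm  # exact endpoint
    couch_path = pos - seg.tank_offset_cm
    zeros = np.zeros_like(t)
    if seg.axis == "crossline":
        x, y, z = couch_path, zeros, np.full_like(t, seg.depth_cm)
    elif seg.axis == "inline":
        x, y, z = zeros, couch_path, np.full_like(t, seg.depth_cm)
    elif seg.axis == "diagonal":
        comp = couch_path / math.sqrt(2.0)
        x, y, z = comp, comp, np.full_like(t, seg.depth_cm)
    elif seg.axis == "depth":
        x, y, z = zeros, zeros, pos
    else:  # pragma: no cover - guarded by ScanSegment
        raise ValueError(f"unknown axis {seg.axis!r}")
    return DeliverySchedule(segment=seg, times_s=t, couch_x_cm=x, couch_y_cm=y,
                            couch_z_cm=z, beam_on=np.ones_like(t, dtype=bool))


# ---------------------------------------------------------------------------
# setup imaging


def imaging_gantry_angle(ssd_cm: float, sad_cm: float = 100.0) -> float:
    """Gantry angle (degrees) for a crisp MV image of the water surface.

    The water surface sits (sad - ssd) below isocenter; imaging tangent to
    it requires 90 degrees minus the arctangent of that depth over the SAD.
    At 100 cm SSD this is 90.0; at 90 cm SSD, 84.3.
    """
    if ssd_cm <= 0:
        raise ValueError("SSD must be positive")
    if ssd_cm > sad_cm:
        raise ValueError("SSD above the SAD puts the isocenter outside the water")
    return 90.0 - math.degrees(math.atan((sad_cm - ssd_cm) / sad_cm))
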