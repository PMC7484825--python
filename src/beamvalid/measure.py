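"""Measurement side of the loop: simulate scans and rebuild profiles.

simulate_scan drives the beam model with a delivery schedule and produces
the electrometer time series (field and reference chamber currents);
reconstruct_profile inverts it, mapping sample times back to detector
positions through the couch trajectory.  stitch_scans merges the two
halves of a bore-limited split scan over their overlap, and
center_profile / normalize_profile apply the only post-processing used on
measured data: centering lateral profiles on the midpoint of their 50%
crossings, normalizing laterals to the mean of the three central samples
and depth curves to their maximum.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .beam import MAX_DEPTH_CM, BeamModelParams, box_averaged_dose
from .curves import Curve
from .protocol import DeliverySchedule, ScanSegment, schedule_from_xml
from .tps import diagonal_positions

__all__ = [
    "NoiseModel",
    "ChamberModel",
    "ElectrometerLog",
    "simulate_scan",
    "reconstruct_profile",
    "stitch_scans",
    "center_profile",
    "normalize_profile",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative detector noise and electrometer drift.

    sigma_rel / ref_sigma_rel: relative Gaussian noise std of the field and
    reference channels; drift_per_min: linear relative drift of the field
    electrometer (machine output fluctuation is common to both channels
    and cancels in the ratio, so it is not modelled separately).
    """

    sigma_rel: float = 0.002
    ref_sigma_rel: float = 0.0
    drift_per_min: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or self.ref_sigma_rel < 0:
            raise ValueError("noise fractions must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ChamberModel:
    """Scanning-chamber response model.

    size_cm: edge of the cubic sensitive volume used for volume averaging
    (matched to the TPS reference voxel that emulates the same 0.13 cc
    chamber).  epom_shift_cm: effective-point-of-measurement shift of a
    cylindrical chamber, 0.6 x the 3 mm cavity radius = 1.8 mm, applied
    upstream (toward the surface) on depth scans only.  The current scales
    are arbitrary electrometer units; only the field/reference ratio
    matters downstream.
    """

    size_cm: float = 0.5
    epom_shift_cm: float = 0.18
    field_current_nA: float = 20.0
    ref_current_nA: float = 12.0
    leakage_nA: float = 0.002


def _sample_times(segment: ScanSegment) -> np.ndarray:
    dt = segment.sampling_interval_s
    n = int(math.floor(segment.duration_s / dt + 1e-9))
    return dt * np.arange(n + 1)


def _detector_coords(schedule: DeliverySchedule, times: np.ndarray):
    """Detector isocenter-frame (x, y, z) at the sample times."""
    seg = schedule.segment
    t = schedule.times_s
    if np.any(times < t[0] - 1e-9) or np.any(times > t[-1] + 1e-9):
        raise ValueError("sample time outside the schedule span")
    cx = np.interp(times, t, schedule.couch_x_cm)
    cy = np.interp(times, t, schedule.couch_y_cm)
    cz = np.interp(times, t, schedule.couch_z_cm)
    if seg.axis == "crossline":
        return cx + seg.tank_offset_cm, cy, cz
    if seg.axis == "inline":
        return cx, cy + seg.tank_offset_cm, cz
    if seg.axis == "diagonal":
        comp = seg.tank_offset_cm / math.sqrt(2.0)
        return cx + comp, cy + comp, cz
    return cx, cy, cz  # depth: z is the scan coordinate


def simulate_scan(schedule: DeliverySchedule, beam: BeamModelParams,
                  noise: NoiseModel, chamber: ChamberModel | None = None,
                  seed: int = 0) -> "ElectrometerLog":
    """Synthesize the electrometer log for one scheduled scan.

    The field reading is the chamber-volume-averaged model dose at the
    detector position (for depth scans, evaluated at the effective point
    of measurement, ``epom_shift_cm`` upstream of the chamber centre)
    scaled to a nominal current, with multiplicative Gaussian noise and
    optional drift; the reference reading is a constant current with its
    own noise.  Deterministic given ``seed``.
    """
    chamber = chamber or ChamberModel()
    seg = schedule.segment
    times = _sample_times(seg)
    x, y, z = _detector_coords(schedule, times)
    if seg.axis == "depth":
        z = np.clip(z - chamber.epom_shift_cm, 0.0, MAX_DEPTH_CM)
        depth = z
    else:
        depth = np.full_like(times, seg.depth_cm)
    dose = box_averaged_dose(x, y, depth, seg.field_size, beam,
                             edge_cm=chamber.size_cm)
    rng = np.random.default_rng(seed)
    drift = 1.0 + noise.drift_per_min * times / 60.0
    field = chamber.field_current_nA * np.asarray(dose) * drift
    field = field * (1.0 + noise.sigma_rel * rng.standard_normal(times.size))
    field = field + chamber.leakage_nA  # electrometer offset keeps readings > 0
    ref = chamber.ref_current_nA * (
        1.0 + noise.ref_sigma_rel * rng.standard_normal(times.size))
    return ElectrometerLog(times_s=times, field_nA=field, ref_nA=ref,
                           segment=seg, seed=seed)


@dataclass(frozen=True, eq=False)
class ElectrometerLog:
    """Timestamped field/reference chamber readings from one scan."""

    times_s: np.ndarray
    field_nA: np.ndarray
    ref_nA: np.ndarray
    segment: ScanSegment
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        f = np.asarray(self.field_nA, dtype=float)
        r = np.asarray(self.ref_nA, dtype=float)
        for name, arr in (("times_s", t), ("field_nA", f), ("ref_nA", r)):
            object.__setattr__(self, name, arr)
        if not (t.shape == f.shape == r.shape):
            raise ValueError("log columns must have equal length")
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, self.segment.sampling_interval_s,
                                          atol=1e-9, rtol=0):
            raise ValueError("sample spacing must equal the sampling interval")
        if np.any(f <= 0) or np.any(r <= 0):
            raise ValueError("chamber readings must be positive")

    def to_csv(self, path: str | Path | None = None) -> str:
        seg = self.segment
        buf = io.StringIO()
        buf.write(f"# axis: {seg.axis}\n")
        buf.write(f"# field_size_cm: {seg.field_size.label()}\n")
        depth = "-" if seg.depth_cm is None else f"{seg.depth_cm:g}"
        buf.write(f"# depth_cm: {depth}\n")
        buf.write(f"# window_start_cm: {seg.window_start_cm!r}\n")
        buf.write(f"# window_end_cm: {seg.window_end_cm!r}\n")
        buf.write(f"# speed_cm_s: {seg.speed_cm_s!r}\n")
        buf.write(f"# sampling_interval_s: {seg.sampling_interval_s!r}\n")
        buf.write(f"# tank_offset_cm: {seg.tank_offset_cm!r}\n")
        buf.write(f"# buffer_min: {seg.buffer_min!r}\n")
        buf.write(f"# seed: {self.seed}\n")
        buf.write("time_s,field_nA,ref_nA\n")
        for t, f, r in zip(self.times_s, self.field_nA, self.ref_nA):
            buf.write(f"{float(t)!r},{float(f)!r},{float(r)!r}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "ElectrometerLog":
        from .beam import FieldSize

        text = source if isinstance(source, str) and "\n" in source else Path(source).read_text()
        meta: dict[str, str] = {}
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition(":")
                meta[k.strip()] = v.strip()
            elif not line.startswith("time_s"):
                rows.append([float(tok) for tok in line.split(",")])
        t, f, r = (np.asarray(col) for col in zip(*rows))
        seg = ScanSegment(
            axis=meta["axis"],
            field_size=FieldSize.from_label(meta["field_size_cm"]),
            depth_cm=None if meta["depth_cm"] == "-" else float(meta["depth_cm"]),
            window_start_cm=float(meta["window_start_cm"]),
            window_end_cm=float(meta["window_end_cm"]),
            speed_cm_s=float(meta["speed_cm_s"]),
            sampling_interval_s=float(meta["sampling_interval_s"]),
            tank_offset_cm=float(meta["tank_offset_cm"]),
            buffer_min=float(meta["buffer_min"]),
        )
        return cls(times_s=t, field_nA=f, ref_nA=r, segment=seg,
                   seed=int(meta.get("seed", 0)))


def reconstruct_profile(log: ElectrometerLog, schedule: DeliverySchedule,
                        chamber: ChamberModel | None = None) -> Curve:
    """Rebuild the spatial profile from a log and its couch trajectory.

    Sample positions are interpolated from the waypoints at the sample
    times and offset by the tank platform; diagonal couch coordinates are
    folded into signed radial positions; depth-scan positions are shifted
    by the EPOM offset toward the surface.  The value is the
    field/reference current ratio, and the output is sorted by position.
    """
    chamber = chamber or ChamberModel()
    seg = log.segment
    if seg != schedule.segment:
        raise ValueError("log and schedule come from different segments")
    x, y, z = _detector_coords(schedule, log.times_s)
    if seg.axis == "crossline":
        pos = x
    elif seg.axis == "inline":
        pos = y
    elif seg.axis == "diagonal":
        pos = np.asarray(diagonal_positions(x, y, tol=1e-6))
    else:
        pos = z - chamber.epom_shift_cm
    ratio = log.field_nA / log.ref_nA
    order = np.argsort(pos, kind="stable")
    pos, ratio = pos[order], ratio[order]
    # merge numerically coincident positions (e.g. stationary endpoints)
    keep = np.concatenate([[True], np.diff(pos) > 1e-9])
    return Curve(axis=seg.axis,
                 depth_cm=None if seg.axis == "depth" else seg.depth_cm,
                 field_size=seg.field_size, positions=pos[keep],
                 values=ratio[keep], provenance="measured")


def stitch_scans(a: Curve, b: Curve, overlap_cm: float = 1.0) -> Curve:
    """Merge the two halves of a split scan over their overlap.

    The right-hand curve is rescaled by the mean left/right ratio over the
    overlap, then the two are blended with a linear cross-fade across it.
    The inputs must share axis, depth and field size and overlap by at
    least ``overlap_cm``.
    """
    if a.key != b.key or a.provenance != b.provenance:
        raise ValueError("curves to stitch have inconsistent metadata")
    left, right = (a, b) if a.lo <= b.lo else (b, a)
    ov_lo, ov_hi = right.lo, left.hi
    if ov_hi - ov_lo < overlap_cm - 1e-9:
        raise ValueError(
            f"scan overlap {max(ov_hi - ov_lo, 0):.3f} cm is below the "
            f"required {overlap_cm:g} cm"
        )
    pos = np.unique(np.concatenate([left.positions, right.positions]))
    keep = np.concatenate([[True], np.diff(pos) > 1e-9])
    pos = pos[keep]
    in_ov = (pos >= ov_lo) & (pos <= ov_hi)
    ratio = float(np.mean(left.interp(pos[in_ov]) / right.interp(pos[in_ov])))
    rv = right.values * ratio

    vals = np.empty_like(pos)
    left_side = pos < ov_lo
    right_side = pos > ov_hi
    vals[left_side] = left.interp(pos[left_side])
    vals[right_side] = np.interp(pos[right_side], right.positions, rv)
    w = (pos[in_ov] - ov_lo) / (ov_hi - ov_lo)
    vals[in_ov] = ((1.0 - w) * left.interp(pos[in_ov])
                   + w * np.interp(pos[in_ov], right.positions, rv))
    return Curve(axis=a.axis, depth_cm=a.depth_cm, field_size=a.field_size,
                 positions=pos, values=vals, provenance=a.provenance)


def center_profile(c: Curve) -> tuple[Curve, float]:
    """Center a lateral profile on the midpoint of its 50% crossings.

    The 50% level is half the value at position 0; the left and right edge
    positions are found by linear interpolation at the outermost crossings
    and the profile is translated so their midpoint sits at 0.  Returns
    ``(centered_curve, shift_cm)`` where the shift is the detected offset.
    """
    p, v = c.positions, c.values
    half = 0.5 * float(np.interp(0.0, p, v))
    s = v - half
    idx = np.flatnonzero(s[:-1] * s[1:] <= 0)
    idx = idx[np.abs(s[idx]) + np.abs(s[idx + 1]) > 0]
    if idx.size < 2:
        raise ValueError("profile does not cross its 50% level on both sides")

    def crossing(i: int) -> float:
        return p[i] + (p[i + 1] - p[i]) * s[i] / (s[i] - s[i + 1])

    left_x = crossing(idx[0])
    right_x = crossing(idx[-1])
    shift = 0.5 * (left_x + right_x)
    return c.with_positions(p - shift), shift


def normalize_profile(c: Curve, kind: str | None = None) -> Curve:
    """Express a curve in percent.

    Lateral profiles divide by the mean of the three samples nearest the
    axis, depth curves by their maximum; both then multiply by 100, so the
    operation is idempotent.  ``kind`` ("cax3" or "max") defaults by axis.
    """
    if kind is None:
        kind = "max" if c.axis == "depth" else "cax3"
    if kind == "max":
        norm = float(np.max(c.values))
    elif kind == "cax3":
        if c.positions.size < 3:
            raise ValueError("need at least three samples for CAX normalization")
        nearest = np.argsort(np.abs(c.positions), kind="stable")[:3]
        norm = float(np.mean(c.values[nearest]))
    else:
        raise ValueError(f"unknown normalization {kind!r}")
    if norm <= 0:
        raise ValueError("normalization value must be positive")
    return c.with_values(c.values / norm * 100.0)
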