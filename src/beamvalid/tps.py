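"""TPS-side curve extraction: region-dependent sampling of the beam model.

The treatment planning system is emulated by evaluating the analytic beam
model at virtual couch positions: dose to a 0.5 cm reference voxel on a
grid whose spacing depends on the profile region (5 mm in-field and in the
umbra, 1 mm through the penumbra and the 5 mm transition bands flanking
it).  Because the planning model is radially symmetric, half profiles are
sampled and mirrored; depth curves are extracted on the central axis from
0 to 30 cm at 5 mm spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .beam import (
    MAX_DEPTH_CM,
    BeamModelParams,
    FieldSize,
    box_averaged_dose,
    dose_at,
)
from .curves import Curve

__all__ = [
    "SpacingRule",
    "build_sampling_grid",
    "sample_half_profile",
    "mirror_half_profile",
    "reference_voxel_dose",
    "sample_depth_curve",
    "sample_lateral_curve",
    "diagonal_positions",
    "penumbra_bounds",
]


@dataclass(frozen=True)
class SpacingRule:
    """Region-dependent sampling spacings, in mm."""

    infield_mm: float = 5.0
    penumbra_mm: float = 1.0
    umbra_mm: float = 5.0
    transition_band_mm: float = 5.0
    #: The finely sampled band additionally extends this many penumbra
    #: sigmas beyond the 80%/20% bounds, so the shoulder and foot of the
    #: erf edge -- which keep significant curvature well past the nominal
    #: penumbra -- are captured at all depths.
    edge_extension_sigmas: float = 2.2

    def __post_init__(self) -> None:
        for name in ("infield_mm", "penumbra_mm", "umbra_mm", "transition_band_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.penumbra_mm > self.infield_mm:
            raise ValueError("penumbra spacing must not exceed in-field spacing")
        if self.edge_extension_sigmas < 0:
            raise ValueError("edge_extension_sigmas must be >= 0")


def _axis_point(positions, axis: str):
    """Map along-axis positions to (x, y) model coordinates."""
    p = np.asarray(positions, dtype=float)
    if axis == "crossline":
        return p, np.zeros_like(p)
    if axis == "inline":
        return np.zeros_like(p), p
    if axis == "diagonal":
        comp = p / math.sqrt(2.0)
        return comp, comp
    raise ValueError(f"not a lateral axis: {axis!r}")


def axis_dose(beam: BeamModelParams, positions, depth_cm: float,
              field_size: FieldSize, axis: str):
    """Point dose of the model along a lateral scan axis."""
    x, y = _axis_point(positions, axis)
    return dose_at(x, y, depth_cm, field_size, beam)


def penumbra_bounds(beam: BeamModelParams, field_size: FieldSize,
                    depth_cm: float, axis: str = "crossline",
                    levels=(0.8, 0.2)) -> tuple[float, float]:
    """Positive-axis positions where the profile crosses the given
    fractions of its central-axis value (default the 80% and 20% levels
    bounding the penumbra)."""
    cax = float(axis_dose(beam, 0.0, depth_cm, field_size, axis))

    def rel(p):
        return float(axis_dose(beam, p, depth_cm, field_size, axis)) / cax

    out = []
    for level in levels:
        f = lambda p, lv=level: rel(p) - lv
        # bracket outward from the projected edge
        edge = beam.edge_cm(depth_cm, field_size.x_cm)
        if axis == "diagonal":
            edge *= math.sqrt(2.0)
        lo, hi = 0.0, min(edge + 6.0 * float(beam.sigma_cm(depth_cm)), 24.9)
        if axis == "diagonal":
            hi = min(hi, 24.9)
        out.append(brentq(f, lo, hi, xtol=1e-10))
    return tuple(out)


def _walk(lo: float, hi: float, step: float) -> np.ndarray:
    """Positions lo, lo+step, ... capped with an exact hi endpoint."""
    n = int(math.floor((hi - lo) / step + 1e-9))
    pts = lo + step * np.arange(n + 1)
    if hi - pts[-1] > 1e-9:
        pts = np.append(pts, hi)
    else:
        pts[-1] = hi
    return pts


def build_sampling_grid(beam: BeamModelParams, field_size: FieldSize,
                        depth_cm: float, rule: SpacingRule, window_cm: float,
                        axis: str = "crossline") -> np.ndarray:
    """Half-axis sampling grid from 0 out to ``window_cm``.

    In-field spacing out to the start of the fine band, 1 mm spacing
    through the penumbra and the transition bands flanking it, umbra
    spacing out to the window edge.  The fine band runs from the 80% bound
    to the 20% bound extended on each side by the transition band plus
    ``edge_extension_sigmas`` penumbra widths, scaling with the erf-edge
    blur at depth.  The grid always contains 0, both region boundaries
    and the window edge.
    """
    if window_cm <= 0:
        raise ValueError("window must be positive")
    x80, x20 = penumbra_bounds(beam, field_size, depth_cm, axis)
    if window_cm < x20:
        raise ValueError(
            f"window {window_cm:g} cm does not cover the field edge "
            f"(20% point at {x20:.2f} cm)"
        )
    sig = float(beam.sigma_cm(depth_cm))
    if axis == "diagonal":
        sig *= math.sqrt(2.0)
    band = rule.transition_band_mm / 10.0 + rule.edge_extension_sigmas * sig
    a = max(x80 - band, 0.0)
    b = min(x20 + band, window_cm)
    parts = []
    if a > 0:
        parts.append(_walk(0.0, a, rule.infield_mm / 10.0))
    parts.append(_walk(a, b, rule.penumbra_mm / 10.0))
    if window_cm - b > 1e-9:
        parts.append(_walk(b, window_cm, rule.umbra_mm / 10.0))
    grid = np.concatenate(parts)
    # drop duplicated region boundaries
    keep = np.concatenate([[True], np.diff(grid) > 1e-9])
    return grid[keep]


def reference_voxel_dose(beam: BeamModelParams, center_x_cm, center_y_cm,
                         depth_cm, field_size: FieldSize,
                         voxel_cm: float = 0.5):
    """Mean model dose over the cubic reference voxel.

    Emulates the planning system's dose scoring to a 0.5 cm reference
    voxel standing in for the 0.13 cc field chamber.  The voxel is clamped
    to the water column in depth (partial volume at the surface) and must
    lie inside the lateral model range.
    """
    return box_averaged_dose(center_x_cm, center_y_cm, depth_cm, field_size,
                             beam, edge_cm=voxel_cm)


def sample_half_profile(beam: BeamModelParams, field_size: FieldSize,
                        depth_cm: float, grid: np.ndarray,
                        axis: str = "crossline",
                        voxel_cm: float = 0.5) -> Curve:
    """Voxel-dose samples along a half axis (grid must start at 0)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or abs(grid[0]) > 1e-12:
        raise ValueError("half-profile grid must start at 0")
    x, y = _axis_point(grid, axis)
    values = reference_voxel_dose(beam, x, y, depth_cm, field_size, voxel_cm)
    return Curve(axis=axis, depth_cm=depth_cm, field_size=field_size,
                 positions=grid, values=np.asarray(values), provenance="tps")


def mirror_half_profile(half: Curve) -> Curve:
    """Reflect a half profile about 0 into an exactly even full profile."""
    p = half.positions
    if abs(p[0]) > 1e-12:
        raise ValueError("half profile must start at 0")
    pos = np.concatenate([-p[:0:-1], p])
    val = np.concatenate([half.values[:0:-1], half.values])
    return Curve(axis=half.axis, depth_cm=half.depth_cm,
                 field_size=half.field_size, positions=pos, values=val,
                 provenance=half.provenance)


def sample_lateral_curve(beam: BeamModelParams, field_size: FieldSize,
                         depth_cm: float, window_cm: float,
                         rule: SpacingRule | None = None,
                         axis: str = "crossline",
                         voxel_cm: float = 0.5) -> Curve:
    """Convenience: grid -> half profile -> mirrored full TPS curve."""
    rule = rule or SpacingRule()
    grid = build_sampling_grid(beam, field_size, depth_cm, rule, window_cm, axis)
    return mirror_half_profile(
        sample_half_profile(beam, field_size, depth_cm, grid, axis, voxel_cm))


def sample_depth_curve(beam: BeamModelParams, field_size: FieldSize,
                       spacing_mm: float = 5.0,
                       voxel_cm: float = 0.5) -> Curve:
    """Central-axis depth curve, 0 to 30 cm (61 points at 5 mm spacing)."""
    depths = _walk(0.0, MAX_DEPTH_CM, spacing_mm / 10.0)
    values = reference_voxel_dose(beam, np.zeros_like(depths),
                                  np.zeros_like(depths), depths, field_size,
                                  voxel_cm)
    return Curve(axis="depth", depth_cm=None, field_size=field_size,
                 positions=depths, values=np.asarray(values), provenance="tps")


def diagonal_positions(x_cm, y_cm, tol: float = 1e-6) -> np.ndarray:
    """Signed radial coordinates for collinear-through-origin (x, y) pairs.

    r_i = sign(x_i) * sqrt(x_i^2 + y_i^2) (sign of y where x is zero).
    Raises if the points are not collinear through the origin.
    """
    scalar = np.ndim(x_cm) == 0 and np.ndim(y_cm) == 0
    x = np.atleast_1d(np.asarray(x_cm, dtype=float))
    y = np.atleast_1d(np.asarray(y_cm, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    scale = max(np.max(np.abs(x), initial=0.0), np.max(np.abs(y), initial=0.0), 1.0)
    nz = np.flatnonzero((np.abs(x) > tol * scale) | (np.abs(y) > tol * scale))
    if nz.size:
        x0, y0 = x[nz[0]], y[nz[0]]
        cross = x * y0 - y * x0
        if np.any(np.abs(cross) > tol * scale * math.hypot(x0, y0)):
            raise ValueError("points are not collinear through the origin")
    sign = np.where(x != 0, np.sign(x), np.sign(y))
    r = sign * np.hypot(x, y)
    return float(r[0]) if scalar else r
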