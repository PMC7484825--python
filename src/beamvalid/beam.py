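"""Analytic 6 MV FFF beam model.

This module provides the shared ground truth from which both sides of the
validation loop are derived: the "TPS prediction" samples it through a
reference voxel, and the simulated 1D-tank measurement samples it through a
scanning chamber.  It is a deliberately simple, radially symmetric model of
an unflattened (FFF) beam:

* central-axis depth dose: exponential build-up times exponential
  attenuation, with an effective attenuation coefficient that decreases
  linearly with equivalent-square field size (more phantom scatter for
  larger fields, so depth dose increases monotonically with field size);
* lateral profiles: error-function field edges at the divergence-projected
  edge position, with a Gaussian penumbra width that grows linearly with
  depth, modulated by the quadratic "cone" falloff characteristic of FFF
  beams;
* 2D dose: separable product of the two lateral axes times the depth dose,
  normalized on the central axis.

The defaults give d_max near 1.3 cm, PDD(10 cm) for a 10x10 field around
0.65, and a cone falloff of ~8% at the field edge of a 28x28 field --
plausible magnitudes for a jawless 6 MV FFF machine, not a fit to any
particular linac.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import erf

__all__ = [
    "FieldSize",
    "BeamModelParams",
    "pdd",
    "lateral_dose",
    "dose_at",
    "box_averaged_dose",
]

#: Depth range (cm) over which the model is defined.
MAX_DEPTH_CM = 30.0
#: Lateral half-range (cm) over which the model is defined.
MAX_OFFAXIS_CM = 25.0
#: Largest collimated field side (cm) of the modelled machine.
MAX_FIELD_CM = 28.0


@dataclass(frozen=True)
class FieldSize:
    """Collimated field size at the isocenter plane, in cm."""

    x_cm: float
    y_cm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_cm", float(self.x_cm))
        object.__setattr__(self, "y_cm", float(self.y_cm))
        for side in (self.x_cm, self.y_cm):
            if not 0 < side <= MAX_FIELD_CM:
                raise ValueError(
                    f"field side {side} cm outside (0, {MAX_FIELD_CM}] cm machine limit"
                )

    @classmethod
    def square(cls, side_cm: float) -> "FieldSize":
        return cls(side_cm, side_cm)

    @property
    def equivalent_square_cm(self) -> float:
        """Sterling equivalent-square side 2xy/(x+y)."""
        return 2.0 * self.x_cm * self.y_cm / (self.x_cm + self.y_cm)

    @property
    def is_square(self) -> bool:
        return self.x_cm == self.y_cm

    def label(self) -> str:
        fmt = lambda v: f"{v:g}"
        return f"{fmt(self.x_cm)}x{fmt(self.y_cm)}"

    @classmethod
    def from_label(cls, text: str) -> "FieldSize":
        x, _, y = text.partition("x")
        return cls(float(x), float(y))


@dataclass(frozen=True)
class BeamModelParams:
    """Parameters of the analytic FFF beam model.

    Attributes
    ----------
    mu_eff0:
        Effective attenuation coefficient for an infinitesimal field (1/cm).
    mu_fs_slope:
        Linear decrease of the effective attenuation per cm of
        equivalent-square side (1/cm per cm); encodes the field-size
        dependence of the depth dose.
    beta:
        Build-up rate (1/cm).
    d_max_cm:
        Depth of maximum dose for the 10x10 reference field (cm); the
        build-up depth offset is derived from it, so other field sizes peak
        within a fraction of a millimetre of this value.
    sigma0_cm, sigma_slope:
        Gaussian penumbra width at the surface (cm) and its growth per cm
        depth (erf-edge broadening with depth).
    cone_c:
        Fractional FFF cone falloff at the field edge (unitless).
    sad_cm, ssd_cm:
        Source-axis and source-surface distances (cm); edges are projected
        to depth d with the factor (ssd + d)/sad.
    output_scale:
        Uniform output multiplier (1 = nominal).  Used to inject
        calibration-type perturbations; note that purely relative profile
        comparisons are insensitive to it.
    edge_offset_cm:
        Additive shift of both field edges (cm); +0.2 moves each penumbra
        2 mm outward.  Used to inject geometric perturbations.
    """

    mu_eff0: float = 0.055
    mu_fs_slope: float = 0.0005
    beta: float = 2.45
    d_max_cm: float = 1.3
    sigma0_cm: float = 0.35
    sigma_slope: float = 0.025
    cone_c: float = 0.08
    sad_cm: float = 100.0
    ssd_cm: float = 90.0
    output_scale: float = 1.0
    edge_offset_cm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_eff0", "beta", "d_max_cm", "sigma0_cm", "cone_c", "sad_cm", "ssd_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_fs_slope < 0 or self.sigma_slope < 0:
            raise ValueError("mu_fs_slope and sigma_slope must be non-negative")
        if self.mu_eff(FieldSize.square(MAX_FIELD_CM)) <= 0:
            raise ValueError("mu_eff must stay positive up to the largest field")

    def mu_eff(self, field_size: FieldSize) -> float:
        """Effective attenuation coefficient (1/cm) for a field size."""
        return self.mu_eff0 - self.mu_fs_slope * field_size.equivalent_square_cm

    @property
    def buildup_offset_cm(self) -> float:
        """Depth offset of the build-up term, derived so the 10x10 field
        peaks exactly at ``d_max_cm`` (and gives a realistic nonzero
        surface dose)."""
        mu = self.mu_eff(FieldSize.square(10.0))
        return float(np.log((self.beta + mu) / mu) / self.beta - self.d_max_cm)

    def sigma_cm(self, depth_cm):
        """Penumbra Gaussian width (cm) at depth."""
        return self.sigma0_cm + self.sigma_slope * np.asarray(depth_cm, dtype=float)

    def d_peak_cm(self, field_size: FieldSize) -> float:
        """Analytic depth of maximum dose for this field size (cm)."""
        mu = self.mu_eff(field_size)
        d = np.log((self.beta + mu) / mu) / self.beta - self.buildup_offset_cm
        return float(max(d, 0.0))

    def edge_cm(self, depth_cm, side_cm: float):
        """Divergence-projected 50%-edge position at depth (cm)."""
        d = np.asarray(depth_cm, dtype=float)
        return (side_cm / 2.0) * (self.ssd_cm + d) / self.sad_cm + self.edge_offset_cm

    def with_perturbation(self, *, output_scale: float = 1.0,
                          edge_shift_cm: float = 0.0) -> "BeamModelParams":
        """A perturbed copy of the model (for discrimination studies)."""
        return replace(
            self,
            output_scale=self.output_scale * output_scale,
            edge_offset_cm=self.edge_offset_cm + edge_shift_cm,
        )


def _check_depth(depth_cm) -> np.ndarray:
    d = np.asarray(depth_cm, dtype=float)
    if np.any(d < 0) or np.any(d > MAX_DEPTH_CM):
        raise ValueError(f"depth outside [0, {MAX_DEPTH_CM}] cm")
    return d


def _check_offaxis(x_cm) -> np.ndarray:
    x = np.asarray(x_cm, dtype=float)
    if np.any(np.abs(x) > MAX_OFFAXIS_CM):
        raise ValueError(f"off-axis position outside +-{MAX_OFFAXIS_CM} cm")
    return x


def _pdd_raw(depth, field_size: FieldSize, params: BeamModelParams):
    mu = params.mu_eff(field_size)
    d0 = params.buildup_offset_cm
    return (1.0 - np.exp(-params.beta * (depth + d0))) * np.exp(-mu * depth)


def pdd(depth_cm, field_size: FieldSize, params: BeamModelParams):
    """Central-axis depth dose, normalized to 1 at its maximum.

    Returns ``output_scale`` times the normalized value, so a nominal model
    peaks at exactly 1.  Accepts scalars or arrays in [0, 30] cm.
    """
    d = _check_depth(depth_cm)
    peak = _pdd_raw(params.d_peak_cm(field_size), field_size, params)
    out = _pdd_raw(d, field_size, params) / peak * params.output_scale
    return out if out.ndim else float(out)


def _edge_profile(x, depth, side_cm: float, params: BeamModelParams):
    """Erf-edged, cone-modulated 1D lateral factor (un-normalized)."""
    e = params.edge_cm(depth, side_cm)
    s = params.sigma_cm(depth) * np.sqrt(2.0)
    edges = 0.5 * (erf((e - x) / s) + erf((e + x) / s))
    cone = 1.0 - params.cone_c * np.minimum((x / e) ** 2, 1.0)
    return edges * cone


def lateral_dose(x_cm, depth_cm, field_size: FieldSize, params: BeamModelParams,
                 axis_dim: str = "x"):
    """Off-axis dose factor at depth along one collimated axis.

    An even function of ``x_cm``, maximal at the axis, with 50% crossings at
    the divergence-projected field edge.  ``axis_dim`` selects which field
    side ("x" or "y") sets the edge.
    """
    x = _check_offaxis(x_cm)
    d = _check_depth(depth_cm)
    side = field_size.x_cm if axis_dim == "x" else field_size.y_cm
    out = _edge_profile(x, d, side, params)
    return out if out.ndim else float(out)


def _dose_at_unchecked(x, y, d, field_size: FieldSize, params: BeamModelParams):
    lx = _edge_profile(x, d, field_size.x_cm, params)
    ly = _edge_profile(y, d, field_size.y_cm, params)
    lx0 = _edge_profile(np.zeros_like(x), d, field_size.x_cm, params)
    ly0 = _edge_profile(np.zeros_like(y), d, field_size.y_cm, params)
    peak = _pdd_raw(params.d_peak_cm(field_size), field_size, params)
    depth_dose = _pdd_raw(d, field_size, params) / peak * params.output_scale
    return depth_dose * (lx / lx0) * (ly / ly0)


def dose_at(x_cm, y_cm, depth_cm, field_size: FieldSize, params: BeamModelParams):
    """Relative dose at (x, y, depth), separable in the two lateral axes.

    Normalized so that ``dose_at(0, 0, d) == pdd(d)``; invariant under
    (x, y) -> (-x, -y) and, for square fields, under x <-> y.
    """
    x = _check_offaxis(x_cm)
    y = _check_offaxis(y_cm)
    d = _check_depth(depth_cm)
    out = _dose_at_unchecked(x, y, d, field_size, params)
    return out if np.ndim(out) else float(out)


def box_averaged_dose(x_cm, y_cm, depth_cm, field_size: FieldSize,
                      params: BeamModelParams, edge_cm: float = 0.5,
                      npts: int = 5):
    """Mean model dose over an axis-aligned cube of side ``edge_cm``.

    Fixed-order Gauss-Legendre quadrature (``npts`` per axis, >= 3) of
    the model dose over the cube centred at (x, y, depth).  This is the
    single averaging operator used both for the TPS reference voxel and for
    the scanning chamber's sensitive volume, so the two sides of the closed
    loop blur the beam identically.  The cube centre must lie in the
    modelled depth range [0, 30] cm; near the surface (or the bottom) the
    quadrature evaluates the model's smooth analytic continuation up to
    half a cube beyond it, which keeps the averaged curve free of
    clamping kinks.  The cube must lie inside the lateral model range.

    With ``edge_cm == 0`` this reduces to the point dose.
    """
    if edge_cm < 0:
        raise ValueError("edge_cm must be >= 0")
    if edge_cm == 0:
        return dose_at(x_cm, y_cm, depth_cm, field_size, params)
    if npts < 3:
        raise ValueError("need at least 3 quadrature points per axis")
    x = np.asarray(x_cm, dtype=float)
    y = np.asarray(y_cm, dtype=float)
    d = _check_depth(depth_cm)
    half = edge_cm / 2.0
    if np.any(np.abs(x) + half > MAX_OFFAXIS_CM) or np.any(np.abs(y) + half > MAX_OFFAXIS_CM):
        raise ValueError("averaging volume extends outside the modelled lateral range")

    nodes, weights = leggauss(npts)  # on [-1, 1]
    off = nodes * half
    w = weights / 2.0  # normalized 1D weights

    # Broadcast sample points: (..., nx, ny, nz)
    xs = x[..., None, None, None] + off[:, None, None]
    ys = y[..., None, None, None] + off[None, :, None]
    zs = d[..., None, None, None] + off[None, None, :]
    vals = _dose_at_unchecked(xs, ys, zs, field_size, params)
    w3 = w[:, None, None] * w[None, :, None] * w[None, None, :]
    out = np.sum(vals * w3, axis=(-3, -2, -1))
    return out if np.ndim(out) else float(out)
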