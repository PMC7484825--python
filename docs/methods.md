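# Methods

This note documents the models, numerical choices and limitations behind
`beamvalid`. The package reproduces, at desk scale, a beam-data-validation
loop for a ring-gantry linac: a scan protocol with couch-synchronized
delivery schedules, a synthetic measurement of that protocol, a synthetic
TPS prediction of the same curves, and a 1D gamma comparison between the
two. Because both sides derive from one analytic beam model, the loop is
*closed*: with no injected noise or perturbation the comparison must pass
by construction, and any injected beam error must be flagged. That is the
property the test suite and `scripts/acceptance.py` verify — it
establishes the internal consistency of the pipeline, not the accuracy of
any physical machine.

## Scan protocol

The default validation request mirrors a published commissioning session
on a 6 MV FFF ring-gantry machine: square fields of 6, 8, 10, 20 and
28 cm; inline, crossline and (for 28×28) diagonal profiles at 1.3, 5, 10,
20 and 30 cm depth; one central-axis depth scan per field size; 90 cm SSD
with SAD 100 cm. Scan speeds are 1.5 mm/s for lateral scans (300 ms
electrometer sampling), 2 mm/s per couch axis for diagonals (2.83 mm/s
along the path) and 2.5 mm/s for depth scans (100 ms sampling).

The bore limits couch travel across it to about 20 cm. A lateral profile
whose required window — the divergence-projected field width at depth plus
a per-side margin — exceeds the single-scan range is split into two scans
taken with the tank offset ±9.5 cm on a sliding platform. Each split
segment has length `2·offset + overlap` (20 cm with the 1 cm default
overlap), so the pair overlaps by exactly the configured length, covers
up to 39 cm symmetrically, and a single offset scan reaches +19.5 cm.
Margins default to 2.5 cm/side for crossline and diagonal scans and
5.5 cm/side inline (the unrestricted direction, range 45 cm); the
diagonal along-path range limit is 25.46 cm with a 12 cm along-path
offset. The required window for a diagonal profile is taken equal to the
crossline one: the corner-to-corner diagonal of a large square field
exceeds any bore-feasible coverage, and the radial reach of the
comparison is what matters. All of these are configuration values.

Scan-time accounting follows the published table: per-scan time is
window/speed (the depth scan is 30 cm at 0.25 cm/s → 2.00 min), a row
total is per-scan time × number of scans, and settling buffers (1 min,
3 min when the tank is shifted, none for depth scans) are tallied in
their own column. The published table carries a small unexplained
additive constant in some per-scan times (e.g. 2.02 min for an 18 cm
crossline scan where the quotient gives 2.00); the formulaic value is
used. Published scan lengths are likewise treated as that session's
realized settings; the package derives windows from the geometry above
and reproduces the published *scan counts* (75 segments;
5/5/5/5/5/5/5/5/5/10/10/10 per row) exactly.

Delivery schedules are generic XML (segment metadata, waypoints at 1 s
cadence plus exact endpoints, beam-on flags) with a SHA-256 checksum of
the canonical body stored as a root attribute; vendor dialects are out of
scope. The checksum is invariant under re-serialization and detects any
change to a waypoint or segment field.

For SSD setup imaging, the gantry angle that grazes the water surface is
90° − atan((SAD − SSD)/SAD): 84.3° at 90 cm SSD, 90° at 100 cm.

## Beam model

The synthetic beam is separable and radially symmetric:

- depth dose: `(1 − exp(−β(d + d₀))) · exp(−μ_eff(s)·d)`, renormalized to
  its maximum, with `μ_eff(s) = μ₀ − k·s` decreasing linearly in the
  Sterling equivalent-square side `s` — larger fields scatter more, so
  depth dose increases monotonically with field size and the five default
  curves never cross beyond the build-up region;
- lateral profile: `½[erf((E−x)/σ√2) + erf((E+x)/σ√2)]` with the edge
  `E = (FS/2)(SSD+d)/SAD` projected for divergence and
  `σ(d) = σ₀ + σ'·d` broadening with depth, modulated by the FFF cone
  factor `1 − c·min((x/E)², 1)`;
- 2D dose: the product of the two lateral factors times the depth dose,
  normalized on the central axis.

Defaults (β = 2.45 cm⁻¹ with the build-up offset d₀ derived so the 10×10
field peaks at d_max = 1.3 cm; μ₀ = 0.055 cm⁻¹, k = 5·10⁻⁴ cm⁻¹/cm;
σ₀ = 0.35 cm, σ' = 0.025; c = 0.08) give a surface dose near 56%,
PDD(10 cm, 10×10) ≈ 0.66 and an ~8% cone falloff at the edge of a 28×28
field — plausible magnitudes for a jawless 6 MV FFF machine, not a fit to
any specific linac. Two perturbation knobs exist for discrimination
studies: a uniform `output_scale` and an `edge_offset_cm` that moves both
field edges outward.

Volume averaging — for the TPS reference voxel *and* the scanning
chamber — is one shared operator: the mean dose over an axis-aligned
0.5 cm cube, by 5-point Gauss–Legendre quadrature per axis. The published
workflow chooses the 0.5 cm voxel precisely to emulate the 0.13 cc
chamber, so the synthetic chamber uses the same cube; a path-aligned 1D
boxcar was rejected because on diagonal scans it averages the two lateral
edges with correlated shifts while a cube averages them independently,
introducing a spurious ~1% penumbra discrepancy between the two sides of
the loop. Near the water surface (and at 30 cm) the quadrature evaluates
the model's smooth analytic continuation up to half a cube beyond the
column rather than clamping, which keeps the averaged build-up free of a
kink at the first depth node. A real chamber is a cylinder, not a cube,
and real water has a surface: both idealizations are shared by the two
sides of the loop and therefore cancel in the comparison.

## TPS sampling

Lateral predictions are sampled on a half axis (the planning model is
radially symmetric) and mirrored, making TPS curves exactly even — a
property measured curves only acquire after centering. Spacing is
region-dependent: 5 mm in-field and in the umbra, 1 mm through the
penumbra and the transition bands flanking it. The penumbra is defined as
the 20–80% span of the central-axis-normalized model profile at that
depth; the fine band extends a further 5 mm *plus 2.2 penumbra sigmas* on
each side. The extension scales with the erf-edge blur because the
shoulder and foot of the edge retain curvature of tens of %/cm² well
beyond the 20%/80% points: with a fixed 5 mm band, linear or spline
interpolation across the first 5 mm umbra step mis-states the reference
by up to ~0.9% of the axis value, an artifact that would dominate the
closed-loop gamma. Depth curves are 61 voxel doses from 0 to 30 cm at
5 mm spacing. Grid generation is deterministic; identical inputs give
byte-identical CSV.

Diagonal couch coordinates are folded to signed radial positions
`r = sign(x)·√(x²+y²)` after verifying the points are collinear through
the origin.

## Measurement simulation and reconstruction

`simulate_scan` samples the delivery schedule at the segment's
electrometer interval: the field reading is the chamber-averaged model
dose scaled to a nominal 20 nA, with multiplicative Gaussian noise
(default σ = 0.2%, an ionization-chamber/electrometer noise magnitude),
optional linear drift on the field channel, and a 2 pA leakage offset
that keeps umbra readings physical; the reference channel is a constant
current with its own (default zero) noise. Machine output fluctuation is
common to both chambers and cancels in the ratio, so it is not modelled
separately. Everything is deterministic given the seed, which is recorded
in the log.

Reconstruction interpolates couch positions at the sample times, restores
the platform offset, folds diagonals to radial coordinates and forms the
field/reference ratio. Depth scans are shifted by the effective point of
measurement — 0.6 × the 3 mm cavity radius = 1.8 mm toward the surface,
for the modelled 0.13 cc cylindrical chamber, applied to depth scans
only. The simulator evaluates the chamber's dose at the same shifted
point, since the EPOM correction exists exactly because a real chamber
reads upstream of its centre; reported depths near the surface can
therefore be slightly negative and are flagged (not scored) in the
comparison.

Split scans are stitched over their overlap: the right-hand curve is
rescaled by the mean left/right ratio across the overlap, then blended
with a linear cross-fade. The pipeline allows the realized overlap to
fall short of the nominal 1 cm by up to one sample spacing, because the
electrometer quantizes each scan end to its sampling grid. Post-processing
is exactly what the published workflow applies: lateral profiles are
centered on the midpoint of their 50% crossings (outermost crossings,
linearly interpolated) and normalized to the mean of the three central
samples; depth curves are normalized to their maximum; both are expressed
in percent.

## Gamma analysis

The evaluated (measured) curve is scored point-by-point against the
reference (TPS) curve; measured points are never interpolated. The
reference, a sparse sampling of a smooth dose curve, is resampled with a
cubic spline at 0.1 × DTA steps over a search radius of 5 × DTA, and the
gamma minimum is taken in closed form over the segments of the densified
polyline (the restriction of γ² to a segment is quadratic, so the
per-segment minimizer is analytic). A discrete minimum over the candidate
points alone overshoots by up to half a dose step in ~1 %/mm gradients;
the closed-form segment minimum removes that error entirely, and the
package agrees with an exhaustive 0.01 mm brute-force minimizer to better
than 0.02 γ. Cubic rather than linear resampling matters most in the
build-up region of depth curves, where a linear chord across a 5 mm node
interval deviates from the smooth curve by several percent — the residual
worst-case closed-loop gamma (~0.3 at 1%/1 mm, always at shallow depths)
is the remaining interpolation error of *any* generic interpolant given
5 mm sampling of that curvature, and is the synthetic counterpart of the
penumbra/build-up gamma hot spots familiar from this kind of comparison.

Normalization is global by default (the dose criterion is a percentage of
the 100% level, matching CAX/max normalization); a local mode is
available. Points outside the reference support are excluded from the
pass-rate denominator. Summaries report pass rate (γ < 1), mean, max and
a 0.05-wide-bin histogram; a criteria sweep tabulates these across
tolerance settings, with pass rates non-decreasing as tolerances loosen.

## Perturbations and what the closed loop can show

Two error injections are provided. The **edge shift** (default study:
2 mm) perturbs the measurement-side beam geometry and produces DTA-type
failures in every penumbra at 1%/1 mm. The **dose-scale discrepancy**
(2%) multiplies the normalized measured curves, emulating a net in-field
dose error between prediction and measurement in comparison space. It is
applied after normalization deliberately: a *physical* uniform output
error scales field and reference readings alike and, even if it did not,
is removed exactly by CAX/max normalization — relative-profile validation
is blind to calibration errors, a limitation shared with the physical
workflow it models (output calibration is a separate commissioning test).
The package includes a model-level `output_scale` so this cancellation is
itself testable.

The synthetic loop emulates: beam divergence, FFF cone shape, penumbra
broadening with depth, field-size-dependent depth dose, detector volume
averaging, EPOM, electrometer sampling/noise/leakage, bore-limited split
scans and platform offsets. It does not emulate: water surface settling
and meniscus effects, cable-in-beam perturbation, tank leveling or couch
sag, chamber polarity/recombination, beam spectral changes off-axis, or
TPS calculation-grid effects. Passing the closed loop therefore
demonstrates that the protocol, reconstruction and comparison machinery
are mutually consistent and sensitive at the stated tolerances — not that
a physical machine would pass.

## Problem sizes and determinism

The default closed loop compares 60 curve pairs (55 lateral/diagonal, 5
depth; ~37 000 scored points) and runs in a few seconds on one CPU; the
acceptance script runs the loop four times (zero-noise, noisy, two
perturbed) plus the brute-force gamma cross-check. All randomness flows
from a single seed: each segment's log gets a deterministic child seed
derived from it, recorded in the log header. Reports contain no
timestamps, so identical configuration and seed give identical output
files.
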