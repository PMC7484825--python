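# beamvalid

Closed-loop treatment-planning-system (TPS) beam-data validation for a
ring-gantry linac, using a 1D water tank driven by couch-synchronized beam
deliveries.

## The problem

A preconfigured ring-gantry linac ships with a factory beam model in the
TPS, but the physicist commissioning the machine must still validate that
model against measurement. The enclosed ~100 cm bore rules out a
conventional 3D scanning tank, so profiles are instead *reconstructed* with
a 1D tank: the treatment couch carries the tank through the beam along a
programmed trajectory while a data-logging electrometer records the field
and reference ionization-chamber currents. The same validation request
also drives the TPS side: virtual couch positions are sampled and the dose
to a 0.5 cm reference voxel (standing in for the 0.13 cc chamber) is
extracted, giving a predicted curve for every measured one.

`beamvalid` implements this whole loop as a self-contained toolkit:

- **protocol builder** — expands a request (field sizes, depths, axes) into
  continuous scan segments, splitting bore-limited crossline/diagonal scans
  into two offset scans with a 1 cm overlap, and emits each segment as a
  couch-position-vs-time XML delivery schedule with a SHA-256 integrity
  checksum, plus a scan-time summary table;
- **beam model** — an analytic, radially symmetric 6 MV FFF beam (erf field
  edges with depth-broadening penumbra, quadratic cone falloff,
  exponential build-up/attenuation depth dose with field-size-dependent
  effective attenuation) that serves as the shared ground truth for both
  sides of the synthetic loop;
- **TPS sampler** — region-dependent sampling (5 mm in-field and umbra,
  1 mm through the penumbra and its transition bands), half-profile
  mirroring, 0.5 cm voxel averaging, 61-point depth curves;
- **measurement simulator / reconstructor** — electrometer time series from
  a schedule (volume averaging, multiplicative noise, effective point of
  measurement), position reconstruction from the couch trajectory,
  split-scan stitching, centering and normalization;
- **gamma comparison** — 1D gamma analysis with configurable criteria.

## The gamma index

For an evaluated point at position $x$ with dose $D_m$, against a
reference curve $D_r(\cdot)$:

$$\gamma(x) = \min_r \sqrt{\left(\frac{r - x}{\delta_{\mathrm{DTA}}}\right)^2 +
\left(\frac{D_r(r) - D_m}{\delta_{\mathrm{dose}}}\right)^2}$$

with e.g. $\delta_{\mathrm{dose}} = 1\%$ of the normalization level and
$\delta_{\mathrm{DTA}} = 1$ mm. A point passes when $\gamma < 1$; a curve
pair is summarized by its pass rate, mean and maximum gamma. The reference
is resampled with a cubic spline at 0.1 × DTA steps and the minimum is
taken in closed form over the densified polyline, so the result is free of
search-discretization error even in ~1 %/mm gradients.

## Worked example

```python
from beamvalid import ProtocolConfig, imaging_gantry_angle
from beamvalid.config import ValidationRunConfig
from beamvalid.report import run_closed_loop, render_text_report

# gantry angle for imaging the water surface when setting 90 cm SSD
print(imaging_gantry_angle(ssd_cm=90))          # 84.28940686250036

cfg = ValidationRunConfig(
    protocol=ProtocolConfig(field_sizes_cm=(6.0, 20.0),
                            profile_depths_cm=(1.3, 10.0),
                            axes=("depth", "crossline"),
                            diagonal_field_sizes_cm=()),
)
report = run_closed_loop(cfg, None, seed=1)
print(render_text_report(report))
```

prints (abridged):

```
Beam data validation report
================================================================
seed: 1
criteria: 1%/1mm, 1.5%/1.5mm

axis      field   depth      1%/1mm pass%  1.5%/1.5mm pass%
-----------------------------------------------------------
crossline 20x20   1.3              100.00          100.00
crossline 20x20   10               100.00          100.00
...
      1%/1mm depth    n=2386    pass 100.00%  mean 0.176  max 0.902
      1%/1mm offaxis  n=2258    pass 100.00%  mean 0.077  max 0.709
      1%/1mm all      n=4644    pass 100.00%  mean 0.128  max 0.902

VERDICT (1%/1mm): PASS
```

Each row is one (axis, field size, depth) curve pair; the groups at the
bottom aggregate depth-dose and off-axis comparisons. With the default
0.2% electrometer noise, every one of the 4644 compared points stays below
gamma 1 at 1%/1 mm; the worst point (gamma 0.90) sits in the build-up
region of a depth curve, where the prediction is sampled most sparsely
relative to its curvature.

The same loop is available from the shell:

```
beamvalid plan        --config run.yaml --out outdir     # schedules + time table
beamvalid closed-loop --config run.yaml --seed 1 --out outdir
beamvalid simulate / reconstruct / stitch / compare ...  # stage by stage
```

`beamvalid plan` with the default request writes 75 schedule XMLs — 5
depth scans, 25 inline, 35 crossline (the 20 cm and 28 cm fields need two
offset scans per depth) and 10 diagonal half-scans — and a per-row time
summary whose scan counts match the published protocol.

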