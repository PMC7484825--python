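"""Closed-loop orchestration: plan, simulate, compare, report.

run_plan expands a request into delivery-schedule XML files plus a
scan-time summary; run_closed_loop drives the whole synthetic feedback
loop (TPS curves and simulated measurements from the same beam model,
reconstruction, stitching, centering, normalization, gamma); run_compare
pairs measured and TPS curve files by metadata and reports per-pair and
aggregate gamma statistics.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import ValidationRunConfig, config_to_dict
from .curves import Curve
from .gamma import GammaCriteria, gamma_1d, summarize
from .measure import (
    center_profile,
    normalize_profile,
    reconstruct_profile,
    simulate_scan,
    stitch_scans,
)
from .protocol import (
    ProtocolError,
    ScanProtocol,
    build_default_protocol,
    emit_delivery_schedule,
    protocol_time_summary,
)
from .tps import sample_depth_curve, sample_lateral_curve

__all__ = ["run_plan", "run_closed_loop", "run_compare", "render_text_report",
           "measured_curves_from_protocol", "tps_curves_from_protocol",
           "plot_pair"]

log = logging.getLogger("beamvalid")


def _segment_filename(i: int, seg) -> str:
    depth = "dd" if seg.depth_cm is None else f"d{seg.depth_cm:g}"
    off = f"_off{seg.tank_offset_cm:+g}" if seg.tank_offset_cm else ""
    return f"{i:03d}_{seg.axis}_{seg.field_size.label()}_{depth}{off}"


def run_plan(config: ValidationRunConfig, outdir: str | Path) -> dict:
    """Write one schedule XML per segment plus the time summary CSV.

    Returns a manifest dict (files, checksums, totals).  Deterministic:
    rerunning with the same config produces byte-identical files.
    """
    outdir = Path(outdir)
    protocol = build_default_protocol(config.protocol)
    sched_dir = outdir / "schedules"
    sched_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, seg in enumerate(protocol.segments, start=1):
        schedule = emit_delivery_schedule(seg)
        name = _segment_filename(i, seg) + ".xml"
        checksum = schedule.write(sched_dir / name)
        entries.append({"file": f"schedules/{name}", "checksum": checksum})
        log.info("planned %s (checksum %s)", name, checksum[:12])
    df, totals = protocol_time_summary(protocol, config.protocol)
    df.to_csv(outdir / "time_summary.csv", index=False)
    manifest = {"n_segments": len(protocol), "schedules": entries,
                "time_totals": totals}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("planned %d segments, scanning time %.2f min",
             len(protocol), totals["scanning_min"])
    return manifest


# ---------------------------------------------------------------------------
# curve generation


def tps_curves_from_protocol(protocol: ScanProtocol,
                             config: ValidationRunConfig) -> dict:
    """One TPS-predicted curve per (axis, field size, depth) group."""
    curves: dict[tuple, Curve] = {}
    for key, segs in protocol.groups().items():
        axis, _, _ = key
        seg = segs[0]
        if axis == "depth":
            curve = sample_depth_curve(config.beam, seg.field_size,
                                       spacing_mm=config.tps.depth_spacing_mm,
                                       voxel_cm=config.tps.voxel_cm)
        else:
            window = max(max(abs(s.window_lo), abs(s.window_hi))
                         for s in segs) + config.tps.window_pad_cm
            curve = sample_lateral_curve(config.beam, seg.field_size,
                                         seg.depth_cm, window,
                                         rule=config.tps.rule, axis=axis,
                                         voxel_cm=config.tps.voxel_cm)
        curves[key] = curve
    return curves


def measured_curves_from_protocol(protocol: ScanProtocol,
                                  config: ValidationRunConfig,
                                  seed: int) -> dict:
    """Simulate and reconstruct every segment, stitching split scans.

    The measurement-side beam carries any configured geometric
    perturbation; each segment gets its own deterministic child seed,
    recorded in its log.
    """
    beam = config.beam.with_perturbation(
        edge_shift_cm=config.perturbation.edge_shift_mm / 10.0)
    curves: dict[tuple, Curve] = {}
    seg_index = {id(s): i for i, s in enumerate(protocol.segments)}
    for key, segs in protocol.groups().items():
        parts = []
        for seg in segs:
            schedule = emit_delivery_schedule(seg)
            child_seed = (seed * 100003 + seg_index[id(seg)]) % (2**31)
            logrec = simulate_scan(schedule, beam, config.noise,
                                   config.chamber, seed=child_seed)
            parts.append(reconstruct_profile(logrec, schedule, config.chamber))
        if len(parts) == 1:
            curves[key] = parts[0]
        elif len(parts) == 2:
            # the electrometer quantizes each scan end to the sample grid,
            # so the realized overlap can fall short by up to one sample
            quant = 2.0 * segs[0].speed_cm_s * segs[0].sampling_interval_s
            curves[key] = stitch_scans(parts[0], parts[1],
                                       overlap_cm=config.protocol.overlap_cm - quant)
        else:  # pragma: no cover - planner emits at most 2 per group
            raise ProtocolError(f"cannot stitch {len(parts)} scans for {key}")
    return curves


def _postprocess(curve: Curve, center: bool) -> Curve:
    if center and curve.axis != "depth":
        curve, _ = center_profile(curve)
    return normalize_profile(curve)


# ---------------------------------------------------------------------------
# comparison and reporting


def _compare_pairs(pairs: dict, criteria) -> dict:
    """Gamma statistics per pair, per axis-type group and overall."""
    report: dict = {"criteria": [c.label() for c in criteria], "pairs": []}
    gammas = {c.label(): {"depth": [], "offaxis": [], "all": []} for c in criteria}
    for key in sorted(pairs, key=str):
        measured, reference = pairs[key]
        axis, fs, depth = key
        entry = {"axis": axis, "field_size_cm": fs, "depth_cm": depth,
                 "n_flagged": 0, "results": {}}
        for crit in criteria:
            res = gamma_1d(measured, reference, crit)
            s = summarize(res)
            entry["results"][crit.label()] = s.to_dict()
            entry["n_flagged"] = int(np.count_nonzero(~res.scored))
            g = res.gamma_values[res.scored]
            bucket = "depth" if axis == "depth" else "offaxis"
            gammas[crit.label()][bucket].append(g)
            gammas[crit.label()]["all"].append(g)
        report["pairs"].append(entry)

    report["groups"] = {}
    for label, buckets in gammas.items():
        report["groups"][label] = {}
        for bucket, parts in buckets.items():
            if not parts:
                continue
            g = np.concatenate(parts)
            report["groups"][label][bucket] = {
                "n_points": int(g.size),
                "pass_rate_pct": float(np.mean(g < 1.0) * 100.0),
                "mean_gamma": float(np.mean(g)),
                "max_gamma": float(np.max(g)),
            }
    return report


def run_closed_loop(config: ValidationRunConfig,
                    outdir: str | Path | None = None,
                    seed: int | None = None,
                    write_plots: bool = False) -> dict:
    """Run the full synthetic feedback loop and return the report dict.

    Both sides derive from the same beam model: the TPS curves by voxel
    sampling, the measurement by simulated couch-synchronized scans.  The
    verdict is PASS when every scored point passes the strictest
    configured criteria (100% pass rate).
    """
    seed = config.seed if seed is None else seed
    criteria = list(config.gamma_criteria)
    log.info("closed loop: seed=%d, criteria=%s", seed,
             [c.label() for c in criteria])

    log.info("stage: protocol")
    protocol = build_default_protocol(config.protocol)
    log.info("stage: tps curves (%d groups)", len(protocol.groups()))
    tps_curves = tps_curves_from_protocol(protocol, config)
    log.info("stage: measurement simulation (%d segments)", len(protocol))
    measured = measured_curves_from_protocol(protocol, config, seed)

    log.info("stage: post-processing and gamma")
    scale = 1.0 + config.perturbation.dose_scale_pct / 100.0
    pairs = {}
    for key, m in measured.items():
        mp = _postprocess(m, center=True)
        if scale != 1.0:
            mp = mp.with_values(mp.values * scale)
        tp = _postprocess(tps_curves[key], center=False)
        pairs[key] = (mp, tp)
    report = _compare_pairs(pairs, criteria)

    strict = config.strictest_criteria().label()
    overall = report["groups"][strict]["all"]
    report["seed"] = seed
    report["verdict"] = "PASS" if overall["pass_rate_pct"] == 100.0 else "FAIL"
    report["strictest_criteria"] = strict
    log.info("verdict %s (%s: pass %.2f%%, mean %.3f, max %.3f)",
             report["verdict"], strict, overall["pass_rate_pct"],
             overall["mean_gamma"], overall["max_gamma"])

    if outdir is not None:
        outdir = Path(outdir)
        for sub, curves in (("tps", {k: v[1] for k, v in pairs.items()}),
                            ("measured", {k: v[0] for k, v in pairs.items()})):
            d = outdir / sub
            d.mkdir(parents=True, exist_ok=True)
            for i, (key, c) in enumerate(sorted(curves.items(), key=lambda kv: str(kv[0]))):
                c.to_csv(d / (f"{i:03d}_{c.axis}_{c.field_size.label()}"
                              + ("" if c.depth_cm is None else f"_d{c.depth_cm:g}")
                              + ".csv"))
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        (outdir / "report.txt").write_text(render_text_report(report))
        (outdir / "config.json").write_text(
            json.dumps(config_to_dict(config), indent=2))
        if write_plots:
            plotdir = outdir / "plots"
            plotdir.mkdir(exist_ok=True)
            for key, (m, t) in pairs.items():
                res = gamma_1d(m, t, config.strictest_criteria())
                name = f"{key[0]}_{key[1]}" + ("" if key[2] is None else f"_d{key[2]:g}")
                plot_pair(m, t, res, plotdir / f"{name}.png")
    return report


def run_compare(measured_dir: str | Path, tps_dir: str | Path,
                criteria) -> dict:
    """Compare measured curve CSVs against TPS curve CSVs by metadata.

    Curves are paired on (axis, field size, depth) regardless of file
    names; unmatched curves are listed as warnings.  Measured laterals are
    centered; both sides are normalized before gamma.
    """
    criteria = list(criteria) or [GammaCriteria()]

    def load_dir(d):
        out = {}
        for path in sorted(Path(d).glob("*.csv")):
            c = Curve.from_csv(path)
            out[c.key] = c
        return out

    measured = load_dir(measured_dir)
    tps = load_dir(tps_dir)
    if not measured or not tps:
        raise ValueError("no curve CSV files found to compare")
    keys = sorted(set(measured) & set(tps), key=str)
    if not keys:
        raise ValueError("no matching (axis, field size, depth) curve pairs")
    warnings = [f"unmatched measured curve: {k}" for k in sorted(set(measured) - set(keys), key=str)]
    warnings += [f"unmatched tps curve: {k}" for k in sorted(set(tps) - set(keys), key=str)]
    for w in warnings:
        log.warning("%s", w)

    pairs = {k: (_postprocess(measured[k], center=True),
                 _postprocess(tps[k], center=False)) for k in keys}
    report = _compare_pairs(pairs, criteria)
    report["warnings"] = warnings
    return report


def render_text_report(report: dict) -> str:
    """Human-readable validation summary table."""
    lines = ["Beam data validation report", "=" * 64]
    if "seed" in report:
        lines.append(f"seed: {report['seed']}")
    lines.append(f"criteria: {', '.join(report['criteria'])}")
    lines.append("")
    header = (f"{'axis':<10}{'field':<8}{'depth':<7}"
              + "".join(f"{c + ' pass%':>16}" for c in report["criteria"]))
    lines.append(header)
    lines.append("-" * len(header))
    for pair in report["pairs"]:
        depth = "-" if pair["depth_cm"] is None else f"{pair['depth_cm']:g}"
        row = f"{pair['axis']:<10}{pair['field_size_cm']:<8}{depth:<7}"
        for c in report["criteria"]:
            row += f"{pair['results'][c]['pass_rate_pct']:>16.2f}"
        lines.append(row)
    lines.append("")
    for label, groups in report["groups"].items():
        for bucket, s in groups.items():
            lines.append(
                f"{label:>12} {bucket:<8} n={s['n_points']:<7} "
                f"pass {s['pass_rate_pct']:6.2f}%  mean {s['mean_gamma']:.3f}  "
                f"max {s['max_gamma']:.3f}")
    if report.get("verdict"):
        lines.append("")
        lines.append(f"VERDICT ({report['strictest_criteria']}): {report['verdict']}")
    lines.append("")
    return "\n".join(lines)


def plot_pair(measured: Curve, reference: Curve, result, path) -> None:
    """Profile overlay, gamma trace and gamma histogram for one pair."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(6, 8),
                             gridspec_kw={"height_ratios": [2, 1, 1]})
    axes[0].plot(reference.positions, reference.values, "-", label="TPS")
    axes[0].plot(measured.positions, measured.values, ".", ms=2, label="measured")
    axes[0].set_ylabel("dose (%)")
    axes[0].legend()
    g = result.gamma_values[result.scored]
    p = result.positions[result.scored]
    colors = np.where(g < 1.0, "green", "red")
    axes[1].scatter(p, g, s=3, c=colors)
    axes[1].axhline(1.0, color="k", lw=0.5)
    axes[1].set_ylabel("gamma")
    axes[1].set_xlabel("position (cm)")
    axes[2].hist(g, bins=np.arange(0, max(g.max(), 0.05) + 0.05, 0.05))
    axes[2].set_xlabel("gamma")
    axes[2].set_ylabel("points")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
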