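"""End-to-end orchestration: simulate -> analyse -> report.

One seeded run generates synthetic inputs for every enabled stage, runs
the corresponding analysis, and writes per-stage CSVs, a diagnostic
summary table, a Markdown report with a classification plot, and a
manifest recording every parameter used plus SHA-256 digests of every
output file.  Rerunning with the same config and seed reproduces
identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dnc, histology, hplc, io, photometry, studyparams, synthetic
from .config import RunConfig

__all__ = ["run_end_to_end"]

log = logging.getLogger("dnctest.pipeline")

# fixed per-stage seed offsets so stage reordering never reshuffles draws
_SEED_OFFSETS = {"cohort": 101, "photometry": 211, "hplc": 307, "histology": 401}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(config: RunConfig, stage: str, extra: int = 0) -> int:
    return (config.seed + _SEED_OFFSETS[stage] + extra) % (2**31)


def run_end_to_end(config: RunConfig, output_dir=None) -> dict:
    """Execute all enabled stages; returns the manifest dictionary."""
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(mode="json"),
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    report: list[str] = ["# DNC Test pipeline report", ""]

    cohorts: dict[str, pd.DataFrame] = {}
    if config.stages.cohort:
        cohorts = _run_cohort(config, outdir, manifest)
    if config.stages.dnc and cohorts:
        _run_dnc(config, outdir, manifest, report, cohorts)
    if config.stages.photometry:
        _run_photometry(config, outdir, manifest, report)
    if config.stages.hplc:
        _run_hplc(config, outdir, manifest, report)
    if config.stages.histology:
        _run_histology(config, outdir, manifest, report)

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(report) + "\n")
    manifest["outputs"]["report.md"] = _digest(report_path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %s", outdir)
    return manifest


def _md_table(df: pd.DataFrame) -> str:
    """Small GitHub-style table formatter (keeps reports dependency-light)."""
    cols = list(df.columns)
    lines = ["| " + " | ".join(str(c) for c in cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines)


def _register(outdir: Path, manifest: dict, path: Path) -> None:
    manifest["outputs"][str(path.relative_to(outdir))] = _digest(path)


def _run_cohort(config: RunConfig, outdir: Path, manifest: dict) -> dict[str, pd.DataFrame]:
    cohorts = {}
    for i, stage in enumerate(config.cohort.stages):
        spec = synthetic.CohortSpec.from_study(stage, seed=_stage_seed(config, "cohort", i))
        table = synthetic.simulate_cohort(spec)
        path = outdir / f"cohort_{stage}.csv"
        io.write_cohort(table, path)
        _register(outdir, manifest, path)
        cohorts[stage] = table
        log.info("cohort stage=%s subjects=%d", stage, len(table))
    manifest["stages"]["cohort"] = {"stages": config.cohort.stages}
    return cohorts


def _run_dnc(config, outdir, manifest, report, cohorts) -> None:
    report += ["## Diagnostic classification", ""]
    # thresholds recomputed from the published challenged-state group means
    pub_rows = []
    for stage in config.cohort.stages:
        for analyte in studyparams.ANALYTES:
            c = studyparams.COHORT_STATS[(stage, analyte, "control", "challenged")]
            p = studyparams.COHORT_STATS[(stage, analyte, "PD", "challenged")]
            pub_rows.append(
                {
                    "stage": stage,
                    "analyte": analyte,
                    "threshold": round(dnc.compute_threshold(c.mean, p.mean), 4),
                }
            )
    pub = pd.DataFrame(pub_rows)
    pub_path = outdir / "published_thresholds.csv"
    pub.to_csv(pub_path, index=False)
    _register(outdir, manifest, pub_path)
    report += [
        "Midpoint thresholds from the published challenged-state group means:",
        "",
        _md_table(pub),
        "",
    ]

    for stage, table in cohorts.items():
        result = dnc.table1(table, state=config.dnc.state)
        path = outdir / f"table1_{stage}.csv"
        result.to_csv(path, index=False)
        _register(outdir, manifest, path)
        report += [
            f"Simulated cohort ({stage} stage), state={config.dnc.state}:",
            "",
            _md_table(result),
            "",
        ]
        _plot_classification(table, result, outdir / f"classification_{stage}.png")
        report += [f"![classification {stage}](classification_{stage}.png)", ""]
    manifest["stages"]["dnc"] = {"state": config.dnc.state}


def _plot_classification(cohort: pd.DataFrame, table1: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    analytes = list(table1["analyte"])
    fig, axes = plt.subplots(1, len(analytes), figsize=(3.2 * len(analytes), 3.2))
    axes = np.atleast_1d(axes)
    rng = np.random.default_rng(0)  # jitter only, cosmetic
    for ax, analyte in zip(axes, analytes):
        thr = float(table1.loc[table1["analyte"] == analyte, "threshold"].iloc[0])
        sub = cohort[(cohort["analyte"] == analyte) & (cohort["state"] == "challenged")]
        for x, grp, color in ((0, "control", "tab:blue"), (1, "PD", "tab:red")):
            vals = sub.loc[sub["genotype_group"] == grp, "value"]
            ax.scatter(
                x + rng.uniform(-0.12, 0.12, len(vals)), vals, s=14, alpha=0.7, color=color
            )
        ax.axhline(thr, color="k", ls="--", lw=1, label=f"threshold {thr:.4g}")
        ax.set_xticks([0, 1], ["control", "PD"])
        ax.set_title(analyte, fontsize=9)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _run_photometry(config, outdir, manifest, report) -> None:
    p = config.photometry
    basis = synthetic.make_basis(
        [synthetic.DLIGHT, synthetic.TDTOMATO], synthetic.default_wavelength_grid()
    )
    if basis.ill_conditioned:
        manifest["warnings"].append("photometry: ill-conditioned spectral basis")
    params = synthetic.SessionParams(
        frame_rate=p.frame_rate,
        duration=p.duration,
        bleach_slope=p.bleach_slope,
        transient_onset=p.transient_onset,
        transient_amplitude=p.transient_amplitude,
        transient_decay=p.transient_decay,
        noise_sd=p.noise_sd,
        seed=_stage_seed(config, "photometry"),
    )
    series, truth = synthetic.simulate_session(basis, params)
    trace = photometry.unmix_series(series, basis)
    dff = photometry.fit_fading_baseline(trace, synthetic.DLIGHT.name, p.fit_window_s)
    rise = photometry.percent_ratio_increase(
        trace,
        injection_time=p.transient_onset,
        pre_window_s=min(300.0, p.transient_onset),
        post_window_s=p.duration - p.transient_onset,
        smoothing_s=p.smoothing_s,
    )
    io.write_trace(trace, outdir / "photometry_trace.csv")
    io.write_dff(dff, outdir / "photometry_dff.csv")
    _register(outdir, manifest, outdir / "photometry_trace.csv")
    _register(outdir, manifest, outdir / "photometry_dff.csv")
    post = dff.timestamps > p.transient_onset
    peak_dff = float(
        np.max(
            photometry.moving_average(
                dff.dff_percent, max(1, int(round(p.smoothing_s * p.frame_rate)))
            )[post]
        )
    )
    manifest["stages"]["photometry"] = {
        "injected_amplitude_pct": p.transient_amplitude * 100.0,
        "recovered_peak_dff_pct": peak_dff,
        "ratio_increase_pct": rise,
    }
    report += [
        "## Photometry",
        "",
        f"- injected transient amplitude: {p.transient_amplitude * 100:.1f}% "
        f"-> recovered peak dF/F0: {peak_dff:.1f}%",
        f"- dLight/tdTomato ratio increase after injection: {rise:.1f}%",
        "",
    ]


def _run_hplc(config, outdir, manifest, report) -> None:
    h = config.hplc
    rng = np.random.default_rng(_stage_seed(config, "hplc"))
    width = h.peak_width_s

    # calibration: one standards chromatogram per published concentration
    points = []
    for i, conc in enumerate(studyparams.STANDARD_CONCENTRATIONS_NG_ML):
        amp = h.curve_slope * conc / (width * np.sqrt(2 * np.pi))
        amp *= 1.0 + rng.normal(0.0, h.curve_noise_fraction)
        chrom = synthetic.simulate_chromatogram(
            [("HVA", 300.0, amp, width)],
            noise_sd=h.noise_sd,
            seed=_stage_seed(config, "hplc", 10 + i),
            duration=600.0,
        )
        auc = hplc.integrate_peak(chrom, hplc.PeakWindow("HVA", 300 - 5 * width, 300 + 5 * width))
        points.append((conc, auc))
    curve = hplc.fit_standard_curve(points)
    io.write_curve(curve, outdir / "standard_curve.json")
    _register(outdir, manifest, outdir / "standard_curve.json")

    # one CSF chromatogram at the published challenged-control area ratios
    stats = studyparams.COHORT_STATS
    dopac_ratio = stats[("early", "DOPAC_5HIAA", "control", "challenged")].mean
    hva_ratio = stats[("early", "HVA_5HIAA", "control", "challenged")].mean
    hiaa_area = 500.0
    csf = synthetic.simulate_chromatogram(
        [
            ("DOPAC", 180.0, dopac_ratio * hiaa_area / (width * np.sqrt(2 * np.pi)), width),
            ("5-HIAA", 360.0, hiaa_area / (width * np.sqrt(2 * np.pi)), width),
            ("HVA", 520.0, hva_ratio * hiaa_area / (width * np.sqrt(2 * np.pi)), width),
        ],
        noise_sd=h.noise_sd * 0.01,
        seed=_stage_seed(config, "hplc", 50),
        duration=600.0,
    )
    io.write_chromatogram(csf, outdir / "csf_chromatogram.csv")
    _register(outdir, manifest, outdir / "csf_chromatogram.csv")
    windows = [
        hplc.PeakWindow("DOPAC", 180 - 5 * width, 180 + 5 * width),
        hplc.PeakWindow("5-HIAA", 360 - 5 * width, 360 + 5 * width),
        hplc.PeakWindow("HVA", 520 - 5 * width, 520 + 5 * width),
    ]
    panel = hplc.compute_panel(csf, windows, None, "CSF", subject_id="csf_demo")

    # one plasma chromatogram constructed at the challenged-control mean
    target = stats[("early", "HVA_ng_ml", "control", "challenged")].mean
    plasma = synthetic.simulate_chromatogram(
        [("HVA", 300.0, curve.auc_for(target) / (width * np.sqrt(2 * np.pi)), width)],
        noise_sd=0.0,
        seed=_stage_seed(config, "hplc", 60),
        duration=600.0,
    )
    ppanel = hplc.compute_panel(
        plasma,
        [hplc.PeakWindow("HVA", 300 - 5 * width, 300 + 5 * width)],
        curve,
        "plasma",
        subject_id="plasma_demo",
    )
    panel_df = pd.DataFrame(
        [
            {
                "subject_id": panel.subject_id,
                "matrix": panel.matrix,
                "dopac_5hiaa": panel.dopac_5hiaa,
                "hva_5hiaa": panel.hva_5hiaa,
                "hva_ng_ml": None,
            },
            {
                "subject_id": ppanel.subject_id,
                "matrix": ppanel.matrix,
                "dopac_5hiaa": None,
                "hva_5hiaa": None,
                "hva_ng_ml": ppanel.hva_ng_ml,
            },
        ]
    )
    panel_df.to_csv(outdir / "metabolite_panels.csv", index=False)
    _register(outdir, manifest, outdir / "metabolite_panels.csv")
    manifest["stages"]["hplc"] = {
        "curve_slope_fit": curve.slope,
        "curve_r_squared": curve.r_squared,
        "csf_dopac_5hiaa": panel.dopac_5hiaa,
        "csf_hva_5hiaa": panel.hva_5hiaa,
        "plasma_hva_ng_ml": ppanel.hva_ng_ml,
    }
    report += [
        "## HPLC",
        "",
        f"- standard curve: slope {curve.slope:.2f} AUC/(ng/ml), r^2 = {curve.r_squared:.4f}",
        f"- CSF panel: DOPAC/5-HIAA = {panel.dopac_5hiaa:.4f} (constructed {dopac_ratio:.4f}), "
        f"HVA/5-HIAA = {panel.hva_5hiaa:.4f} (constructed {hva_ratio:.4f})",
        f"- plasma HVA: {ppanel.hva_ng_ml:.2f} ng/ml (constructed {target:.2f})",
        "",
    ]


def _run_histology(config, outdir, manifest, report) -> None:
    img_cfg = config.histology_image
    params = histology.CountingParams(
        maxima_filter_size=config.counting.maxima_filter_size,
        blur_size=config.counting.blur_size,
        background_radius=config.counting.background_radius,
        min_particle_area=config.counting.min_particle_area,
        marker_min_distance=config.counting.marker_min_distance,
    )
    counts = {}
    rows = []
    for i, (label_name, n_cells) in enumerate(
        (("control", img_cfg.n_cells_control), ("PD", img_cfg.n_cells_pd))
    ):
        spec = synthetic.ImageSpec(
            shape=img_cfg.shape,
            n_cells=n_cells,
            cell_radius_range=img_cfg.cell_radius_range,
            cell_intensity=img_cfg.cell_intensity,
            background_level=img_cfg.background_level,
            texture_sd=img_cfg.texture_sd,
            seed=_stage_seed(config, "histology", i),
        )
        sim = synthetic.simulate_histology(spec)
        io.write_image(sim.image, outdir / f"section_{label_name}.tif")
        _register(outdir, manifest, outdir / f"section_{label_name}.tif")
        res = histology.count_cells(sim.image, params, section_id=label_name)
        counts[label_name] = res.cell_count
        rows.append(
            {"section_id": label_name, "cell_count": res.cell_count, "ground_truth": sim.count}
        )
        if res.cell_count != sim.count:
            manifest["warnings"].append(
                f"histology: {label_name} count {res.cell_count} != ground truth {sim.count}"
            )
    counts_df = pd.DataFrame(rows)
    counts_df.to_csv(outdir / "section_counts.csv", index=False)
    _register(outdir, manifest, outdir / "section_counts.csv")
    loss = histology.percent_loss(counts["control"], counts["PD"])
    manifest["stages"]["histology"] = {
        "counts": counts,
        "percent_loss": loss.percent,
        "percent_loss_rounded": loss.rounded,
    }
    report += [
        "## Histology",
        "",
        _md_table(counts_df),
        "",
        f"- cell loss (PD vs control sections): {loss.rounded}% ({loss.percent:.2f} unrounded)",
        "",
    ]
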