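"""End-to-end workflows: the phantom accuracy study and the cohort analysis.

``run_phantom_study`` chains the whole quantitative pipeline — simulate a
uniform calibration cylinder, derive the conversion factor, simulate the body
phantom acquisition, calibrate it, and run the sphere-by-sphere CRC /
recovered-activity analysis. ``run_cohort_study`` produces the inter-scanner
tissue comparison, the intrapatient liver variability summary, and the
longitudinal tumor report from a synthetic (or user-supplied) cohort.

Each run can write its outputs plus a manifest (config hash, seed, package
version) so that identical manifests imply identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import config, io
from .calibration import apply_calibration, derive_conversion_factor
from .errors import ArgumentError
from .quantitation import CRCAnalysis, crc_analysis, report_percent
from .simulate import (CohortData, CohortSpec, PhantomSpec, ScannerProfile,
                       build_ground_truth, nema_iec_body_phantom,
                       simulate_acquisition, simulate_patient_cohort,
                       simulate_uniform_cylinder)
from .stats import (ScannerComparison, VariabilityResult, compare_scanners,
                    intrapatient_variability, iqr_summary, percent_reduction,
                    trajectory_report)

__version__ = "0.1.0"


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for the two study workflows."""
    seed: int = 0
    scanner: str = "symbia_lehr"
    spacing_mm: float = config.DEFAULT_SPACING_MM
    supersample: int = config.DEFAULT_SUPERSAMPLE
    # calibration cylinder
    cylinder_activity_kbq: float = config.CYLINDER_ACTIVITY_KBQ
    cylinder_volume_cm3: float = config.CYLINDER_VOLUME_CM3
    # phantom fill
    sphere_kbq_cm3: float = config.DEFAULT_SPHERE_KBQ_CM3
    background_kbq_cm3: float = config.DEFAULT_BACKGROUND_KBQ_CM3
    phantom_net_activity_kbq: float = config.PHANTOM_NET_ACTIVITY_KBQ
    phantom_weight_g: float = config.PHANTOM_WEIGHT_G
    # VOI / visibility
    voi_scale: float = 0.8
    n_background_vois: int = 12
    visibility_k: float = config.VISIBILITY_K
    # statistics
    exact_limit: int = config.EXACT_TEST_LIMIT
    alpha: float = config.ALPHA

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ArgumentError("alpha must lie in (0, 1)")


def stage_seeds(seed: int, n: int) -> list[int]:
    """Deterministically fan one study seed out to per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _manifest(cfg: PipelineConfig, kind: str) -> dict:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return {"kind": kind, "seed": cfg.seed, "version": __version__,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest()}


@dataclass
class PhantomStudyReport:
    table: pd.DataFrame          # one row per visible sphere plus background
    analysis: CRCAnalysis
    calibration: dict
    manifest: dict

    def text(self) -> str:
        lines = ["Phantom accuracy study", "======================", ""]
        lines.append(
            f"conversion factor: {self.calibration['kbq_per_count']:.6g} kBq/count "
            f"({self.calibration['count_rate_kcts_s']:.2f} kcts/s)")
        for r in self.analysis.spheres:
            lines.append(
                f"{r.sphere_diameter_mm:>4.0f} mm sphere  CRC {r.crc:5.2f}  "
                f"recovered {r.recovered_kbq_cm3:5.1f} kBq/cm3  "
                f"error {report_percent(r.percent_error):+d}%")
        bg = self.analysis.background
        lines.append(
            f"background      measured {bg.mean_kbq_cm3:5.1f} kBq/cm3  "
            f"error {report_percent(bg.percent_error):+d}%")
        if self.analysis.not_visible_mm:
            mm = ", ".join(f"{d:g}" for d in self.analysis.not_visible_mm)
            lines.append(f"not visible: {mm} mm sphere(s)")
        return "\n".join(lines) + "\n"


def run_phantom_study(cfg: PipelineConfig = PipelineConfig(),
                      spec: PhantomSpec | None = None,
                      profile: ScannerProfile | None = None,
                      outdir: str | Path | None = None) -> PhantomStudyReport:
    """Simulate and analyze the full phantom accuracy experiment."""
    if profile is None:
        profile = io.load_scanner_profile(cfg.scanner)
    if spec is None:
        spec = nema_iec_body_phantom(cfg.sphere_kbq_cm3, cfg.background_kbq_cm3)
    seed_cyl, seed_phantom = stage_seeds(cfg.seed, 2)

    counts_cyl, _ = simulate_uniform_cylinder(
        cfg.cylinder_activity_kbq, cfg.cylinder_volume_cm3, profile,
        seed=seed_cyl, spacing=cfg.spacing_mm, supersample=cfg.supersample)
    factor = derive_conversion_factor(
        counts_cyl, cfg.cylinder_activity_kbq, cfg.cylinder_volume_cm3,
        profile.acquisition_seconds, scanner=profile.name)

    truth = build_ground_truth(spec, spacing=cfg.spacing_mm,
                               supersample=cfg.supersample)
    counts = simulate_acquisition(truth, profile, seed=seed_phantom)
    calibrated = apply_calibration(counts, factor)
    analysis = crc_analysis(
        calibrated, spec, cfg.phantom_net_activity_kbq, cfg.phantom_weight_g,
        voi_scale=cfg.voi_scale, n_background=cfg.n_background_vois,
        visibility_k=cfg.visibility_k)

    rows = [{
        "label": f"{r.sphere_diameter_mm:g}mm",
        "sphere_diameter_mm": r.sphere_diameter_mm,
        "crc": r.crc, "suv_sphere": r.suv_sphere, "suv_bkgd": r.suv_bkgd,
        "recovered_kbq_cm3": r.recovered_kbq_cm3,
        "percent_error": r.percent_error,
        "reported_percent": report_percent(r.percent_error),
    } for r in analysis.spheres]
    bg = analysis.background
    rows.append({"label": "background", "sphere_diameter_mm": np.nan,
                 "crc": np.nan, "suv_sphere": np.nan, "suv_bkgd": np.nan,
                 "recovered_kbq_cm3": bg.mean_kbq_cm3,
                 "percent_error": bg.percent_error,
                 "reported_percent": report_percent(bg.percent_error)})
    report = PhantomStudyReport(
        table=pd.DataFrame(rows), analysis=analysis,
        calibration=dict(factor.derivation, kbq_per_count=factor.kbq_per_count,
                         rate_warning=factor.rate_warning),
        manifest=_manifest(cfg, "phantom-study"))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.table.to_csv(outdir / "crc_results.csv", index=False)
        (outdir / "report.txt").write_text(report.text())
        (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
    return report


@dataclass
class CohortStudyReport:
    comparison: ScannerComparison
    iqr: pd.DataFrame            # per tissue/scanner box summary
    variability: VariabilityResult | None
    trajectory: pd.DataFrame
    liver_segments: dict
    tumor_reduction_percent: float
    manifest: dict

    def text(self) -> str:
        c = self.comparison
        n_sig = int(c.table["significant"].sum())
        lines = ["Cohort analysis", "===============", ""]
        lines.append(f"tissues compared: {len(c.table)}; "
                     f"significant at alpha: {n_sig}; "
                     f"average p value {c.average_p:.3f}")
        lines.append("no significant differences" if n_sig == 0
                     else "significant differences present")
        if self.variability is not None:
            v = self.variability
            lines.append(
                f"intrapatient liver: min/max {v.overall_min:.1f}/{v.overall_max:.1f} "
                f"-> {v.reported_percent}%  cohort mean {v.cohort_mean:.1f} "
                f"(variance of the mean {v.variance_of_mean:.1f})")
        lines.append(f"tumor SUVmax reduction: {report_percent(self.tumor_reduction_percent)}%")
        return "\n".join(lines) + "\n"


def run_cohort_study(cfg: PipelineConfig = PipelineConfig(),
                     cohort_spec: CohortSpec | None = None,
                     cohort: CohortData | None = None,
                     outdir: str | Path | None = None) -> CohortStudyReport:
    """Simulate (or take) a two-camera cohort and run the study statistics."""
    if cohort is None:
        if cohort_spec is None:
            cohort_spec = CohortSpec()
        (cohort_seed,) = stage_seeds(cfg.seed, 1)
        cohort = simulate_patient_cohort(cohort_spec, seed=cohort_seed)

    by_scanner: dict[str, list] = {}
    for s in cohort.tissue_samples:
        by_scanner.setdefault(s.scanner, []).append(s)
    if len(by_scanner) != 2:
        raise ArgumentError(
            f"cohort must span exactly two scanners, got {sorted(by_scanner)}")
    name_a, name_b = sorted(by_scanner)
    comparison = compare_scanners(by_scanner[name_a], by_scanner[name_b],
                                  alpha=cfg.alpha, exact_limit=cfg.exact_limit)

    iqr_rows = []
    for s in cohort.tissue_samples:
        summary = iqr_summary(s.suvs)
        iqr_rows.append({"tissue": s.tissue, "scanner": s.scanner,
                         "median": summary.median, "q1": summary.q1,
                         "q3": summary.q3, "iqr": summary.iqr,
                         "n_outliers": len(summary.outliers)})
    iqr_table = pd.DataFrame(iqr_rows)

    liver = {p: grp["mean_suv"].tolist()
             for p, grp in cohort.liver_studies.groupby("patient_id")}
    multi = {p: v for p, v in liver.items() if len(v) >= 2}
    variability = intrapatient_variability(liver) if multi else None

    traj = trajectory_report(cohort.longitudinal)
    reduction = percent_reduction(cohort.longitudinal)

    report = CohortStudyReport(
        comparison=comparison, iqr=iqr_table, variability=variability,
        trajectory=traj.table, liver_segments=traj.liver_segments,
        tumor_reduction_percent=reduction,
        manifest=_manifest(cfg, "cohort-study"))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        comparison.table.to_csv(outdir / "comparison.csv", index=False)
        iqr_table.to_csv(outdir / "iqr_summary.csv", index=False)
        traj.table.to_csv(outdir / "trajectory.csv", index=False)
        (outdir / "report.txt").write_text(report.text())
        (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
    return report
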