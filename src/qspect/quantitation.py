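"""VOI measurement, SUV, contrast recovery, and activity-recovery accuracy.

The standardized uptake value normalizes a measured activity concentration
A_v (kBq/cm3) by the decay-corrected injected activity per unit body weight:

    SUV = A_v / (A / w)

In a phantom the SUV carries units of g/cm3; in tissue (density 1 g/cm3) it
is unitless. The contrast recovery coefficient compares measured to true
sphere-to-background contrast,

    CRC = (SUV_sphere / SUV_bkgd - 1) / (A_sphere / A_bkgd - 1),

and the partial-volume-corrected recovered activity is

    A_v(recovered) = SUV * (A / w) * [1 + (1 - CRC)].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import config
from .errors import (ArgumentError, ContrastRecoveryWarning, DataError,
                     GeometryError)
from .image import ActivityImage
from .simulate import PhantomSpec

__all__ = [
    "VOI", "VOIStats", "SUVMeasurement", "CRCResult", "BackgroundResult",
    "CRCAnalysis", "measure_voi", "compute_suv", "measure_suv", "compute_crc",
    "recover_activity", "percent_error", "report_percent", "background_vois",
    "crc_analysis",
]


@dataclass(frozen=True)
class VOI:
    """Spherical volume of interest (center and diameter in mm) or an explicit
    boolean voxel mask. Membership is voxel-center-inside-shape."""
    label: str
    center_mm: tuple[float, float, float] | None = None
    diameter_mm: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            if self.center_mm is None or self.diameter_mm is None:
                raise ArgumentError("VOI needs either a mask or center+diameter")
            if self.diameter_mm <= 0:
                raise ArgumentError("VOI diameter must be positive")

    def membership(self, image: ActivityImage) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != image.shape:
                raise GeometryError("VOI mask shape does not match the image")
            return self.mask.astype(bool)
        r = self.diameter_mm / 2.0
        cx, cy, cz = self.center_mm
        for ax, c in enumerate(self.center_mm):
            lo, hi = image.origin[ax], image.origin[ax] + image.spacing[ax] * (image.shape[ax] - 1)
            if c + r < lo - image.spacing[ax] or c - r > hi + image.spacing[ax]:
                raise GeometryError(f"VOI {self.label!r} lies outside the image")
        dx = image.axis_coords(0) - cx
        dy = image.axis_coords(1) - cy
        dz = image.axis_coords(2) - cz
        r2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        return r2 <= r * r


@dataclass(frozen=True)
class VOIStats:
    label: str
    mean: float
    max: float
    n_voxels: int


def measure_voi(image: ActivityImage, voi: VOI) -> VOIStats:
    """Mean and max of the image over the VOI's member voxels."""
    member = voi.membership(image)
    n = int(member.sum())
    if n == 0:
        raise GeometryError(f"VOI {voi.label!r} contains no voxel centers")
    vals = image.voxels[member]
    return VOIStats(voi.label, float(vals.mean()), float(vals.max()), n)


def compute_suv(a_v_kbq_cm3: float, injected_kbq: float, weight_g: float) -> float:
    """SUV = A_v / (A / w), with A decay-corrected to the scan start."""
    if injected_kbq <= 0:
        raise ArgumentError("injected activity must be positive")
    if weight_g <= 0:
        raise ArgumentError("weight must be positive")
    return a_v_kbq_cm3 * weight_g / injected_kbq


@dataclass(frozen=True)
class SUVMeasurement:
    voi_label: str
    mean_suv: float
    max_suv: float
    n_voxels: int
    units: str = "g_per_cm3"  # phantom convention; tissue SUV is unitless

    def __post_init__(self) -> None:
        if not (self.max_suv >= self.mean_suv >= 0):
            raise DataError("SUV measurement must satisfy max >= mean >= 0")


def measure_suv(image: ActivityImage, voi: VOI, injected_kbq: float,
                weight_g: float, tissue: bool = False) -> SUVMeasurement:
    """Measure a VOI and express its mean/max as SUV.

    Accepts a concentration image (kBq/cm3, converted through the SUV
    formula) or an image already in SUV units.
    """
    stats = measure_voi(image, voi)
    if image.units == "suv":
        mean, mx = stats.mean, stats.max
    elif image.units == "kBq_per_cm3":
        mean = compute_suv(stats.mean, injected_kbq, weight_g)
        mx = compute_suv(stats.max, injected_kbq, weight_g)
    else:
        raise ArgumentError("SUV needs a concentration or SUV image, not counts")
    return SUVMeasurement(voi.label, mean, mx, stats.n_voxels,
                          units="unitless" if tissue else "g_per_cm3")


def compute_crc(suv_sphere: float, suv_bkgd: float,
                a_sphere_kbq_cm3: float, a_bkgd_kbq_cm3: float) -> float:
    """Contrast recovery coefficient of a hot sphere against background."""
    if suv_bkgd <= 0:
        raise DataError("background SUV must be positive")
    if a_bkgd_kbq_cm3 <= 0 or a_sphere_kbq_cm3 == a_bkgd_kbq_cm3:
        raise ArgumentError(
            "true sphere/background contrast is undefined (equal or non-positive "
            "concentrations)")
    return ((suv_sphere / suv_bkgd) - 1.0) / ((a_sphere_kbq_cm3 / a_bkgd_kbq_cm3) - 1.0)


def recover_activity(suv: float, injected_kbq: float, weight_g: float,
                     crc: float) -> float:
    """Partial-volume-corrected activity concentration (kBq/cm3):
    SUV * (A/w) * (2 - CRC). CRC > 1 passes through with a warning."""
    if injected_kbq <= 0 or weight_g <= 0:
        raise ArgumentError("injected activity and weight must be positive")
    if crc < 0:
        raise ArgumentError("CRC must be >= 0")
    if crc > 1:
        warnings.warn(f"CRC {crc:.3f} exceeds 1; applying the correction as-is",
                      ContrastRecoveryWarning, stacklevel=2)
    return suv * (injected_kbq / weight_g) * (2.0 - crc)


def percent_error(measured: float, actual: float) -> float:
    """Signed percent deviation of measured from actual."""
    if actual <= 0:
        raise ArgumentError("actual value must be positive")
    return 100.0 * (measured / actual - 1.0)


def report_percent(value: float) -> int:
    """Round to integer percent, halves away from zero (reporting convention)."""
    return int(math.copysign(math.floor(abs(value) + 0.5), value))


# ---------------------------------------------------------------------------
# Phantom CRC analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRCResult:
    sphere_diameter_mm: float
    crc: float
    suv_sphere: float
    suv_bkgd: float
    recovered_kbq_cm3: float
    percent_error: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.crc):
            raise DataError("CRC must be finite")
        if self.recovered_kbq_cm3 < 0:
            raise DataError("recovered activity must be >= 0")


@dataclass(frozen=True)
class BackgroundResult:
    mean_kbq_cm3: float
    voxel_sd_kbq_cm3: float
    percent_error: float
    n_vois: int


@dataclass(frozen=True)
class CRCAnalysis:
    spheres: tuple[CRCResult, ...]
    not_visible_mm: tuple[float, ...]
    background: BackgroundResult
    visibility_threshold: float


def background_vois(spec: PhantomSpec, n: int = 12, diameter_mm: float = 30.0,
                    clearance_mm: float = 25.0, min_separation_mm: float = 32.0,
                    ) -> list[VOI]:
    """Deterministic background VOI placement in the central transverse plane.

    Candidate centers on a polar grid are kept when they sit at least
    ``clearance_mm`` inside the body wall and at least ``clearance_mm`` from
    the surface of every insert; ``n`` of them are then chosen greedily to
    maximize mutual separation.
    """
    a, b = spec.body_semi_axes_mm
    sa, sb = a - clearance_mm, b - clearance_mm
    if sa <= 0 or sb <= 0:
        raise GeometryError("clearance exceeds the body cross-section")
    lung_r = (spec.lung_insert.outer_diameter_mm / 2.0
              if spec.lung_insert is not None else 0.0)
    cands = []
    for radius in np.arange(lung_r + clearance_mm, max(a, b), 4.0):
        for ang in np.arange(0.0, 360.0, 5.0):
            x = radius * math.cos(math.radians(ang))
            y = radius * math.sin(math.radians(ang))
            if (x / sa) ** 2 + (y / sb) ** 2 > 1.0:
                continue
            if any(math.dist((x, y, 0.0), s.center_mm) < clearance_mm + s.radius_mm
                   for s in spec.spheres):
                continue
            cands.append((x, y))
    if not cands:
        raise GeometryError("no admissible background VOI position")
    # greedy farthest-point selection, seeded at the candidate farthest from
    # all inserts (deterministic)
    def insert_dist(p):
        d = [math.dist((p[0], p[1], 0.0), s.center_mm) - s.radius_mm
             for s in spec.spheres]
        d.append(math.hypot(p[0], p[1]) - lung_r)
        return min(d) if d else math.inf

    chosen = [max(cands, key=insert_dist)]
    rest = [c for c in cands if c != chosen[0]]
    while len(chosen) < n and rest:
        best = max(rest, key=lambda c: min(math.dist(c, q) for q in chosen))
        if min(math.dist(best, q) for q in chosen) < min_separation_mm:
            break
        chosen.append(best)
        rest.remove(best)
    if len(chosen) < 3:
        raise GeometryError(
            f"only {len(chosen)} background VOIs could be placed (need >= 3)")
    return [VOI(label=f"bkgd{k + 1:02d}", center_mm=(x, y, 0.0),
                diameter_mm=diameter_mm) for k, (x, y) in enumerate(chosen)]


def crc_analysis(image: ActivityImage, spec: PhantomSpec, injected_kbq: float,
                 weight_g: float, voi_scale: float = 0.8,
                 n_background: int = 12, background_diameter_mm: float = 30.0,
                 background_clearance_mm: float = 25.0,
                 visibility_k: float = config.VISIBILITY_K) -> CRCAnalysis:
    """Full sphere-by-sphere CRC and recovered-activity accuracy analysis.

    The sphere VOI is the full inner diameter at the known center (scaled by
    ``voi_scale``); the background SUV is the mean of the background-VOI
    means. Spheres whose VOI mean does not exceed background mean +
    ``visibility_k`` * background voxel SD are reported as not visible and
    excluded from the CRC calculation.
    """
    if image.units not in ("kBq_per_cm3", "suv"):
        raise ArgumentError("crc_analysis needs a concentration or SUV image")
    if not spec.spheres:
        raise GeometryError("phantom spec has no spheres")
    if spec.background_kbq_cm3 <= 0:
        raise ArgumentError("CRC is undefined for a cold background")

    bvois = background_vois(spec, n=n_background,
                            diameter_mm=background_diameter_mm,
                            clearance_mm=background_clearance_mm)
    bstats = [measure_voi(image, v) for v in bvois]
    bkgd_mean = float(np.mean([s.mean for s in bstats]))
    pooled = np.concatenate([image.voxels[v.membership(image)] for v in bvois])
    bkgd_sd = float(pooled.std(ddof=1))
    threshold = bkgd_mean + visibility_k * bkgd_sd

    def to_suv(x: float) -> float:
        return x if image.units == "suv" else compute_suv(x, injected_kbq, weight_g)

    def to_conc(x: float) -> float:
        return x if image.units == "kBq_per_cm3" else x * injected_kbq / weight_g

    suv_bkgd = to_suv(bkgd_mean)
    results, invisible = [], []
    for s in sorted(spec.spheres, key=lambda s: s.inner_diameter_mm):
        voi = VOI(label=f"sphere{s.inner_diameter_mm:g}mm", center_mm=s.center_mm,
                  diameter_mm=s.inner_diameter_mm * voi_scale)
        st = measure_voi(image, voi)
        if st.mean <= threshold:
            invisible.append(s.inner_diameter_mm)
            continue
        suv_sphere = to_suv(st.mean)
        crc = compute_crc(suv_sphere, suv_bkgd, s.concentration_kbq_cm3,
                          spec.background_kbq_cm3)
        # visibility (mean above background) guarantees crc > 0 here
        recovered = recover_activity(suv_sphere, injected_kbq, weight_g, crc)
        results.append(CRCResult(
            sphere_diameter_mm=s.inner_diameter_mm, crc=crc,
            suv_sphere=suv_sphere, suv_bkgd=suv_bkgd,
            recovered_kbq_cm3=recovered,
            percent_error=percent_error(recovered, s.concentration_kbq_cm3)))

    background = BackgroundResult(
        mean_kbq_cm3=to_conc(bkgd_mean),
        voxel_sd_kbq_cm3=to_conc(bkgd_sd),
        percent_error=percent_error(to_conc(bkgd_mean), spec.background_kbq_cm3),
        n_vois=len(bvois))
    return CRCAnalysis(tuple(results), tuple(invisible), background,
                       visibility_threshold=threshold)
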