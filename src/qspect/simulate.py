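"""Synthetic phantoms, a parametric camera forward model, and patient cohorts.

Ground truth is rasterized on a reconstructed-style voxel grid: an elliptical-
cylinder body filled with background activity, a cold cylindrical lung insert,
and hot spheres on a ring in the central transverse plane. Boundary voxels are
antialiased by midpoint supersampling so that voxel sums conserve the analytic
activity integral.

The camera is modelled in the reconstructed domain: an isotropic Gaussian
point-spread function (the partial-volume mechanism that contrast recovery
measures), a sensitivity that maps activity to expected counts, and optional
Poisson counting noise. Attenuation, scatter and projection-space effects are
deliberately absent; the profile parameters summarize their net effect on the
final images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from . import config
from .errors import ArgumentError, DataError, GeometryError
from .image import ActivityImage, centered_grid

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereInsert:
    """A fillable sphere: inner diameter, center position and fill."""
    inner_diameter_mm: float
    center_mm: tuple[float, float, float]
    fill_volume_cm3: float
    concentration_kbq_cm3: float

    @property
    def radius_mm(self) -> float:
        return self.inner_diameter_mm / 2.0


@dataclass(frozen=True)
class LungInsert:
    """Central low-density insert, modelled as a zero-activity cylinder."""
    outer_diameter_mm: float = config.LUNG_INSERT_DIAMETER_MM
    length_mm: float = config.BODY_LENGTH_MM
    concentration_kbq_cm3: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and ground-truth concentrations of a body phantom."""
    body_semi_axes_mm: tuple[float, float] = config.BODY_SEMI_AXES_MM
    body_length_mm: float = config.BODY_LENGTH_MM
    spheres: tuple[SphereInsert, ...] = ()
    lung_insert: LungInsert | None = None
    background_kbq_cm3: float = config.DEFAULT_BACKGROUND_KBQ_CM3
    total_fill_volume_cm3: float = config.PHANTOM_CAPACITY_CM3

    def __post_init__(self) -> None:
        if self.background_kbq_cm3 < 0:
            raise ArgumentError("background concentration must be >= 0")
        a, b = self.body_semi_axes_mm
        if a <= 0 or b <= 0 or self.body_length_mm <= 0:
            raise ArgumentError("body dimensions must be positive")
        for s in self.spheres:
            if s.inner_diameter_mm <= 0:
                raise ArgumentError("sphere diameters must be positive")
            if s.concentration_kbq_cm3 < 0:
                raise ArgumentError("sphere concentrations must be >= 0")
            self._check_inside_body(s)
        for i, s1 in enumerate(self.spheres):
            for s2 in self.spheres[i + 1:]:
                d = math.dist(s1.center_mm, s2.center_mm)
                if d < s1.radius_mm + s2.radius_mm:
                    raise GeometryError(
                        f"spheres of {s1.inner_diameter_mm} and {s2.inner_diameter_mm} mm overlap")
        if self.lung_insert is not None:
            lr = self.lung_insert.outer_diameter_mm / 2.0
            for s in self.spheres:
                x, y, z = s.center_mm
                if (abs(z) - s.radius_mm < self.lung_insert.length_mm / 2.0
                        and math.hypot(x, y) < lr + s.radius_mm):
                    raise GeometryError(
                        f"{s.inner_diameter_mm} mm sphere overlaps the lung insert")

    def _check_inside_body(self, s: SphereInsert) -> None:
        a, b = self.body_semi_axes_mm
        x, y, z = s.center_mm
        r = s.radius_mm
        if a - r <= 0 or b - r <= 0:
            raise GeometryError("sphere larger than the body cross-section")
        if (x / (a - r)) ** 2 + (y / (b - r)) ** 2 > 1.0 or abs(z) + r > self.body_length_mm / 2.0:
            raise GeometryError(
                f"{s.inner_diameter_mm} mm sphere at {s.center_mm} extends outside the body")

    @property
    def sphere_diameters_mm(self) -> tuple[float, ...]:
        return tuple(s.inner_diameter_mm for s in self.spheres)


def nema_iec_body_phantom(sphere_kbq_cm3: float = config.DEFAULT_SPHERE_KBQ_CM3,
                          background_kbq_cm3: float = config.DEFAULT_BACKGROUND_KBQ_CM3,
                          ) -> PhantomSpec:
    """The NEMA IEC body phantom with its six spheres (10-37 mm) on a 57.2 mm
    ring in the central transverse plane and a cold central lung insert."""
    spheres = []
    ring = config.SPHERE_RING_RADIUS_MM
    # largest sphere at 0 degrees, then descending diameter every 60 degrees
    for k, (d, v) in enumerate(zip(reversed(config.SPHERE_DIAMETERS_MM),
                                   reversed(config.SPHERE_FILL_VOLUMES_CM3))):
        ang = math.radians(60.0 * k)
        center = (ring * math.cos(ang), ring * math.sin(ang), 0.0)
        spheres.append(SphereInsert(d, center, v, sphere_kbq_cm3))
    return PhantomSpec(
        spheres=tuple(sorted(spheres, key=lambda s: s.inner_diameter_mm)),
        lung_insert=LungInsert(),
        background_kbq_cm3=background_kbq_cm3,
    )


@dataclass(frozen=True)
class ScannerProfile:
    """Parametric camera: PSF width, sensitivity, acquisition time, noise.

    ``sensitivity`` is the expected number of counts recorded per kBq of
    in-field activity per second of acquisition. It is an *effective*
    information-content parameter of the reconstructed images, not a physical
    crystal sensitivity.
    """
    name: str
    psf_fwhm_mm: float
    sensitivity_counts_per_kbq_s: float = 2.0e-3
    acquisition_seconds: float = config.DEFAULT_ACQUISITION_SECONDS
    noise: bool = True
    calibration_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ArgumentError("psf_fwhm_mm must be >= 0")
        if self.sensitivity_counts_per_kbq_s <= 0:
            raise ArgumentError("sensitivity must be > 0")
        if self.acquisition_seconds <= 0:
            raise ArgumentError("acquisition_seconds must be > 0")


#: GE Infinia Hawkeye 4 with medium-energy collimators (stand-in).
INFINIA_ME = ScannerProfile(name="infinia_me", psf_fwhm_mm=15.0)
#: Siemens Symbia Intevo with low-energy high-resolution collimators (stand-in).
SYMBIA_LEHR = ScannerProfile(name="symbia_lehr", psf_fwhm_mm=13.0)

DEFAULT_PROFILES = {p.name: p for p in (INFINIA_ME, SYMBIA_LEHR)}


# ---------------------------------------------------------------------------
# Rasterization helpers (midpoint supersampling)
# ---------------------------------------------------------------------------

def _subcenters(n: int, origin: float, spacing: float, ss: int) -> np.ndarray:
    """Coordinates of the ss midpoint subsamples of each of n voxels (n*ss,)."""
    base = origin + spacing * np.arange(n)
    off = ((np.arange(ss) + 0.5) / ss - 0.5) * spacing
    return (base[:, None] + off[None, :]).ravel()


def _ellipse_fraction(nx: int, ny: int, ox: float, oy: float, spacing: float,
                      a: float, b: float, ss: int) -> np.ndarray:
    xs = _subcenters(nx, ox, spacing, ss)
    ys = _subcenters(ny, oy, spacing, ss)
    inside = (xs[:, None] / a) ** 2 + (ys[None, :] / b) ** 2 <= 1.0
    return inside.reshape(nx, ss, ny, ss).mean(axis=(1, 3))


def _interval_fraction(n: int, origin: float, spacing: float,
                       lo: float, hi: float, ss: int) -> np.ndarray:
    z = origin + spacing * np.arange(n)
    if ss <= 1:  # voxel-center membership
        return ((z >= lo) & (z <= hi)).astype(float)
    zlo, zhi = z - spacing / 2.0, z + spacing / 2.0
    return np.clip((np.minimum(zhi, hi) - np.maximum(zlo, lo)) / spacing, 0.0, 1.0)


def _sphere_fraction(img_shape, origin, spacing: float, center, radius: float,
                     ss: int) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Volume fraction of a sphere in each voxel of its bounding box."""
    idx, subs = [], []
    for ax in range(3):
        lo = int(math.floor((center[ax] - radius - origin[ax]) / spacing - 0.5))
        hi = int(math.ceil((center[ax] + radius - origin[ax]) / spacing + 0.5))
        lo, hi = max(lo, 0), min(hi, img_shape[ax] - 1)
        if hi < lo:
            raise GeometryError("sphere lies outside the image grid")
        idx.append(slice(lo, hi + 1))
        subs.append(_subcenters(hi - lo + 1, origin[ax] + lo * spacing, spacing, ss)
                    - center[ax])
    dx, dy, dz = subs
    r2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
    inside = r2 <= radius * radius
    nx, ny, nz = (s.stop - s.start for s in idx)
    frac = inside.reshape(nx, ss, ny, ss, nz, ss).mean(axis=(1, 3, 5))
    return tuple(idx), frac  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Ground truth and forward model
# ---------------------------------------------------------------------------

def build_ground_truth(spec: PhantomSpec,
                       spacing: float = config.DEFAULT_SPACING_MM,
                       supersample: int = config.DEFAULT_SUPERSAMPLE,
                       margin_mm: float = 30.0) -> ActivityImage:
    """Rasterize a phantom onto a voxel grid of the given isotropic spacing.

    Returns an image in kBq/cm3 whose voxels inside each structure equal the
    structure's concentration; voxels straddling a boundary receive the
    volume-fraction-weighted mixture (``supersample`` midpoints per axis;
    ``supersample=1`` degenerates to voxel-center membership).
    """
    if spacing <= 0:
        raise ArgumentError("spacing must be positive")
    if supersample < 1:
        raise ArgumentError("supersample must be >= 1")
    a, b = spec.body_semi_axes_mm
    extent = (2 * a + 2 * margin_mm, 2 * b + 2 * margin_mm,
              spec.body_length_mm + 2 * margin_mm)
    shape, origin = centered_grid(extent, spacing)
    if min(shape) < 32:
        raise ArgumentError(
            f"spacing {spacing} mm yields grid {shape}; need >= 32 voxels per axis")

    ss = int(supersample)
    body2d = _ellipse_fraction(shape[0], shape[1], origin[0], origin[1], spacing, a, b, ss)
    bodyz = _interval_fraction(shape[2], origin[2], spacing,
                               -spec.body_length_mm / 2.0, spec.body_length_mm / 2.0, ss)
    body = body2d[:, :, None] * bodyz[None, None, :]

    vox = spec.background_kbq_cm3 * body

    if spec.lung_insert is not None:
        lr = spec.lung_insert.outer_diameter_mm / 2.0
        lung2d = _ellipse_fraction(shape[0], shape[1], origin[0], origin[1],
                                   spacing, lr, lr, ss)
        lungz = _interval_fraction(shape[2], origin[2], spacing,
                                   -spec.lung_insert.length_mm / 2.0,
                                   spec.lung_insert.length_mm / 2.0, ss)
        lung = lung2d[:, :, None] * lungz[None, None, :]
        vox += (spec.lung_insert.concentration_kbq_cm3 - spec.background_kbq_cm3) * lung

    for s in spec.spheres:
        idx, frac = _sphere_fraction(shape, origin, spacing, s.center_mm, s.radius_mm, ss)
        vox[idx] += (s.concentration_kbq_cm3 - spec.background_kbq_cm3) * frac

    np.maximum(vox, 0.0, out=vox)
    return ActivityImage(vox, (spacing,) * 3, "kBq_per_cm3", origin,
                         meta={"phantom": "body", "supersample": ss})


def simulate_acquisition(truth: ActivityImage, profile: ScannerProfile,
                         seed: int | None = None) -> ActivityImage:
    """Forward-project a truth concentration image into a count image.

    counts ~ Poisson(sensitivity * T * voxel_volume * blur(truth) * bias)
    with the blur an isotropic Gaussian of the profile's FWHM; without noise
    the expectation itself is returned.
    """
    if truth.units != "kBq_per_cm3":
        raise ArgumentError("simulate_acquisition expects a kBq_per_cm3 truth image")
    if np.any(truth.voxels < 0):
        raise DataError("truth image contains negative activity")
    if profile.psf_fwhm_mm > 0:
        sigma = [profile.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in truth.spacing]
        blurred = ndimage.gaussian_filter(truth.voxels, sigma=sigma,
                                          mode="constant", truncate=5.0)
    else:
        blurred = truth.voxels
    lam = (profile.sensitivity_counts_per_kbq_s * profile.acquisition_seconds
           * truth.voxel_volume_cm3 * profile.calibration_bias) * blurred
    if profile.noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam).astype(np.float64)
    else:
        counts = lam
    meta = dict(truth.meta)
    meta.update(scanner=profile.name, seed=seed, noise=profile.noise,
                acquisition_seconds=profile.acquisition_seconds)
    return ActivityImage(counts, truth.spacing, "counts", truth.origin, meta)


def build_uniform_cylinder_truth(concentration_kbq_cm3: float, volume_cm3: float,
                                 radius_mm: float = config.CYLINDER_RADIUS_MM,
                                 spacing: float = config.DEFAULT_SPACING_MM,
                                 supersample: int = config.DEFAULT_SUPERSAMPLE,
                                 margin_mm: float = 30.0) -> ActivityImage:
    """Uniform cylinder of the given volume (length follows from the radius)."""
    length_mm = volume_cm3 * 1000.0 / (math.pi * radius_mm ** 2)
    extent_z = max(length_mm + 2 * margin_mm, 32 * spacing)
    shape, origin = centered_grid(
        (2 * radius_mm + 2 * margin_mm, 2 * radius_mm + 2 * margin_mm, extent_z), spacing)
    ss = int(supersample)
    disc = _ellipse_fraction(shape[0], shape[1], origin[0], origin[1], spacing,
                             radius_mm, radius_mm, ss)
    zfrac = _interval_fraction(shape[2], origin[2], spacing,
                               -length_mm / 2.0, length_mm / 2.0, ss)
    vox = concentration_kbq_cm3 * disc[:, :, None] * zfrac[None, None, :]
    return ActivityImage(vox, (spacing,) * 3, "kBq_per_cm3", origin,
                         meta={"phantom": "cylinder", "length_mm": length_mm,
                               "radius_mm": radius_mm})


def simulate_uniform_cylinder(activity_kbq: float, volume_cm3: float,
                              profile: ScannerProfile, seed: int | None = None,
                              spacing: float = config.DEFAULT_SPACING_MM,
                              supersample: int = config.DEFAULT_SUPERSAMPLE,
                              ) -> tuple[ActivityImage, float]:
    """Acquire a uniform calibration cylinder of known activity and volume.

    Returns the count image and the true concentration activity/volume.
    """
    if activity_kbq <= 0 or volume_cm3 <= 0:
        raise ArgumentError("activity and volume must be positive")
    truth_concentration = activity_kbq / volume_cm3
    truth = build_uniform_cylinder_truth(truth_concentration, volume_cm3,
                                         spacing=spacing, supersample=supersample)
    counts = simulate_acquisition(truth, profile, seed)
    return counts, truth_concentration


# ---------------------------------------------------------------------------
# Patient cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Distribution parameters for a synthetic two-camera patient cohort.

    ``tissues`` maps tissue label -> scanner name -> (mean SUV, SD, n). Tissue
    mean-SUV draws come from a normal truncated at zero. The longitudinal
    series follows ``tumor_suvmax`` plus Gaussian noise of ``tumor_noise_sd``,
    with a per-scanner liver background reference.
    """
    tissues: dict[str, dict[str, tuple[float, float, int]]] = field(
        default_factory=lambda: {t: dict(v) for t, v in config.TABLE1_TISSUES.items()})
    n_patients: int = 28
    study_counts: dict[int, int] = field(
        default_factory=lambda: dict(config.STUDY_COUNT_DISTRIBUTION))
    liver_reference: tuple[float, float] = config.LIVER_REFERENCE
    tumor_weeks: tuple[float, ...] = config.TUMOR_WEEKS
    tumor_suvmax: tuple[float, ...] = config.TUMOR_SUVMAX
    tumor_scanners: tuple[str, ...] = config.TUMOR_SCANNERS
    tumor_noise_sd: float = 0.0
    liver_segments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(config.LIVER_SEGMENTS))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ArgumentError("n_patients must be >= 1")
        for t, per_scanner in self.tissues.items():
            for sc, (mean, sd, n) in per_scanner.items():
                if sd < 0:
                    raise ArgumentError(f"SD for {t}/{sc} must be >= 0")
                if n < 1:
                    raise ArgumentError(f"n for {t}/{sc} must be >= 1")
        if self.liver_reference[1] < 0 or self.tumor_noise_sd < 0:
            raise ArgumentError("SDs must be >= 0")
        if len(self.tumor_weeks) != len(self.tumor_suvmax) or \
                len(self.tumor_weeks) != len(self.tumor_scanners):
            raise ArgumentError("tumor trajectory fields must have equal length")
        if any(b <= a for a, b in zip(self.tumor_weeks, self.tumor_weeks[1:])):
            raise ArgumentError("tumor weeks must be strictly increasing")


@dataclass
class TissueSample:
    """Per-tissue, per-scanner collection of mean SUV measurements."""
    tissue: str
    scanner: str
    suvs: np.ndarray

    def __post_init__(self) -> None:
        self.suvs = np.asarray(self.suvs, dtype=float)
        if self.suvs.size == 0:
            raise ArgumentError("tissue sample must be non-empty")
        if np.any(self.suvs < 0):
            raise DataError("SUVs must be >= 0")

    @property
    def n(self) -> int:
        return int(self.suvs.size)


@dataclass
class LongitudinalSeries:
    """Time-ordered tumor SUVmax with a liver reference, per scanner segment."""
    subject: str
    weeks: np.ndarray
    tumor_suvmax: np.ndarray
    liver_mean_suv: np.ndarray
    scanner: tuple[str, ...]

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=float)
        self.tumor_suvmax = np.asarray(self.tumor_suvmax, dtype=float)
        self.liver_mean_suv = np.asarray(self.liver_mean_suv, dtype=float)
        n = self.weeks.size
        if not (self.tumor_suvmax.size == n == self.liver_mean_suv.size == len(self.scanner)):
            raise ArgumentError("series fields must have equal length")
        if np.any(np.diff(self.weeks) <= 0):
            raise ArgumentError("weeks must be strictly increasing")
        if np.any(self.tumor_suvmax < 0) or np.any(self.liver_mean_suv < 0):
            raise DataError("SUVs must be >= 0")


@dataclass
class CohortData:
    """Everything simulate_patient_cohort produces."""
    tissue_samples: list[TissueSample]
    liver_studies: "pd.DataFrame"  # columns: patient_id, study, scanner, mean_suv
    longitudinal: LongitudinalSeries


def _truncnorm_at_zero(rng: np.random.Generator, mean: float, sd: float,
                       size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_patient_cohort(spec: CohortSpec, seed: int | None = None) -> CohortData:
    """Draw a reproducible synthetic cohort from the spec's distributions."""
    import pandas as pd

    rng = np.random.default_rng(spec.seed if seed is None else seed)

    samples = []
    for tissue in sorted(spec.tissues):
        for scanner in sorted(spec.tissues[tissue]):
            mean, sd, n = spec.tissues[tissue][scanner]
            samples.append(TissueSample(tissue, scanner,
                                        _truncnorm_at_zero(rng, mean, sd, n)))

    # intrapatient liver follow-up: patients imaged on both cameras
    counts = []
    for k in sorted(spec.study_counts):
        counts.extend([k] * spec.study_counts[k])
    while len(counts) < spec.n_patients:
        counts.append(2)
    counts = counts[:spec.n_patients]
    lmean, lsd = spec.liver_reference
    rows = []
    for p, n_studies in enumerate(counts):
        vals = _truncnorm_at_zero(rng, lmean, lsd, n_studies)
        for j, v in enumerate(vals):
            scanner = "infinia_me" if j < max(1, n_studies // 2) else "symbia_lehr"
            rows.append({"patient_id": f"P{p + 1:03d}", "study": j + 1,
                         "scanner": scanner, "mean_suv": float(v)})
    liver = pd.DataFrame(rows)

    tumor = np.asarray(spec.tumor_suvmax, dtype=float)
    if spec.tumor_noise_sd > 0:
        tumor = np.maximum(tumor + rng.normal(0.0, spec.tumor_noise_sd, tumor.size), 0.0)
    liver_ref = np.array([
        _truncnorm_at_zero(rng, *spec.liver_segments[sc], size=1)[0]
        for sc in spec.tumor_scanners])
    series = LongitudinalSeries("case-1", spec.tumor_weeks, tumor, liver_ref,
                                tuple(spec.tumor_scanners))
    return CohortData(samples, liver, series)
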