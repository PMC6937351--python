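"""Readers and writers: NIfTI volumes with a units sidecar, YAML specs, CSV.

Volumes are stored as NIfTI-1 (float32) with the voxel spacing in the header
and the origin in the affine translation; the units tag and any acquisition
metadata live in a JSON sidecar next to the volume (``image.nii.gz`` +
``image.json``). A missing sidecar defaults the units to ``counts`` with a
warning.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import simulate
from .errors import ArgumentError, DataError
from .image import ActivityImage
from .simulate import (CohortSpec, LungInsert, PhantomSpec, ScannerProfile,
                       SphereInsert)

COHORT_COLUMNS = ["patient_id", "study_date", "scanner", "tissue",
                  "mean_suv", "max_suv"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_image(image: ActivityImage, path) -> Path:
    path = Path(path)
    affine = np.diag(list(image.spacing) + [1.0])
    affine[:3, 3] = image.origin
    nii = nib.Nifti1Image(image.voxels.astype(np.float32), affine)
    nii.header.set_zooms(image.spacing)
    nib.save(nii, str(path))
    # exact grid geometry goes in the sidecar: the NIfTI header holds float32
    meta = {"units": image.units, "spacing": list(image.spacing),
            "origin": list(image.origin)}
    meta.update({k: v for k, v in image.meta.items()
                 if isinstance(v, (str, int, float, bool, type(None)))})
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image(path) -> ActivityImage:
    path = Path(path)
    try:
        nii = nib.load(str(path))
        voxels = np.asarray(nii.dataobj, dtype=np.float64)
    except Exception as exc:  # corrupt header or unreadable file
        raise DataError(f"cannot read NIfTI volume {path}: {exc}") from exc
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise DataError(f"non-positive voxel spacing {spacing} in {path}")
    origin = tuple(float(v) for v in nii.affine[:3, 3])
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "spacing" in meta:
            spacing = tuple(float(s) for s in meta.pop("spacing"))
            if any(s <= 0 for s in spacing):
                raise DataError(f"non-positive voxel spacing {spacing} in {sidecar}")
        origin = tuple(float(o) for o in meta.pop("origin", origin))
        units = meta.pop("units", None)
        if units is None:
            warnings.warn(f"sidecar {sidecar} lacks a units tag; assuming counts",
                          UserWarning, stacklevel=2)
            units = "counts"
    else:
        warnings.warn(f"no units sidecar next to {path}; assuming counts",
                      UserWarning, stacklevel=2)
        meta, units = {}, "counts"
    return ActivityImage(voxels, spacing, units, origin, meta)


# ---------------------------------------------------------------------------
# YAML specifications
# ---------------------------------------------------------------------------

def phantom_spec_to_dict(spec: PhantomSpec) -> dict:
    d = {
        "body": {"semi_axes_mm": list(spec.body_semi_axes_mm),
                 "length_mm": spec.body_length_mm},
        "background_kbq_cm3": spec.background_kbq_cm3,
        "total_fill_volume_cm3": spec.total_fill_volume_cm3,
        "spheres": [{
            "inner_diameter_mm": s.inner_diameter_mm,
            "center_mm": list(s.center_mm),
            "fill_volume_cm3": s.fill_volume_cm3,
            "concentration_kbq_cm3": s.concentration_kbq_cm3,
        } for s in spec.spheres],
    }
    if spec.lung_insert is not None:
        d["lung_insert"] = {
            "outer_diameter_mm": spec.lung_insert.outer_diameter_mm,
            "length_mm": spec.lung_insert.length_mm,
            "concentration_kbq_cm3": spec.lung_insert.concentration_kbq_cm3,
        }
    return d


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    body = d.get("body", {})
    lung = d.get("lung_insert")
    return PhantomSpec(
        body_semi_axes_mm=tuple(body.get("semi_axes_mm", (150.0, 110.0))),
        body_length_mm=float(body.get("length_mm", 186.0)),
        spheres=tuple(SphereInsert(
            inner_diameter_mm=float(s["inner_diameter_mm"]),
            center_mm=tuple(float(c) for c in s["center_mm"]),
            fill_volume_cm3=float(s.get("fill_volume_cm3", 0.0)),
            concentration_kbq_cm3=float(s["concentration_kbq_cm3"]),
        ) for s in d.get("spheres", [])),
        lung_insert=None if lung is None else LungInsert(
            outer_diameter_mm=float(lung["outer_diameter_mm"]),
            length_mm=float(lung["length_mm"]),
            concentration_kbq_cm3=float(lung.get("concentration_kbq_cm3", 0.0))),
        background_kbq_cm3=float(d["background_kbq_cm3"]),
        total_fill_volume_cm3=float(d.get("total_fill_volume_cm3", 9650.0)),
    )


def load_phantom_spec(path) -> PhantomSpec:
    return phantom_spec_from_dict(yaml.safe_load(Path(path).read_text()))


def save_phantom_spec(spec: PhantomSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(phantom_spec_to_dict(spec), sort_keys=False))


def default_nema_spec() -> PhantomSpec:
    """The bundled NEMA IEC body phantom description."""
    with resources.files("qspect.data").joinpath("nema_iec_default.yaml").open() as fh:
        return phantom_spec_from_dict(yaml.safe_load(fh))


def load_scanner_profile(path_or_name) -> ScannerProfile:
    """A profile YAML file, or the name of a built-in profile."""
    if str(path_or_name) in simulate.DEFAULT_PROFILES:
        return simulate.DEFAULT_PROFILES[str(path_or_name)]
    path = Path(path_or_name)
    if not path.exists():
        raise ArgumentError(
            f"unknown scanner profile {path_or_name!r}; built-ins: "
            f"{sorted(simulate.DEFAULT_PROFILES)}")
    d = yaml.safe_load(path.read_text())
    return ScannerProfile(
        name=d["name"], psf_fwhm_mm=float(d["psf_fwhm_mm"]),
        sensitivity_counts_per_kbq_s=float(
            d.get("sensitivity_counts_per_kbq_s", 2.0e-3)),
        acquisition_seconds=float(d.get("acquisition_seconds", 3360.0)),
        noise=bool(d.get("noise", True)),
        calibration_bias=float(d.get("calibration_bias", 1.0)))


def load_cohort_spec(path) -> CohortSpec:
    d = yaml.safe_load(Path(path).read_text())
    kwargs = {}
    if "tissues" in d:
        kwargs["tissues"] = {
            t: {sc: tuple(v) for sc, v in per.items()}
            for t, per in d["tissues"].items()}
    for key in ("n_patients", "tumor_noise_sd", "seed"):
        if key in d:
            kwargs[key] = d[key]
    if "study_counts" in d:
        kwargs["study_counts"] = {int(k): int(v) for k, v in d["study_counts"].items()}
    if "liver_reference" in d:
        kwargs["liver_reference"] = tuple(d["liver_reference"])
    for key in ("tumor_weeks", "tumor_suvmax", "tumor_scanners"):
        if key in d:
            kwargs[key] = tuple(d[key])
    if "liver_segments" in d:
        kwargs["liver_segments"] = {k: tuple(v) for k, v in d["liver_segments"].items()}
    return CohortSpec(**kwargs)


# ---------------------------------------------------------------------------
# Tidy cohort CSV
# ---------------------------------------------------------------------------

def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise DataError(f"cohort CSV {path} lacks columns {missing}")
    bad = df.index[df["mean_suv"].isna() | (df["mean_suv"] < 0)]
    if len(bad):
        raise DataError(
            f"cohort CSV {path}: invalid mean_suv in row(s) {list(bad[:5])}")
    return df


def cohort_to_tissue_samples(df: pd.DataFrame):
    """Tidy cohort rows -> {scanner: [TissueSample, ...]}."""
    out: dict[str, list] = {}
    for (scanner, tissue), grp in df.groupby(["scanner", "tissue"]):
        out.setdefault(str(scanner), []).append(
            simulate.TissueSample(str(tissue), str(scanner),
                                  grp["mean_suv"].to_numpy()))
    return out


def tissue_samples_to_cohort(samples, study_date: str = "synthetic") -> pd.DataFrame:
    rows = []
    for s in samples:
        for k, v in enumerate(s.suvs):
            rows.append({"patient_id": f"{s.tissue}-{k + 1:03d}",
                         "study_date": study_date, "scanner": s.scanner,
                         "tissue": s.tissue, "mean_suv": float(v),
                         "max_suv": float(v)})
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
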