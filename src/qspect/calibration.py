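"""Dose bookkeeping, decay correction, and the camera conversion factor.

The conversion factor (kBq per count) is derived from a uniform cylinder of
known activity and volume: factor = activity / total counts in the phantom.
Applying it to a count image, divided by the voxel volume, yields activity
concentration in kBq/cm3. The net injected activity is the syringe difference
(pre minus post assay), with both assays decay-corrected to the injection
time; SUV normalization further decay-corrects the net activity to the scan
start.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

from . import config
from .errors import (ArgumentError, ConfigurationError, CountRateWarning,
                     DataError)
from .image import ActivityImage


def _hours_between(t0, t) -> float:
    """Elapsed hours from t0 to t; accepts datetimes or plain hour numbers."""
    if isinstance(t0, datetime) != isinstance(t, datetime):
        raise ArgumentError("t0 and t must both be datetimes or both numbers")
    if isinstance(t0, datetime):
        return (t - t0) / timedelta(hours=1)
    return float(t) - float(t0)


def decay_correct(activity0_kbq: float, t0, t,
                  half_life_h: float = config.I123_HALF_LIFE_HOURS) -> float:
    """Activity at time ``t`` given ``activity0_kbq`` at ``t0``.

    ``t`` earlier than ``t0`` back-corrects (the activity grows).
    """
    if half_life_h <= 0:
        raise ArgumentError("half_life_h must be positive")
    dt_h = _hours_between(t0, t)
    return activity0_kbq * 2.0 ** (-dt_h / half_life_h)


@dataclass(frozen=True)
class DoseRecord:
    """Syringe assays around an injection, all activities in kBq."""
    pre_activity_kbq: float
    pre_assay_time: object  # datetime or hours
    post_activity_kbq: float
    post_assay_time: object
    injection_time: object

    def __post_init__(self) -> None:
        if self.post_activity_kbq < 0:
            raise ArgumentError("post-injection activity cannot be negative")
        if self.pre_activity_kbq <= 0:
            raise ArgumentError("pre-injection activity must be positive")


def net_injected_activity(rec: DoseRecord,
                          half_life_h: float = config.I123_HALF_LIFE_HOURS) -> float:
    """Net administered activity: pre minus post assay, both decay-corrected
    to the injection time. Raises :class:`DataError` if the result is <= 0."""
    pre = decay_correct(rec.pre_activity_kbq, rec.pre_assay_time,
                        rec.injection_time, half_life_h)
    post = decay_correct(rec.post_activity_kbq, rec.post_assay_time,
                         rec.injection_time, half_life_h)
    net = pre - post
    if net <= 0:
        raise DataError(
            f"net injected activity {net:.1f} kBq is not positive "
            f"(pre {pre:.1f}, post {post:.1f} at injection time)")
    return net


@dataclass(frozen=True)
class StudyMeta:
    """Patient-level metadata entered at the console for SUV computation."""
    weight_g: float
    scan_start: object  # datetime or hours, same convention as the DoseRecord
    scanner: str
    height_cm: float | None = None

    def __post_init__(self) -> None:
        if self.weight_g <= 0:
            raise ArgumentError("weight must be positive")


def injected_activity_at_scan(rec: DoseRecord, meta: StudyMeta,
                              half_life_h: float = config.I123_HALF_LIFE_HOURS) -> float:
    """Net injected activity decay-corrected from injection to scan start —
    the denominator activity of the SUV."""
    net = net_injected_activity(rec, half_life_h)
    return decay_correct(net, rec.injection_time, meta.scan_start, half_life_h)


@dataclass(frozen=True)
class CalibrationFactor:
    """Counts-to-activity conversion with its derivation provenance."""
    kbq_per_count: float
    scanner: str
    derivation: dict = field(default_factory=dict)
    rate_warning: bool = False

    def __post_init__(self) -> None:
        if self.kbq_per_count <= 0:
            raise ArgumentError("kbq_per_count must be positive")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "kbq_per_count": self.kbq_per_count,
            "scanner": self.scanner,
            "derivation": self.derivation,
            "rate_warning": self.rate_warning,
        }, indent=2))

    @classmethod
    def from_json(cls, path) -> "CalibrationFactor":
        d = json.loads(Path(path).read_text())
        return cls(kbq_per_count=d["kbq_per_count"], scanner=d["scanner"],
                   derivation=d.get("derivation", {}),
                   rate_warning=d.get("rate_warning", False))


def derive_conversion_factor(counts: ActivityImage, activity_kbq: float,
                             volume_cm3: float, acquisition_seconds: float,
                             scanner: str | None = None,
                             rate_limit_kcts_s: float = config.COUNT_RATE_LIMIT_KCTS_S,
                             ) -> CalibrationFactor:
    """Derive the kBq-per-count factor from a uniform-phantom count image.

    Total counts are summed over the whole image (the phantom is the only
    source in the field of view). A warning is raised, and flagged on the
    returned factor, when the implied count rate reaches the calibration
    limit of ``rate_limit_kcts_s``.
    """
    if counts.units != "counts":
        raise ArgumentError("expected a count image")
    if activity_kbq <= 0 or volume_cm3 <= 0:
        raise ArgumentError("activity and volume must be positive")
    if acquisition_seconds <= 0:
        raise ArgumentError("acquisition_seconds must be positive")
    total = float(counts.voxels.sum())
    if total <= 0:
        raise DataError("uniform phantom image contains no counts")
    rate_kcts_s = total / acquisition_seconds / 1000.0
    rate_warning = rate_kcts_s >= rate_limit_kcts_s
    if rate_warning:
        warnings.warn(
            f"count rate {rate_kcts_s:.1f} kcts/s exceeds the "
            f"{rate_limit_kcts_s:.0f} kcts/s calibration limit",
            CountRateWarning, stacklevel=2)
    name = scanner if scanner is not None else counts.meta.get("scanner", "unknown")
    return CalibrationFactor(
        kbq_per_count=activity_kbq / total,
        scanner=name,
        derivation={"activity_kbq": activity_kbq, "volume_cm3": volume_cm3,
                    "total_counts": total, "count_rate_kcts_s": rate_kcts_s,
                    "acquisition_seconds": acquisition_seconds},
        rate_warning=rate_warning)


def apply_calibration(counts: ActivityImage, factor: CalibrationFactor) -> ActivityImage:
    """Convert a count image to activity concentration (kBq/cm3).

    The factor must come from the same scanner profile as the image; a
    mismatch raises :class:`ConfigurationError`.
    """
    if counts.units != "counts":
        raise ArgumentError("expected a count image")
    image_scanner = counts.meta.get("scanner")
    if image_scanner is not None and factor.scanner != image_scanner:
        raise ConfigurationError(
            f"calibration factor from {factor.scanner!r} cannot be applied to "
            f"an image acquired on {image_scanner!r}")
    conc = counts.voxels * (factor.kbq_per_count / counts.voxel_volume_cm3)
    out = counts.replace(conc, units="kBq_per_cm3")
    out.meta["calibration"] = {"kbq_per_count": factor.kbq_per_count,
                               "scanner": factor.scanner}
    return out
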