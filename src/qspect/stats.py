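"""Cohort statistics: inter-scanner comparison, variability, trajectories.

The inter-scanner comparison uses a two-tailed Mann-Whitney U test per
tissue. U is computed from rank sums with midranks for ties; the two-tailed p
comes from exact enumeration of labelings when the combined sample is small
(n1 + n2 <= 12 by default) and otherwise from the normal approximation with
tie-corrected variance and a continuity correction. No multiplicity
correction is applied across tissues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import config
from .errors import ArgumentError, DataError
from .simulate import LongitudinalSeries, TissueSample


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"
    n1: int
    n2: int
    tissue: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_statistic <= self.n1 * self.n2 + 1e-9):
            raise DataError("U must lie in [0, n1*n2]")
        if not (0.0 < self.p_value <= 1.0):
            raise DataError("p value must lie in (0, 1]")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """U of the first sample (midranks for ties) and the pooled rank vector."""
    n1 = x.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    return u1, ranks


def _exact_two_tailed_p(ranks: np.ndarray, n1: int, u1: float) -> float:
    """Two-tailed p by full enumeration of the C(N, n1) labelings.

    The permutation distribution of U1 is symmetric about n1*n2/2 (the rank
    multiset maps onto itself under rank reflection), so the two-tailed p is
    the probability of a deviation from the center at least as large as the
    observed one.
    """
    n = ranks.size
    n2 = n - n1
    center = n1 * n2 / 2.0
    obs_dev = abs(u1 - center)
    offset = n1 * (n1 + 1) / 2.0
    count = total = 0
    for comb in combinations(range(n), n1):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if abs(u - center) >= obs_dev - 1e-9:
            count += 1
    return count / total


def mann_whitney(x, y, mode: str = "auto",
                 exact_limit: int = config.EXACT_TEST_LIMIT,
                 continuity: bool = True, tissue: str | None = None,
                 ) -> ComparisonResult:
    """Two-tailed Mann-Whitney U test.

    ``mode`` is ``"auto"`` (exact when n1 + n2 <= exact_limit), ``"exact"``,
    or ``"approx"``. The reported U is that of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ArgumentError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u1, ranks = _u_statistic(x, y)

    if mode not in ("auto", "exact", "approx"):
        raise ArgumentError(f"unknown mode {mode!r}")
    exact = mode == "exact" or (mode == "auto" and n1 + n2 <= exact_limit)

    if exact:
        p = _exact_two_tailed_p(ranks, n1, u1)
        method = "exact"
    else:
        n = n1 + n2
        _, t_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(t_counts ** 3 - t_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:  # all observations identical
            p = 1.0
        else:
            dev = u1 - n1 * n2 / 2.0
            if continuity:
                dev -= math.copysign(min(0.5, abs(dev)), dev)
            p = min(1.0, 2.0 * sps.norm.sf(abs(dev) / math.sqrt(var)))
        method = "normal-approximation"
    return ComparisonResult(u_statistic=u1, p_value=max(p, np.finfo(float).tiny),
                            method=method, n1=n1, n2=n2, tissue=tissue)


# ---------------------------------------------------------------------------
# Inter-scanner tissue comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScannerComparison:
    table: pd.DataFrame  # one row per tissue
    average_p: float


def _index_samples(samples) -> dict[str, TissueSample]:
    out = {}
    for s in samples:
        if s.tissue in out:
            raise DataError(f"duplicate tissue label {s.tissue!r} in cohort")
        out[s.tissue] = s
    return out


def compare_scanners(cohort_a, cohort_b, alpha: float = config.ALPHA,
                     **mw_kwargs) -> ScannerComparison:
    """Per-tissue Mann-Whitney comparison of two scanners' tissue samples.

    ``cohort_a``/``cohort_b`` are iterables of :class:`TissueSample` with
    matching tissue labels. The summary statistic is the cross-tissue average
    p value.
    """
    a, b = _index_samples(cohort_a), _index_samples(cohort_b)
    if set(a) != set(b):
        raise DataError(
            f"tissue labels differ between cohorts: {sorted(set(a) ^ set(b))}")
    rows = []
    for tissue in sorted(a):
        res = mann_whitney(a[tissue].suvs, b[tissue].suvs, tissue=tissue,
                           **mw_kwargs)
        rows.append({
            "tissue": tissue,
            "mean_a": float(a[tissue].suvs.mean()),
            "sd_a": float(a[tissue].suvs.std(ddof=1)) if a[tissue].n > 1 else 0.0,
            "n_a": a[tissue].n,
            "mean_b": float(b[tissue].suvs.mean()),
            "sd_b": float(b[tissue].suvs.std(ddof=1)) if b[tissue].n > 1 else 0.0,
            "n_b": b[tissue].n,
            "u_statistic": res.u_statistic,
            "p_value": res.p_value,
            "method": res.method,
            "significant": res.p_value < alpha,
        })
    table = pd.DataFrame(rows)
    return ScannerComparison(table=table, average_p=float(table["p_value"].mean()))


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IqrSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def iqr_summary(sample) -> IqrSummary:
    """Box-plot summary: quartiles by linear interpolation, Tukey whiskers
    (most extreme points within 1.5*IQR of the quartiles), outliers beyond."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ArgumentError("sample must be non-empty")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(sorted(float(v) for v in x[(x < lo_fence) | (x > hi_fence)]))
    return IqrSummary(float(med), float(q1), float(q3), float(iqr),
                      float(inside.min()), float(inside.max()), outliers)


# ---------------------------------------------------------------------------
# Intrapatient variability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariabilityResult:
    per_patient_means: dict[str, float]
    overall_min: float
    overall_max: float
    min_max_percent: float
    reported_percent: int
    cohort_mean: float
    variance_of_mean: float
    n_patients: int
    n_studies: int


def intrapatient_variability(liver_series: dict[str, list[float]]) -> VariabilityResult:
    """Liver mean-SUV consistency across repeat studies.

    ``liver_series`` maps patient id -> per-study mean liver SUVs. Patients
    with fewer than two studies are excluded with a warning. The headline
    statistic is 100 * (overall minimum study SUV) / (overall maximum study
    SUV); the cohort summary is the average of the per-patient means and the
    variance (across patients) of those means.
    """
    from .quantitation import report_percent

    kept: dict[str, np.ndarray] = {}
    for patient, vals in liver_series.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            warnings.warn(f"patient {patient!r} has fewer than 2 studies; excluded",
                          UserWarning, stacklevel=2)
            continue
        kept[patient] = arr
    if not kept:
        raise DataError("no patient has two or more studies")
    all_studies = np.concatenate(list(kept.values()))
    overall_min, overall_max = float(all_studies.min()), float(all_studies.max())
    if overall_max <= 0:
        raise DataError("maximum liver SUV must be positive")
    pct = 100.0 * overall_min / overall_max
    means = {p: float(v.mean()) for p, v in kept.items()}
    mvals = np.array(list(means.values()))
    return VariabilityResult(
        per_patient_means=means,
        overall_min=overall_min, overall_max=overall_max,
        min_max_percent=pct, reported_percent=report_percent(pct),
        cohort_mean=float(mvals.mean()),
        variance_of_mean=float(mvals.var(ddof=1)) if mvals.size > 1 else 0.0,
        n_patients=len(kept), n_studies=int(all_studies.size))


# ---------------------------------------------------------------------------
# Longitudinal tumor response
# ---------------------------------------------------------------------------

def percent_reduction(series: LongitudinalSeries, from_index: int = 0,
                      to_index: int = -1) -> float:
    """Percent reduction of tumor SUVmax between two time points."""
    baseline = float(series.tumor_suvmax[from_index])
    final = float(series.tumor_suvmax[to_index])
    if baseline <= 0:
        raise ArgumentError("baseline SUVmax must be positive")
    return 100.0 * (1.0 - final / baseline)


@dataclass(frozen=True)
class TrajectoryReport:
    table: pd.DataFrame  # week, scanner, tumor_suvmax, liver_mean_suv, pct_change
    liver_segments: dict[str, tuple[float, float]]  # scanner -> (mean, sd)


def trajectory_report(series: LongitudinalSeries) -> TrajectoryReport:
    """Per-timepoint tumor SUVmax with cumulative percent change from baseline
    and a per-scanner-segment liver reference summary (mean +/- SD)."""
    baseline = float(series.tumor_suvmax[0])
    if baseline <= 0:
        raise ArgumentError("baseline SUVmax must be positive")
    pct_change = 100.0 * (series.tumor_suvmax / baseline - 1.0)
    table = pd.DataFrame({
        "week": series.weeks,
        "scanner": list(series.scanner),
        "tumor_suvmax": series.tumor_suvmax,
        "liver_mean_suv": series.liver_mean_suv,
        "pct_change_from_baseline": pct_change,
    })
    segments = {}
    for scanner, grp in table.groupby("scanner", sort=False):
        vals = grp["liver_mean_suv"].to_numpy()
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        segments[str(scanner)] = (float(vals.mean()), sd)
    return TrajectoryReport(table=table, liver_segments=segments)
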