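# Methods

This note documents the models behind `qspect`: what is simulated and how,
which parameters matter, the numerical conventions, and what the synthetic
experiments can and cannot say about real scanners.

## Quantitation chain

All quantitation runs on reconstructed-domain voxel images (`ActivityImage`:
a 3D grid with millimetre spacing, voxel-center coordinates, axis order
(x, y, z) with z the scanner axis, and a units tag — counts, kBq/cm³, or SUV).

1. **Calibration.** A uniform cylinder of known activity `A_cal` and volume
   `V` is acquired; the conversion factor is `A_cal / (total counts)`, total
   counts summed over the whole field of view (the phantom is the only
   source). This total-counts recipe, rather than a per-voxel regression, is
   noise-robust and matches the known-activity/known-volume procedure used
   with uniform water phantoms. Applying the factor divides by the voxel
   volume to give kBq/cm³. The implied count rate is recorded and a warning
   raised at ≥ 20 kcts/s, the usual ceiling for deriving a camera factor.
2. **Dose bookkeeping.** Net injected activity is the syringe difference,
   pre-assay minus post-assay, with both assays decay-corrected to the
   injection time (physically consistent even when the assays are timestamped
   away from the injection). SUV normalization further decay-corrects the net
   activity to the scan start; that target time is explicit in the API. The
   I-123 half-life is fixed at 13.2213 h in `qspect.config`, overridable per
   call.
3. **SUV / CRC / recovery.** `SUV = A_v/(A/w)`;
   `CRC = (SUV_s/SUV_b − 1)/(A_s/A_b − 1)`; recovered activity
   `SUV·(A/w)·(2 − CRC)`. The linear `(2 − CRC)` partial-volume correction is
   exact at CRC = 1 and progressively undercorrects as CRC falls; with an
   unbiased calibration it keeps recovered activity within ±10% of truth for
   CRC ≳ 0.33, which is what restricts reliable recovery to spheres of 17 mm
   and above at SPECT resolution.

## Phantom simulation

The NEMA IEC body phantom is modelled as an elliptical cylinder (semi-axes
150 × 110 mm, length 186 mm; ≈ 9.64 L, matching the 9 650 cm³ fill capacity)
holding a central 50 mm cold cylinder (the lung insert; attenuation itself is
not simulated) and six spheres of inner diameter 10–37 mm on a 57.2 mm ring
in the central transverse plane — the standard arrangement; positions are a
package convention. Default fill: spheres 35.4 kBq/cm³, background
11.0 kBq/cm³ (≈ 3.2 : 1), phantom weight 16 kg and net activity 106.2 MBq for
the SUV denominator.

Rasterization uses midpoint supersampling (default 8× per axis) so boundary
voxels carry volume-fraction mixtures; the voxel sum then conserves the
analytic activity integral to ≪ 1% at the default 4.8 mm spacing (128-matrix
convention over a ~60 cm field of view). With `supersample=1` the
rasterization degenerates to voxel-center membership — the same rule VOI
measurement uses — which makes the no-blur, no-noise chain an exact identity
(CRC = 1, zero recovery error); this configuration exists for verification,
not realism.

### Camera forward model

Acquisition and iterative reconstruction are replaced by a parametric model
acting on the truth grid:

    counts ~ Poisson(sensitivity · T · voxel_volume · Gaussian(truth; FWHM) · bias)

* `psf_fwhm_mm` — isotropic Gaussian resolution. Defaults: 15 mm
  (`infinia_me`, medium-energy collimators) and 13 mm (`symbia_lehr`,
  low-energy high-resolution collimators). These are effective reconstructed
  resolutions chosen so the simulated CRC-versus-diameter curve covers the
  range observed for visible spheres on clinical cameras (≈ 0.3 at 17 mm to
  ≈ 0.8 at 37 mm).
* `sensitivity` (counts per kBq·s, default 2×10⁻³) — an *effective*
  information-content parameter of the final images, not a crystal
  sensitivity: iterative reconstruction, scatter rejection and energy
  windowing discard most raw counts' worth of information. The default is set
  so that, with the statistical visibility rule below, the default phantom
  acquisition reproduces the four-of-six sphere detectability characteristic
  of I-123 body SPECT: the 10 and 13 mm spheres sit below threshold, 17 mm
  and larger above it.
* `acquisition_seconds` (default 3 360 s = 96 views × 35 s) and
  `calibration_bias` (multiplicative, default 1 — the simulated camera is
  unbiased).
* Noise is independent Poisson per voxel on the blurred expectation; a single
  integer seed makes every simulation bit-reproducible. Pipeline runs fan one
  study seed into per-stage seeds through `numpy.random.SeedSequence`.

### CRC analysis conventions

* **Sphere VOI**: concentric sphere at the known center, diameter 0.8× the
  inner diameter (`voi_scale`, configurable). A full-diameter VOI averages
  over the blurred rim and cannot exceed CRC ≈ 0.65 even for the 37 mm sphere
  at these resolutions; the 0.8 concentric VOI reproduces both the observed
  CRC range and the small-ROI practice of measuring within the visible hot
  area of a sphere. Sphere SUV uses the VOI mean (the usual CRC convention).
* **Background**: twelve 30 mm spherical VOIs placed deterministically in the
  central transverse plane, each center ≥ 25 mm from every insert surface and
  from the body wall, chosen greedily for mutual separation. Background SUV
  is the mean of the VOI means; the background noise scale is the pooled
  voxel SD within those VOIs.
* **Visibility rule**: a sphere is reported only when its VOI mean exceeds
  background mean + 2 × background voxel SD (`visibility_k` configurable);
  others are listed as not visible. The voxel-level SD is the operative noise
  scale for detecting a small hot object; the SD of VOI means would shrink
  with VOI size and declare everything visible.
* CRC > 1 (possible under noise) is warned about, never clamped; percent
  errors are reported both raw and rounded to integer percent, halves away
  from zero.

At the defaults this yields, averaged over seeds, CRC ≈ 0.39/0.52/0.66/0.80
and recovery errors ≈ −7/−1/+2/+3% for the 17/22/28/37 mm spheres, background
within ±1%, with the 10 and 13 mm spheres failing visibility in essentially
every run. Because the 17 mm sphere lies near the visibility threshold,
single-run results for it fluctuate by a few percent; multi-seed means are
the stable summary (the acceptance experiment uses 10–12 seeds).

## Synthetic cohorts

`CohortSpec` defaults encode the two-camera study conditions: nine normal
tissues (parotid and submandibular glands left/right, left ventricle, liver,
adrenals left/right, bladder) with per-scanner mean ± SD and sample sizes as
reported for the 111-examination cohort; mean-SUV draws come from a normal
truncated at zero (the truncation bias is negligible at these mean/SD
ratios). The intrapatient arm simulates 28 patients imaged on both cameras
with 2–10 studies each (6×2, 14×3, 5×4, 1×5, 1×6, 1×10), liver mean SUV drawn
from 1.6 ± 0.5. The longitudinal arm is a 10-point, 73-week tumor SUVmax
trajectory falling 12.0 → 3.1 with the camera switching after week 20 and a
liver reference of 2.1 ± 0.3 (first camera) / 2.1 ± 0.1 (second); trajectory
noise defaults to zero so the deterministic series is the reference.

### Statistics

* **Mann-Whitney U** (two-tailed): U from rank sums with midranks for ties;
  exact p by full enumeration of labelings when n₁+n₂ ≤ 12 (the permutation
  distribution of U is symmetric about n₁n₂/2, so the two-tailed p is the
  symmetric tail mass); otherwise a normal approximation with tie-corrected
  variance and continuity correction. The implementation is cross-checked
  against brute-force enumeration and against `scipy.stats.mannwhitneyu` in
  the tests. No multiplicity correction is applied across tissues — with nine
  independent tests at α = 0.05 a truly null cohort still flags at least one
  tissue in ≈ 1 − 0.95⁹ ≈ 37% of replicates, so the per-tissue level, the
  average p value, and the family-wise behavior must not be conflated.
* **Box summaries**: quartiles by linear interpolation; Tukey whiskers and
  1.5·IQR outliers.
* **Intrapatient variability**: patients with < 2 studies are excluded with a
  warning; the headline ratio is min/max over all study-level liver means,
  reported as an integer percent; the cohort summary is the mean of
  per-patient means and the variance across patients of those means (the
  interpretation adopted for "variance of the mean").
* **Trajectories**: cumulative percent change from baseline per time point
  and per-camera liver segments as mean ± SD (ddof = 1).

## What the synthetic experiments do and do not show

Passing tests demonstrate that the quantitation chain is self-consistent:
calibration inverts the forward model, CRC measures the imposed resolution
loss, the partial-volume correction recovers known truth within its validity
range, and the statistics hold their nominal levels on known distributions.
They do not validate attenuation or scatter correction (not simulated),
septal penetration of I-123's high-energy emissions, reconstruction
nonlinearity and its correlated noise, registration error, or reader ROI
variability — all of which affect real examinations. Clinical per-tissue U/p
values, clinical IQR summaries, and individual patient SUVmax series depend
on the original examinations and are not reproducible from this package; the
synthetic cohorts exercise those code paths with known ground truth instead.

## Problem sizes

Default grids are ≈ 75×59×52 voxels at 4.8 mm; a full phantom-study chain
runs in well under a second on one core, and the multi-seed acceptance
experiments use 10–12 noise realizations and a few hundred to a few thousand
statistical replicates — sizes chosen to keep every summary statistic's Monte
Carlo error small relative to the tolerances being checked.
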