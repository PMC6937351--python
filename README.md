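# qspect

Quantitative analysis of [I-123] mIBG SPECT/CT for pediatric neuroblastoma
imaging: phantom-based calibration of reconstructed counts to activity
concentration, standardized uptake values (SUV), contrast-recovery-coefficient
(CRC) measurement with partial-volume correction, and the nonparametric
statistics used to compare two SPECT/CT cameras, quantify intrapatient
variability, and track tumor response over treatment.

The package is aimed at nuclear-medicine physicists and imaging scientists who
want the full quantitation chain as tested, scriptable code. Because clinical
examinations cannot be redistributed, `qspect` ships first-class synthetic
generators — a NEMA IEC body phantom, a uniform calibration cylinder, and
two-camera patient cohorts — so every stage runs end to end on data with known
ground truth.

## The quantities

With `A_v` the activity concentration (kBq/cm³) measured in a volume of
interest, `A` the net injected activity decay-corrected to the scan start, and
`w` the body (or phantom) weight:

```
SUV = A_v / (A / w)

CRC = (SUV_sphere / SUV_bkgd − 1) / (A_sphere / A_bkgd − 1)

A_v(recovered) = SUV · (A / w) · [1 + (1 − CRC)]
```

SUV in a phantom carries units of g/cm³; in tissue (density 1 g/cm³) it is
unitless. CRC quantifies how much of the true sphere-to-background contrast
survives the camera's resolution; the `[1 + (1 − CRC)]` factor is the linear
partial-volume correction applied to recovered activity. Counts become kBq/cm³
through a conversion factor (kBq per count) derived from a uniform cylinder of
known activity and volume.

## Worked example

```python
import qspect as q

report = q.run_phantom_study(q.PipelineConfig(seed=1))
print(report.text())
```

prints

```
Phantom accuracy study
======================

conversion factor: 0.148485 kBq/count (0.22 kcts/s)
  17 mm sphere  CRC  0.35  recovered  32.3 kBq/cm3  error -9%
  22 mm sphere  CRC  0.57  recovered  35.7 kBq/cm3  error +1%
  28 mm sphere  CRC  0.67  recovered  36.4 kBq/cm3  error +3%
  37 mm sphere  CRC  0.79  recovered  36.7 kBq/cm3  error +4%
background      measured  11.0 kBq/cm3  error +0%
not visible: 10, 13 mm sphere(s)
```

The chain behind those numbers: a 111 MBq / 6000 cm³ uniform cylinder is
acquired and yields the kBq-per-count conversion factor at a count rate well
under the 20 kcts/s calibration limit; the NEMA IEC body phantom (six spheres,
10–37 mm, filled at 35.4 kBq/cm³ over an 11.0 kBq/cm³ background) is acquired
with the default camera profile; the count volume is calibrated back to
kBq/cm³; and for each sphere passing the visibility rule the CRC, the
partial-volume-corrected recovered activity and its percent error against the
35.4 kBq/cm³ truth are reported. The two smallest spheres fall below the
visibility threshold at this noise level, so four of six spheres are
quantified, with recovered activity accurate to better than ±10%.

The cohort side is symmetric:

```python
report = q.run_cohort_study(q.PipelineConfig(seed=1))
print(report.text())
```

producing the nine-tissue two-camera Mann-Whitney comparison table with its
average p value, the intrapatient liver variability summary (28 patients,
min/max study ratio as an integer percent), and the longitudinal tumor SUVmax
trajectory with its percent reduction (74% for the default series, 12.0 →
3.1).

A `qspect` CLI wraps the same operations (`qspect simulate phantom`,
`qspect calibrate`, `qspect crc`, `qspect compare`, `qspect run-phantom-study`,
...); volumes travel as NIfTI-1 with a JSON units sidecar, specs as YAML,
tables as CSV.

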