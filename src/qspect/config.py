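"""Physical constants and study-level default parameters.

Defaults here describe the experimental conditions the package emulates: the
NEMA IEC body phantom fill, the two-camera patient cohort distributions, and
the intrapatient liver follow-up structure. Values are in the units stated in
the field names (kBq, cm3, mm, g, hours).
"""

from __future__ import annotations

# Iodine-123 physical half-life in hours. Used for every decay correction;
# overridable wherever a half-life argument is accepted.
I123_HALF_LIFE_HOURS: float = 13.2213

# NEMA IEC body phantom -----------------------------------------------------
# Six fillable spheres, smallest to largest, with the fill volumes used when
# the phantom was prepared (fill volume includes the stem and is metadata;
# geometric volumes follow from the inner diameters).
SPHERE_DIAMETERS_MM: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
SPHERE_FILL_VOLUMES_CM3: tuple[float, ...] = (0.5, 1.0, 2.8, 5.8, 11.7, 29.0)
SPHERE_RING_RADIUS_MM: float = 57.2  # standard NEMA arrangement, transverse mid-plane

DEFAULT_SPHERE_KBQ_CM3: float = 35.4       # hot-sphere activity concentration
DEFAULT_BACKGROUND_KBQ_CM3: float = 11.0   # background water concentration
PHANTOM_CAPACITY_CM3: float = 9650.0       # body fill volume with inserts in place
PHANTOM_WEIGHT_G: float = 16000.0          # phantom weight entered for SUV
PHANTOM_NET_ACTIVITY_KBQ: float = 106200.0  # net activity of the 3000 cm3 stock

BODY_SEMI_AXES_MM: tuple[float, float] = (150.0, 110.0)
BODY_LENGTH_MM: float = 186.0
LUNG_INSERT_DIAMETER_MM: float = 50.0

# Uniform calibration cylinder (Jaszczak-style, no inserts) -----------------
CYLINDER_ACTIVITY_KBQ: float = 111000.0  # 111 MBq, keeps count rate < 20 kcts/s
CYLINDER_VOLUME_CM3: float = 6000.0
CYLINDER_RADIUS_MM: float = 108.0

# Camera calibration guard rail: derive the conversion factor below this rate.
COUNT_RATE_LIMIT_KCTS_S: float = 20.0

# Acquisition geometry ------------------------------------------------------
DEFAULT_SPACING_MM: float = 4.8          # 128 matrix over a ~60 cm field of view
DEFAULT_SUPERSAMPLE: int = 8             # boundary antialiasing factor per axis
DEFAULT_ACQUISITION_SECONDS: float = 3360.0  # 96 views x 35 s/stop

# Normal-tissue mean SUV distributions per scanner: tissue -> scanner ->
# (mean, SD, n). These parameterize the synthetic two-camera cohort.
TABLE1_TISSUES: dict[str, dict[str, tuple[float, float, int]]] = {
    "r_parotid":       {"infinia_me": (4.4, 1.5, 16), "symbia_lehr": (4.4, 1.8, 14)},
    "l_parotid":       {"infinia_me": (4.4, 1.3, 16), "symbia_lehr": (4.4, 1.6, 14)},
    "r_submandibular": {"infinia_me": (3.0, 0.7, 19), "symbia_lehr": (3.2, 1.2, 18)},
    "l_submandibular": {"infinia_me": (2.8, 0.6, 19), "symbia_lehr": (3.3, 1.3, 18)},
    "heart_lv":        {"infinia_me": (2.0, 0.3, 33), "symbia_lehr": (2.0, 0.8, 64)},
    "liver":           {"infinia_me": (1.5, 0.6, 39), "symbia_lehr": (1.6, 0.5, 63)},
    "r_adrenal":       {"infinia_me": (2.0, 0.3, 14), "symbia_lehr": (2.5, 0.9, 23)},
    "l_adrenal":       {"infinia_me": (1.9, 0.2, 6),  "symbia_lehr": (2.4, 0.9, 43)},
    "bladder":         {"infinia_me": (4.4, 1.5, 35), "symbia_lehr": (4.4, 1.9, 50)},
}

# Liver reference distribution used for the intrapatient-variability cohort.
LIVER_REFERENCE: tuple[float, float] = (1.6, 0.5)

# Intrapatient follow-up: number of patients with k studies each (28 patients
# imaged on both cameras, 2 to 10 studies per patient).
STUDY_COUNT_DISTRIBUTION: dict[int, int] = {2: 6, 3: 14, 4: 5, 5: 1, 6: 1, 10: 1}

# Longitudinal tumor follow-up: 10 time points over 18 months, camera switch
# after week 20, maximum SUV falling from 12.0 at baseline to 3.1.
TUMOR_WEEKS: tuple[float, ...] = (0, 4, 8, 14, 20, 26, 33, 40, 51, 73)
TUMOR_SUVMAX: tuple[float, ...] = (12.0, 11.2, 10.5, 9.8, 9.2, 7.8, 6.4, 5.1, 4.0, 3.1)
TUMOR_SCANNERS: tuple[str, ...] = ("infinia_me",) * 5 + ("symbia_lehr",) * 5
# Liver background mean/SD per camera segment along the follow-up.
LIVER_SEGMENTS: dict[str, tuple[float, float]] = {
    "infinia_me": (2.1, 0.3),
    "symbia_lehr": (2.1, 0.1),
}

# Visibility rule for phantom spheres: a sphere counts as visible when its
# VOI mean exceeds background mean + VISIBILITY_K * background voxel SD.
VISIBILITY_K: float = 2.0

# Statistics defaults.
EXACT_TEST_LIMIT: int = 12  # exact Mann-Whitney when n1 + n2 <= this
ALPHA: float = 0.05
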