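"""Published summary values from the reference four-device study.

A cross-sectional study imaged 109 healthy eyes twice on each of four
commercial OCT-angiography instruments (Spectralis, Optovue, Triton,
Cirrus) with a 3 x 3 mm disc-centered scan, and reported peri-papillary
capillary vessel length density (VLD) on four quadrants of the annulus
between the 1.5 and 2.25 mm circles.  The printed summary tables from
that study are inputs here: they drive the arithmetic-reproduction
checks (coefficients of variation, eligibility percentages) and anchor
the defaults of the synthetic cohort generator.
"""

from __future__ import annotations

import pandas as pd

DEVICES = ("Spectralis", "Optovue", "Triton", "Cirrus")
LOCATIONS = ("superior", "nasal", "inferior", "temporal")

#: Axial-length cut separating the longer-eye group (group 2), in mm.
AL_GROUP_CUTOFF_MM = 25.5

#: Minimum signal-strength demand per device, each on the device's own scale.
MIN_SIGNAL = {
    "Spectralis": 25,
    "Optovue": 50,
    "Triton": 50,
    "Cirrus": 7,
}

#: Eligible / total acquisitions per device after quality screening.
ELIGIBILITY_COUNTS = {
    "Spectralis": (79, 218),
    "Optovue": (201, 218),
    "Triton": (165, 218),
    "Cirrus": (192, 218),
}

#: Printed eligibility percentages (integer-rounded).
ELIGIBILITY_PERCENT = {
    "Spectralis": 36,
    "Optovue": 92,
    "Triton": 76,
    "Cirrus": 88,
}

#: Between-subject VLD summaries, mm^-1: (device, location) -> (mean, SD).
VLD_SUMMARY = {
    ("Spectralis", "superior"): (20.1, 3.4),
    ("Spectralis", "nasal"): (25.2, 3.4),
    ("Spectralis", "inferior"): (19.4, 3.1),
    ("Spectralis", "temporal"): (23.8, 4.0),
    ("Optovue", "superior"): (18.8, 1.9),
    ("Optovue", "nasal"): (20.9, 2.3),
    ("Optovue", "inferior"): (18.7, 2.1),
    ("Optovue", "temporal"): (22.8, 2.3),
    ("Triton", "superior"): (21.9, 2.6),
    ("Triton", "nasal"): (22.8, 2.9),
    ("Triton", "inferior"): (21.9, 2.0),
    ("Triton", "temporal"): (24.3, 2.7),
    ("Cirrus", "superior"): (16.9, 1.9),
    ("Cirrus", "nasal"): (20.7, 2.4),
    ("Cirrus", "inferior"): (16.8, 2.2),
    ("Cirrus", "temporal"): (19.8, 4.4),
}

#: Printed integer CVs (%) accompanying VLD_SUMMARY.
PRINTED_CV = {
    ("Spectralis", "superior"): 17,
    ("Spectralis", "nasal"): 14,
    ("Spectralis", "inferior"): 16,
    ("Spectralis", "temporal"): 17,
    ("Optovue", "superior"): 10,
    ("Optovue", "nasal"): 11,
    ("Optovue", "inferior"): 11,
    ("Optovue", "temporal"): 10,
    ("Triton", "superior"): 12,
    ("Triton", "nasal"): 13,
    ("Triton", "inferior"): 9,
    ("Triton", "temporal"): 11,
    ("Cirrus", "superior"): 11,
    ("Cirrus", "nasal"): 12,
    ("Cirrus", "inferior"): 13,
    ("Cirrus", "temporal"): 22,
}

#: Cells whose printed CV does not equal round(100*SD/mean) of the printed
#: mean/SD pair (the published value was presumably computed from unrounded
#: data). Excluded from arithmetic-reproduction checks.
CV_INCONSISTENT_CELLS = frozenset({("Spectralis", "nasal")})

#: Scan-rescan ICC per device on the whole 1-3 mm ring (estimate, CI95 low, high).
REPEATABILITY_ICC = {
    "Spectralis": (0.94, 0.86, 0.98),
    "Optovue": (0.90, 0.74, 0.96),
    "Triton": (0.84, 0.59, 0.94),
    "Cirrus": (0.87, 0.67, 0.95),
}


def vld_summary_frame() -> pd.DataFrame:
    """Reference VLD summaries as a tidy frame (device, location, mean, sd, cv_printed)."""
    rows = []
    for (device, location), (mean, sd) in VLD_SUMMARY.items():
        rows.append(
            {
                "device": device,
                "location": location,
                "mean": mean,
                "sd": sd,
                "cv_printed": PRINTED_CV[(device, location)],
                "cv_consistent": (device, location) not in CV_INCONSISTENT_CELLS,
            }
        )
    return pd.DataFrame(rows)
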