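"""Commissioning measurements bundled as package inputs.

These are the measured numbers from the clinical commissioning of a
GE Discovery 670-class Lu-177 SPECT/CT system: the re-entrant-chamber decay /
constancy ledger, the pre- and post-service hybrid-registration QA offsets,
the system volume-sensitivity calibration factors, and the NEMA-sphere VOI
count rates.  They are *inputs* to the QA arithmetic in this package (the
machine-measured values themselves cannot be derived from first principles).
"""

from __future__ import annotations

import pandas as pd

from .units import ActivityAssay, parse_timestamp

__all__ = [
    "CALIBRATION_ASSAY",
    "lu177_constancy_ledger",
    "CF_PRE_SERVICE_CPS_PER_MBQ",
    "CF_POST_SERVICE_CPS_PER_MBQ",
    "NEMA_SPHERE_COUNT_RATES_CPS",
    "NEMA_SPHERE_INJECTED_MCI",
    "REGISTRATION_QA_OFFSETS_MM",
    "REGISTRATION_TOLERANCE_MM",
]

#: NIST-traceable calibration point for the Lu-177 constancy ledger:
#: 245.270 mCi assayed at 10/22/18 12:00 (vial volume 24.5 mL, T1/2 6.6500 d).
CALIBRATION_ASSAY = ActivityAssay(parse_timestamp("10/22/18 12:00"), 245.270, "NIST")

# Daily constancy readings on two AtomLab 500 chambers, with the calculated
# (decay-corrected) dose as worked on the original ledger.
_CONSTANCY_ROWS = [
    # timestamp, calculated mCi, Atom Lab 1 mCi, Atom Lab 2 mCi
    ("10/24/18 11:00", 199.97, 206.0, 208.0),
    ("10/25/18 10:00", 180.95, 186.5, 187.9),
    ("10/26/18 10:00", 163.03, 168.5, 170.3),
    ("10/30/18 10:00", 107.43, 110.9, 112.2),
    ("10/31/18 11:20", 96.37, 99.3, 100.6),
]


def lu177_constancy_ledger() -> pd.DataFrame:
    """The daily constancy ledger as a DataFrame.

    Columns: ``timestamp`` (datetime), ``calculated_mCi`` (the ledger's own
    decay-corrected column), ``atomlab1_mCi``, ``atomlab2_mCi``.
    """
    return pd.DataFrame(
        [
            {
                "timestamp": parse_timestamp(ts),
                "calculated_mCi": calc,
                "atomlab1_mCi": m1,
                "atomlab2_mCi": m2,
            }
            for ts, calc, m1, m2 in _CONSTANCY_ROWS
        ]
    )


#: System volume sensitivity (cps/MBq) from the uniform-cylinder calibration,
#: before and after the field-service realignment of the hybrid system.
CF_PRE_SERVICE_CPS_PER_MBQ = 5.04159
CF_POST_SERVICE_CPS_PER_MBQ = 5.124969

#: VOI count rates (cps) measured in the 37 / 28 / 22 mm NEMA spheres, and the
#: activities injected into those spheres (mCi), largest sphere first.
NEMA_SPHERE_COUNT_RATES_CPS = {37: 251.6, 28: 109.5, 22: 51.5}
NEMA_SPHERE_INJECTED_MCI = {37: 0.63, 28: 0.27, 22: 0.13}

#: Hybrid NM-CT registration QA (mean, SD) per axis in mm, measured with the
#: MEGP collimator before (2022-05-02) and after (2022-06-06) machine service.
REGISTRATION_QA_OFFSETS_MM = {
    "pre_service": {"X": (3.04, 0.95), "Y": (0.87, 0.48), "Z": (1.24, 0.68)},
    "post_service": {"X": (0.82, 0.39), "Y": (0.63, 0.45), "Z": (0.91, 0.06)},
}

#: Per-axis registration tolerance in mm.
REGISTRATION_TOLERANCE_MM = 2.2
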