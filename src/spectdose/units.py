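"""Units, timestamps, and radioactive-decay arithmetic.

Everything downstream (calibrator QA, calibration factors, dosimetry) leans on
three small pieces of bookkeeping: exponential decay of an assayed activity,
the exact definitional mCi/MBq conversion, and elapsed time between assay
timestamps recorded at minute resolution in the ``MM/DD/YY HH:MM`` dialect
used on dose-calibrator worksheets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "RadionuclideSpec",
    "ActivityAssay",
    "EnergyWindow",
    "LU177",
    "TEW_WINDOWS",
    "MBQ_PER_MCI",
    "SECONDS_PER_DAY",
    "parse_timestamp",
    "elapsed_days",
    "decay_factor",
    "decay_correct",
    "decay_constant_per_s",
    "mci_to_mbq",
    "mbq_to_mci",
    "mci_mbq_convert",
    "read_assay_ledger",
    "write_assay_ledger",
]

#: Exact definitional conversion: 1 mCi = 37 MBq.
MBQ_PER_MCI = 37.0
SECONDS_PER_DAY = 86400.0

_TIMESTAMP_FORMAT = "%m/%d/%y %H:%M"

TimestampLike = Union[str, datetime]


@dataclass(frozen=True)
class RadionuclideSpec:
    """Physical constants of a radionuclide.

    Parameters
    ----------
    name
        Nuclide label, e.g. ``"Lu-177"``.
    half_life_days
        Physical half-life in days.  Must be positive.
    photopeak_keV
        Energy of the imaging photopeak in keV.
    energy_per_decay_J
        Locally absorbed energy per decay in joules (beta plus conversion /
        Auger electrons), used by the local-deposition dose model.
    """

    name: str
    half_life_days: float
    photopeak_keV: float
    energy_per_decay_J: float

    def __post_init__(self) -> None:
        if not self.half_life_days > 0:
            raise ValueError(f"half_life_days must be positive, got {self.half_life_days}")
        if not self.energy_per_decay_J > 0:
            raise ValueError(f"energy_per_decay_J must be positive, got {self.energy_per_decay_J}")


#: Lu-177 constants.  The 6.6500-day half-life matches the value used on the
#: commissioning decay ledger (the common literature value is 6.647 d; the
#: ledger value is kept so the ledger reproduces exactly).  The absorbed
#: energy per decay, 147.9 keV = 2.3694e-14 J, is the mean beta energy plus
#: conversion/Auger electrons from standard decay data; it is configurable
#: and not tied to any ledger.
LU177 = RadionuclideSpec(
    name="Lu-177",
    half_life_days=6.6500,
    photopeak_keV=208.0,
    energy_per_decay_J=147.9e3 * 1.602176634e-19,
)


@dataclass(frozen=True)
class ActivityAssay:
    """A single dose-calibrator reading: activity at a timestamp on a device."""

    timestamp: datetime
    activity_mCi: float
    device_id: str = ""

    def __post_init__(self) -> None:
        if self.activity_mCi < 0:
            raise ValueError(f"activity_mCi must be >= 0, got {self.activity_mCi}")
        if not isinstance(self.timestamp, datetime):
            object.__setattr__(self, "timestamp", parse_timestamp(self.timestamp))


@dataclass(frozen=True)
class EnergyWindow:
    """An acquisition energy window [lower_keV, upper_keV]."""

    label: str
    lower_keV: float
    upper_keV: float

    def __post_init__(self) -> None:
        if self.label not in ("main", "upper_scatter", "lower_scatter"):
            raise ValueError(f"unknown window label {self.label!r}")
        if not self.upper_keV > self.lower_keV:
            raise ValueError(
                f"window {self.label}: upper ({self.upper_keV}) must exceed lower ({self.lower_keV})"
            )

    @property
    def width_keV(self) -> float:
        return self.upper_keV - self.lower_keV


#: Lu-177 triple-energy-window protocol: 208 keV +/-10% photopeak flanked by
#: narrow scatter windows at 240 keV +/-5% and 177.8 keV +/-5%.  Bounds are
#: carried verbatim (widths 41.6 / 24.0 / 17.8 keV).
TEW_WINDOWS = {
    "main": EnergyWindow("main", 187.6, 229.2),
    "upper_scatter": EnergyWindow("upper_scatter", 228.0, 252.0),
    "lower_scatter": EnergyWindow("lower_scatter", 168.9, 186.7),
}


def parse_timestamp(value: TimestampLike) -> datetime:
    """Parse a ``MM/DD/YY HH:MM`` string (datetimes pass through unchanged)."""
    if isinstance(value, datetime):
        return value
    try:
        return datetime.strptime(value.strip(), _TIMESTAMP_FORMAT)
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"unparseable timestamp {value!r}; expected 'MM/DD/YY HH:MM'") from exc


def elapsed_days(t0: TimestampLike, t: TimestampLike) -> float:
    """Signed fractional days from ``t0`` to ``t`` at minute resolution."""
    return (parse_timestamp(t) - parse_timestamp(t0)).total_seconds() / SECONDS_PER_DAY


def decay_factor(dt_days: float, half_life_days: float) -> float:
    """Fraction of activity remaining after ``dt_days`` (2^(-dt/T1/2))."""
    if not half_life_days > 0:
        raise ValueError(f"half_life_days must be positive, got {half_life_days}")
    return 2.0 ** (-dt_days / half_life_days)


def decay_correct(
    a0: float,
    t0: TimestampLike,
    t: TimestampLike,
    spec: RadionuclideSpec = LU177,
) -> float:
    """Activity at ``t`` given ``a0`` at ``t0``: a0 * 2^(-(t-t0)/T1/2).

    ``t`` earlier than ``t0`` back-corrects (the result exceeds ``a0``).
    Units are whatever ``a0`` carries (mCi throughout this package).
    """
    return a0 * decay_factor(elapsed_days(t0, t), spec.half_life_days)


def decay_constant_per_s(spec: RadionuclideSpec) -> float:
    """Decay constant lambda = ln2 / T1/2 in 1/s."""
    import math

    return math.log(2.0) / (spec.half_life_days * SECONDS_PER_DAY)


def mci_to_mbq(activity_mCi: float) -> float:
    if activity_mCi < 0:
        raise ValueError(f"activity must be >= 0, got {activity_mCi}")
    return activity_mCi * MBQ_PER_MCI


def mbq_to_mci(activity_MBq: float) -> float:
    if activity_MBq < 0:
        raise ValueError(f"activity must be >= 0, got {activity_MBq}")
    return activity_MBq / MBQ_PER_MCI


def mci_mbq_convert(x: float, direction: str) -> float:
    """Convert activity between mCi and MBq (direction 'to_mbq' or 'to_mci')."""
    if direction == "to_mbq":
        return mci_to_mbq(x)
    if direction == "to_mci":
        return mbq_to_mci(x)
    raise ValueError(f"direction must be 'to_mbq' or 'to_mci', got {direction!r}")


def read_assay_ledger(path: Union[str, Path]) -> list[ActivityAssay]:
    """Read an assay ledger CSV with columns timestamp, activity_mCi, device_id."""
    df = pd.read_csv(path, dtype={"device_id": str})
    required = {"timestamp", "activity_mCi", "device_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay ledger {path} missing columns {sorted(missing)}")
    return [
        ActivityAssay(parse_timestamp(row.timestamp), float(row.activity_mCi), str(row.device_id))
        for row in df.itertuples()
    ]


def write_assay_ledger(assays: Iterable[ActivityAssay], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "timestamp": [a.timestamp.strftime(_TIMESTAMP_FORMAT) for a in assays],
            "activity_mCi": [a.activity_mCi for a in assays],
            "device_id": [a.device_id for a in assays],
        }
    )
    df.to_csv(path, index=False)
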