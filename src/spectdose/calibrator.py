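"""Re-entrant-chamber (dose calibrator) QA: constancy and linearity.

Daily *constancy* compares each chamber reading against the decay-corrected
NIST-traceable calibration activity and reports the signed percent
difference.  Quarterly *linearity* fits measured response against expected
activity over a series of sources and reports slope, intercept and the
Pearson correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .units import ActivityAssay, RadionuclideSpec, LU177, decay_correct

__all__ = [
    "ConstancyRow",
    "LinearityResult",
    "percent_difference",
    "constancy_report",
    "linearity_check",
    "constancy_to_frame",
    "constancy_to_markdown",
]


def percent_difference(measured: float, calculated: float) -> float:
    """Signed percent difference 100 * (measured - calculated) / calculated."""
    if calculated == 0:
        raise ZeroDivisionError("percent difference undefined for zero calculated activity")
    return 100.0 * (measured - calculated) / calculated


@dataclass(frozen=True)
class ConstancyRow:
    """One constancy-check day: calculated activity vs per-device readings."""

    timestamp: datetime
    calculated_mCi: float
    measured_mCi: dict[str, float]
    pct_diff: dict[str, float]

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Percent differences rounded for display (2 decimals by convention)."""
        return {dev: round(v, ndigits) for dev, v in self.pct_diff.items()}


@dataclass(frozen=True)
class LinearityResult:
    """Least-squares line of measured vs expected activity."""

    pairs: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    correlation: float

    def __post_init__(self) -> None:
        if abs(self.correlation) > 1 + 1e-12:
            raise ValueError(f"|correlation| must be <= 1, got {self.correlation}")

    @property
    def correlation_rounded(self) -> float:
        """Correlation rounded to one decimal, as reported on QA sheets."""
        return round(self.correlation, 1)


def constancy_report(
    calibration: ActivityAssay,
    readings: Sequence[ActivityAssay],
    spec: RadionuclideSpec = LU177,
) -> list[ConstancyRow]:
    """Build a constancy report from a calibration point and daily readings.

    Readings sharing a timestamp (different ``device_id``) are grouped into
    one row.  The calculated activity is the calibration activity decayed to
    the reading's timestamp; the percent difference is signed,
    ``100 * (measured - calculated) / calculated``.
    """
    if not readings:
        return []
    grouped: dict[datetime, dict[str, float]] = {}
    for r in readings:
        grouped.setdefault(r.timestamp, {})[r.device_id] = r.activity_mCi
    rows = []
    for ts in sorted(grouped):
        calc = decay_correct(calibration.activity_mCi, calibration.timestamp, ts, spec)
        if calc == 0:
            raise ZeroDivisionError(f"calculated activity is zero at {ts}")
        measured = grouped[ts]
        rows.append(
            ConstancyRow(
                timestamp=ts,
                calculated_mCi=calc,
                measured_mCi=measured,
                pct_diff={dev: percent_difference(m, calc) for dev, m in measured.items()},
            )
        )
    return rows


def linearity_check(series: Sequence[tuple[float, float]]) -> LinearityResult:
    """Fit measured vs expected activity and report slope/intercept/Pearson r.

    Requires at least 3 points with strictly positive, non-constant expected
    activities.  The fit is on the activities themselves (response plotted
    against activity), not on logs.
    """
    if len(series) < 3:
        raise ValueError(f"linearity check needs >= 3 points, got {len(series)}")
    expected = np.asarray([p[0] for p in series], dtype=float)
    measured = np.asarray([p[1] for p in series], dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected activities must be strictly positive")
    if np.ptp(expected) == 0:
        raise ValueError("expected activities have zero variance; cannot fit a line")
    fit = stats.linregress(expected, measured)
    return LinearityResult(
        pairs=tuple((float(e), float(m)) for e, m in zip(expected, measured)),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        correlation=float(fit.rvalue),
    )


def constancy_to_frame(rows: Iterable[ConstancyRow]) -> pd.DataFrame:
    """Flatten a constancy report to a DataFrame (one column pair per device)."""
    records = []
    for row in rows:
        rec: dict = {"timestamp": row.timestamp, "calculated_mCi": row.calculated_mCi}
        for dev in sorted(row.measured_mCi):
            rec[f"{dev}_mCi"] = row.measured_mCi[dev]
            rec[f"{dev}_pct_diff"] = round(row.pct_diff[dev], 2)
        records.append(rec)
    return pd.DataFrame(records)


def constancy_to_markdown(rows: Iterable[ConstancyRow]) -> str:
    df = constancy_to_frame(rows)
    return df.to_markdown(index=False) if hasattr(df, "to_markdown") else df.to_string()
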