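"""Year-long continuous measurement (YLCM) series and room eligibility.

A YLCM is a uniformly sampled record of indoor radon concentration (Bq/m3)
covering a full year at a registration step of typically 1 h or 3 h, giving
M = 8760 or 2920 samples.  The annual average of such a record is the
quantity a reference level regulates, and the windowed sub-records of the
same series are the raw material for estimating the temporal uncertainty of
shorter tests.

Rooms feeding a temporal-uncertainty study must satisfy eligibility
requirements: elevated concentration (annual average at least ~50 Bq/m3 and
at least five times the outdoor level), long daily occupancy (>= 6 h), and
regular operation of the room over the whole monitored year.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DataCompletenessError

logger = logging.getLogger(__name__)

HOURS_PER_YEAR = 365 * 24

#: Default annual-average threshold for "elevated" indoor radon, Bq/m3.
#: The eligibility guidance gives a 50-70 Bq/m3 range; the lower bound is the
#: conservative (inclusive) default.
ELEVATED_THRESHOLD_BQM3 = 50.0

#: A monitored room must exceed outdoor radon by at least this factor.
OUTDOOR_RATIO = 5.0

#: Minimum daily occupancy of the monitored room, hours.
MIN_OCCUPANCY_HOURS = 6.0

#: Fraction of missing samples tolerated before a record is rejected.
MAX_GAP_FRACTION = 0.05


def expected_length(step_hours: float) -> int:
    """Number of samples in a complete YLCM at the given registration step."""
    return round(HOURS_PER_YEAR / step_hours)


@dataclass
class RadonSeries:
    """A uniformly sampled indoor radon concentration series.

    Parameters
    ----------
    values : array-like of float
        Concentrations in Bq/m3, one per registration interval, in time order.
    step_hours : float
        Registration step; must divide 24 h.
    start_time : str
        ISO-8601 timestamp of the first sample (calendar anchor only; the
        statistics are calendar-agnostic).
    room_id : str
        Label of the monitored room.
    mode : {"normal", "closed"}
        Operation mode of the room during monitoring.
    occupancy_hours_per_day : float, optional
        Daily occupancy of the room; ``None`` means unknown.
    outdoor_concentration : float, optional
        Local outdoor radon concentration in Bq/m3; ``None`` means unknown.
    """

    values: np.ndarray
    step_hours: float = 3.0
    start_time: str = "2023-01-01T00:00:00"
    room_id: str = "room"
    mode: str = "normal"
    occupancy_hours_per_day: Optional[float] = None
    outdoor_concentration: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if self.step_hours <= 0 or not math.isclose(
            24.0 / self.step_hours, round(24.0 / self.step_hours)
        ):
            raise ValueError(
                f"step of {self.step_hours} h must be positive and divide 24 h"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("radon concentrations must be non-negative")
        if self.mode not in ("normal", "closed"):
            raise ValueError(f"mode must be 'normal' or 'closed', got {self.mode!r}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def is_full_year(self) -> bool:
        """True when the series has exactly M = round(8760 / step) samples."""
        return self.n_samples == expected_length(self.step_hours)

    def require_full_year(self) -> None:
        if not self.is_full_year:
            raise DataCompletenessError(
                f"series has {self.n_samples} samples; a complete year at "
                f"{self.step_hours} h step needs {expected_length(self.step_hours)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataCompletenessError("series contains unfilled gaps (NaN)")

    def fill_gaps(self, max_gap_fraction: float = MAX_GAP_FRACTION) -> "RadonSeries":
        """Return a copy with NaN gaps linearly interpolated.

        A record with more than ``max_gap_fraction`` missing samples is not a
        usable YLCM and is rejected.  Interpolation is linear over the sample
        index, with circular wrap for runs touching either end of the year so
        the filled record stays periodic in the same sense as the transform.
        """
        missing = ~np.isfinite(self.values)
        if not missing.any():
            return self
        frac = missing.mean()
        if frac > max_gap_fraction:
            raise DataCompletenessError(
                f"{frac:.1%} of samples missing exceeds the "
                f"{max_gap_fraction:.0%} gap tolerance"
            )
        logger.info(
            "room %s: interpolating %d missing samples (%.2f%%)",
            self.room_id, int(missing.sum()), 100 * frac,
        )
        n = self.values.size
        idx = np.arange(n)
        # wrap one period on each side so edge gaps interpolate circularly
        known = idx[~missing]
        xp = np.concatenate([known - n, known, known + n])
        fp = np.tile(self.values[~missing], 3)
        filled = self.values.copy()
        filled[missing] = np.interp(idx[missing], xp, fp)
        return replace(self, values=filled)


def annual_average(series: RadonSeries) -> float:
    """Annual average concentration: the arithmetic mean of all M samples.

    Equals the mean of any circular moving-average transform of the same
    series, so the deviation statistics are anchored to a single well-defined
    annual value.
    """
    series.require_full_year()
    return float(series.values.mean())


@dataclass(frozen=True)
class EligibilityReport:
    """Outcome of the room-eligibility screen for temporal-uncertainty studies."""

    elevated_concentration: bool
    exceeds_outdoor_5x: bool
    occupancy_ok: bool
    mode_regular: bool
    annual_average: float
    warnings: tuple = field(default=())

    @property
    def eligible(self) -> bool:
        return (
            self.elevated_concentration
            and self.exceeds_outdoor_5x
            and self.occupancy_ok
            and self.mode_regular
        )

    def to_dict(self) -> dict:
        return {
            "elevated_concentration": self.elevated_concentration,
            "exceeds_outdoor_5x": self.exceeds_outdoor_5x,
            "occupancy_ok": self.occupancy_ok,
            "mode_regular": self.mode_regular,
            "eligible": self.eligible,
            "annual_average_bqm3": self.annual_average,
            "warnings": list(self.warnings),
        }


def check_eligibility(
    series: RadonSeries,
    elevated_threshold: float = ELEVATED_THRESHOLD_BQM3,
    regular_operation: bool = True,
) -> EligibilityReport:
    """Screen a monitored room for inclusion in a temporal-uncertainty study.

    The report never raises: missing metadata produces warnings and the
    corresponding check defaults permissively (the screen is about selecting
    representative rooms, not about rejecting data outright).
    """
    c_aa = annual_average(series)
    warnings: list[str] = []

    elevated = c_aa >= elevated_threshold

    if series.outdoor_concentration is None:
        warnings.append("outdoor concentration unknown; 5x-outdoor check skipped")
        exceeds_outdoor = True
    else:
        exceeds_outdoor = c_aa >= OUTDOOR_RATIO * series.outdoor_concentration

    if series.occupancy_hours_per_day is None:
        warnings.append("occupancy unknown; occupancy check skipped")
        occupancy_ok = True
    else:
        occupancy_ok = series.occupancy_hours_per_day >= MIN_OCCUPANCY_HOURS

    for w in warnings:
        logger.warning("room %s: %s", series.room_id, w)

    return EligibilityReport(
        elevated_concentration=bool(elevated),
        exceeds_outdoor_5x=bool(exceeds_outdoor),
        occupancy_ok=bool(occupancy_ok),
        mode_regular=bool(regular_operation),
        annual_average=c_aa,
        warnings=tuple(warnings),
    )
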