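"""Temporal uncertainty U_V(t) of indoor radon.

A measurement of duration t differs from the annual average it stands in for
because indoor radon varies in time.  The deviation of window i in room j is

    D_ij(t) = C_j_AA / C_ij(t) - 1,

the relative error committed by scaling the windowed value up to the annual
average.  Pooling D over all windows of all rooms in a representative sample
and taking the 95th percentile gives the temporal uncertainty U_V(t): with
probability >= 95% the annual average does not exceed C(t) * (1 + U_V(t)).

The percentile is the *nearest-rank* order statistic (no interpolation), so
the in-sample fraction of deviations strictly exceeding U_V is <= 5% exactly
— this is what caps the false-negative rate of the conformity criterion.

When no ensemble of year-long records is available, conservative default
values are used: U_V = 1.0 (100%) at 2 days and 0.7 (70%) at 7 days, with
log-linear interpolation in between and constant extrapolation beyond the
last knot.  Spot measurements (t < 2 days) have uncontrolled temporal
uncertainty above 200% and are rejected outright.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import SpotMeasurementError
from .series import RadonSeries
from .transform import TransformedEnsemble, circular_moving_average, window_size

logger = logging.getLogger(__name__)

#: Replacement for zero concentrations before forming ratios, Bq/m3.
ZERO_FLOOR_BQM3 = 0.1

#: Smallest pool size for a confident percentile estimate.
MIN_POOL_SIZE = 20

#: Shortest duration with controlled temporal uncertainty, hours (2 days).
MIN_TEST_HOURS = 48.0

DEFAULT_PERCENTILE = 95.0


# ----------------------------------------------------------------------
# deviations and pooling
# ----------------------------------------------------------------------

def deviations(
    ensemble: TransformedEnsemble,
    annual_avg: float,
    zero_floor: float = ZERO_FLOOR_BQM3,
) -> dict[float, np.ndarray]:
    """Per-interval deviation arrays D_i(t) = C_AA / C_i(t) - 1.

    Zero windowed concentrations are floored at ``zero_floor`` (logged) so
    the ratio stays finite; since both quantities are positive, D > -1
    always.
    """
    if not annual_avg > 0:
        raise ValueError(f"annual average must be positive, got {annual_avg}")
    out: dict[float, np.ndarray] = {}
    for t, arr in ensemble.arrays.items():
        c = np.asarray(arr, dtype=float)
        n_zero = int((c <= 0).sum())
        if n_zero:
            if zero_floor is None or zero_floor <= 0:
                raise ValueError(
                    f"{n_zero} non-positive windowed concentrations at t={t} h "
                    "and no zero floor configured"
                )
            logger.info(
                "flooring %d non-positive windowed values at %.3g Bq/m3 (t=%g h)",
                n_zero, zero_floor, t,
            )
            c = np.maximum(c, zero_floor)
        out[t] = annual_avg / c - 1.0
    return out


@dataclass(frozen=True)
class DeviationPool:
    """Deviations pooled over a sample of rooms, keyed by integration interval."""

    pools: Mapping[float, np.ndarray]
    n_rooms: int
    annual_averages: tuple

    def size(self, t_hours: float) -> int:
        return int(np.asarray(self.pools[t_hours]).size)

    @property
    def intervals(self) -> tuple:
        return tuple(self.pools.keys())


def pool_deviations(
    ensembles: Sequence[TransformedEnsemble],
    annual_averages: Sequence[float],
    zero_floor: float = ZERO_FLOOR_BQM3,
) -> DeviationPool:
    """Pool D_ij(t) across rooms; all ensembles must share the same intervals."""
    if len(ensembles) == 0:
        raise ValueError("at least one ensemble is required")
    if len(ensembles) != len(annual_averages):
        raise ValueError("one annual average per ensemble is required")
    intervals = ensembles[0].intervals
    for e in ensembles[1:]:
        if e.intervals != intervals:
            raise ValueError("all ensembles must share the same intervals")
    per_room = [deviations(e, c, zero_floor) for e, c in zip(ensembles, annual_averages)]
    pools = {
        t: np.concatenate([d[t] for d in per_room]) for t in intervals
    }
    return DeviationPool(
        pools=pools,
        n_rooms=len(ensembles),
        annual_averages=tuple(float(c) for c in annual_averages),
    )


# ----------------------------------------------------------------------
# percentile and U_V
# ----------------------------------------------------------------------

def nearest_rank_percentile(values: Iterable[float], percentile: float) -> float:
    """Order statistic at rank ceil(p*n/100) of the sorted sample.

    The convention guarantees that the fraction of the sample strictly above
    the returned value is at most (100 - p)%.
    """
    a = np.sort(np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float))
    n = a.size
    if n == 0:
        raise ValueError("cannot take a percentile of an empty pool")
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    rank = max(1, math.ceil(percentile * n / 100.0))
    return float(a[rank - 1])


def estimate_uv(
    pool: DeviationPool,
    t_hours: float,
    percentile: float = DEFAULT_PERCENTILE,
    min_pool_size: int = MIN_POOL_SIZE,
) -> float:
    """U_V at interval t: nearest-rank percentile of the pooled signed
    deviations, clipped below at 0.

    The percentile runs over the full signed distribution; negative
    deviations (windows above the annual average) simply never reach the
    upper tail.  A pool smaller than ``min_pool_size`` still yields a value
    but is flagged low-confidence in the log.
    """
    if t_hours not in pool.pools:
        raise KeyError(f"no deviations pooled at t={t_hours} h")
    d = pool.pools[t_hours]
    if d.size < min_pool_size:
        logger.warning(
            "pool of %d deviations at t=%g h is below the minimum of %d; "
            "U_V estimate is low-confidence", d.size, t_hours, min_pool_size,
        )
    return max(0.0, nearest_rank_percentile(d, percentile))


# ----------------------------------------------------------------------
# U_V(t) curves
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TemporalUncertaintyCurve:
    """U_V as a function of test duration, defined by (hours, U_V) knots.

    Evaluation interpolates U_V linearly in log(t) between knots — the
    decay of temporal uncertainty with duration is concave on a log axis,
    so log-linear interpolation stays on the conservative side of sparse
    knots — and extrapolates as a constant beyond the last knot.  Durations
    below the first knot raise :class:`SpotMeasurementError`.
    """

    knots: tuple
    source: str = "estimated"
    percentile: float = DEFAULT_PERCENTILE

    def __post_init__(self) -> None:
        ts = [k[0] for k in self.knots]
        uvs = [k[1] for k in self.knots]
        if len(self.knots) == 0:
            raise ValueError("a curve needs at least one knot")
        if any(t <= 0 for t in ts) or list(ts) != sorted(set(ts)):
            raise ValueError("knot durations must be positive and strictly increasing")
        if any(u < 0 for u in uvs):
            raise ValueError("U_V values must be non-negative")
        if self.source not in ("estimated", "conservative"):
            raise ValueError(f"unknown curve source {self.source!r}")

    def __call__(self, t_hours: float) -> float:
        t = float(t_hours)
        ts = np.array([k[0] for k in self.knots], dtype=float)
        uvs = np.array([k[1] for k in self.knots], dtype=float)
        if t < ts[0]:
            raise SpotMeasurementError(
                f"duration {t:g} h is below the {ts[0]:g} h floor of this "
                "U_V curve; spot measurements cannot support conformity assessment"
            )
        if t >= ts[-1]:
            return float(uvs[-1])
        return float(np.interp(np.log(t), np.log(ts), uvs))

    def to_rows(self) -> list[tuple[float, float]]:
        return [(float(t), float(u)) for t, u in self.knots]


#: Built-in conservative defaults: 100% at 2 days, 70% at 7 days.  The full
#: indicative curve down to ~10% at year scale exists in the underlying
#: monitoring studies but only these two values are carried as built-ins;
#: users supply richer tables when available.
CONSERVATIVE_UV = TemporalUncertaintyCurve(
    knots=((48.0, 1.0), (168.0, 0.7)),
    source="conservative",
)


def conservative_uv(
    t_hours: float, table: TemporalUncertaintyCurve | None = None
) -> float:
    """Conservative U_V at duration t (>= 2 days) from a knot table."""
    curve = CONSERVATIVE_UV if table is None else table
    if t_hours < MIN_TEST_HOURS:
        raise SpotMeasurementError(
            f"duration {t_hours:g} h is a spot measurement (< {MIN_TEST_HOURS:g} h)"
        )
    return curve(t_hours)


# ----------------------------------------------------------------------
# estimator
# ----------------------------------------------------------------------

class TemporalUncertaintyEstimator(BaseEstimator):
    """Estimate the U_V(t) curve from a sample of year-long records.

    Fit takes ``X`` of shape (n_rooms, M): one complete YLCM per row, all at
    the same registration step.  For each configured integration interval the
    rows are circularly window-averaged, deviations from each room's own
    annual average are pooled, and U_V is the nearest-rank percentile of the
    pool.  Predict evaluates the fitted curve at arbitrary durations.

    Parameters
    ----------
    intervals_hours : sequence of float
        Integration intervals t at which to estimate U_V; each must be a
        multiple of ``step_hours``.
    step_hours : float
        Registration step of the rows of X.
    percentile : float
        Upper percentile defining U_V (default 95).
    zero_floor : float
        Floor applied to non-positive windowed concentrations, Bq/m3.

    Attributes
    ----------
    annual_averages_ : ndarray of shape (n_rooms,)
    uv_values_ : ndarray aligned with ``sorted(intervals_hours)``
    pool_sizes_ : ndarray of pool sizes per interval
    curve_ : TemporalUncertaintyCurve
    """

    def __init__(
        self,
        intervals_hours: Sequence[float] = (48.0, 168.0, 720.0),
        step_hours: float = 3.0,
        percentile: float = DEFAULT_PERCENTILE,
        zero_floor: float = ZERO_FLOOR_BQM3,
    ):
        self.intervals_hours = intervals_hours
        self.step_hours = step_hours
        self.percentile = percentile
        self.zero_floor = zero_floor

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        if (X < 0).any():
            raise ValueError("radon concentrations must be non-negative")
        ts = sorted(float(t) for t in self.intervals_hours)
        if len(ts) != len(set(ts)) or not ts:
            raise ValueError("intervals must be non-empty and distinct")
        windows = {t: window_size(self.step_hours, t) for t in ts}
        self.annual_averages_ = X.mean(axis=1)
        uvs, sizes, pools = [], [], {}
        for t in ts:
            w = windows[t]
            d = [
                c_aa / np.maximum(circular_moving_average(row, w), self.zero_floor) - 1.0
                for row, c_aa in zip(X, self.annual_averages_)
            ]
            pool = np.concatenate(d)
            pools[t] = pool
            uvs.append(max(0.0, nearest_rank_percentile(pool, self.percentile)))
            sizes.append(pool.size)
        self.intervals_ = np.array(ts)
        self.uv_values_ = np.array(uvs)
        self.pool_sizes_ = np.array(sizes)
        self.pool_ = DeviationPool(
            pools=pools, n_rooms=X.shape[0],
            annual_averages=tuple(self.annual_averages_),
        )
        self.curve_ = TemporalUncertaintyCurve(
            knots=tuple(zip(self.intervals_, self.uv_values_)),
            source="estimated",
            percentile=self.percentile,
        )
        return self

    def predict(self, T) -> np.ndarray:
        """U_V at each duration in ``T`` (hours, array-like or scalar)."""
        check_is_fitted(self, "curve_")
        t_arr = np.atleast_1d(np.asarray(T, dtype=float))
        return np.array([self.curve_(t) for t in t_arr])


def estimate_uv_curve(
    rooms: Sequence[RadonSeries],
    intervals_hours: Sequence[float],
    percentile: float = DEFAULT_PERCENTILE,
    zero_floor: float = ZERO_FLOOR_BQM3,
) -> TemporalUncertaintyCurve:
    """Convenience wrapper: fit a U_V(t) curve from RadonSeries objects."""
    if not rooms:
        raise ValueError("at least one room is required")
    steps = {s.step_hours for s in rooms}
    if len(steps) > 1:
        raise ValueError(f"all rooms must share one registration step, got {steps}")
    for s in rooms:
        s.require_full_year()
    X = np.vstack([s.values for s in rooms])
    est = TemporalUncertaintyEstimator(
        intervals_hours=intervals_hours,
        step_hours=steps.pop(),
        percentile=percentile,
        zero_floor=zero_floor,
    ).fit(X)
    return est.curve_
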