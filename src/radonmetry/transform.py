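"""Circular moving-average transform of YLCM series.

A single year-long record C_1..C_M at registration step h can be re-read as M
overlapping measurements of any longer duration t = w*h: window i is the mean
of the w consecutive samples starting at sample i.  Windows running past
31 December wrap to 1 January, which is the only convention that keeps every
transformed array at exactly M entries and preserves the annual mean — both
properties the deviation statistics rely on.

Stacking the transforms at I different integration intervals gives an
ensemble of L = M * I windowed values per room (each interval contributes a
full-length array), which is what makes a handful of monitored rooms yield
statistically powerful deviation pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import InvalidIntervalError
from .series import RadonSeries


def window_size(step_hours: float, t_hours: float) -> int:
    """Window length in samples for integration interval ``t_hours``.

    ``t_hours`` must be a positive integer multiple of the registration step.
    """
    w = t_hours / step_hours
    if t_hours <= 0 or abs(w - round(w)) > 1e-9:
        raise InvalidIntervalError(
            f"integration interval {t_hours} h is not a positive multiple "
            f"of the {step_hours} h registration step"
        )
    return int(round(w))


def circular_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Mean of each length-``window`` run of ``values``, wrapping circularly.

    Output o[i] = mean(values[i], ..., values[i+window-1]) with indices taken
    modulo len(values).  Output length equals input length and the mean is
    conserved exactly (every sample enters exactly ``window`` windows).
    """
    x = np.asarray(values, dtype=float)
    m = x.size
    if not 1 <= window <= m:
        raise InvalidIntervalError(
            f"window of {window} samples does not fit a series of length {m}"
        )
    ext = np.concatenate([x, x[: window - 1]])
    cs = np.concatenate([[0.0], np.cumsum(ext)])
    return (cs[window:] - cs[:-window]) / window


class CircularMovingAverage(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer applying the circular moving average row-wise.

    Each row of X is one full-year series (M samples at ``step_hours``); the
    transform replaces it by the M window averages of duration
    ``window_hours``.

    Parameters
    ----------
    window_hours : float
        Integration interval t; must be a positive multiple of ``step_hours``.
    step_hours : float
        Registration step of the rows.
    """

    def __init__(self, window_hours: float = 48.0, step_hours: float = 3.0):
        self.window_hours = window_hours
        self.step_hours = step_hours

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=1)
        self.window_samples_ = window_size(self.step_hours, self.window_hours)
        if self.window_samples_ > X.shape[1]:
            raise InvalidIntervalError(
                f"window of {self.window_samples_} samples exceeds series "
                f"length {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "window_samples_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return np.vstack(
            [circular_moving_average(row, self.window_samples_) for row in X]
        )


def moving_average_transform(series: RadonSeries, t_hours: float) -> np.ndarray:
    """Window averages C_i(t) of a complete YLCM at integration interval t."""
    series.require_full_year()
    w = window_size(series.step_hours, t_hours)
    return circular_moving_average(series.values, w)


@dataclass(frozen=True)
class TransformedEnsemble:
    """All windowed re-readings of one YLCM at several integration intervals.

    ``arrays`` maps interval t (hours) to the M window averages C_i(t).
    """

    source: str
    M: int
    arrays: Mapping[float, np.ndarray]

    @property
    def intervals(self) -> tuple:
        return tuple(self.arrays.keys())

    @property
    def I(self) -> int:  # noqa: E743 - domain symbol
        return len(self.arrays)

    @property
    def L(self) -> int:
        """Total number of windowed values, L = M * I."""
        return self.M * self.I


def build_ensemble(
    series: RadonSeries, intervals_hours: Sequence[float]
) -> TransformedEnsemble:
    """Transform one YLCM at each requested integration interval.

    Intervals must be distinct and each a valid multiple of the registration
    step; every transformed array has the full M entries.
    """
    if len(intervals_hours) == 0:
        raise InvalidIntervalError("at least one integration interval is required")
    ts = [float(t) for t in intervals_hours]
    if len(set(ts)) != len(ts):
        raise InvalidIntervalError(f"duplicate integration intervals in {ts}")
    arrays = {t: moving_average_transform(series, t) for t in ts}
    return TransformedEnsemble(
        source=series.room_id, M=series.n_samples, arrays=arrays
    )
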