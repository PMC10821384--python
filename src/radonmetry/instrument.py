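"""Instrumental (device) uncertainty U_D for radon measurement devices.

Two device families share one metrological scheme built on a sensitivity
(calibration factor) epsilon and a background:

* counting devices (continuous radon monitors, charcoal, electret):
  C = (r_g - r_0) / eps from gross and background count *rates*; the random
  component of uncertainty follows Poisson statistics of the counted pulses,
  u(r) = sqrt(n) / t = sqrt(r / t), and

      U_D = k * sqrt[ (r_g/t + r_0/t_0) / (r_g - r_0)^2 + u_rel(eps)^2 ]

* track-etch devices (SSNTD and retrospective CD/DVD measurements): the
  observable is the total number of etched tracks over the exposure, so
  C = (n_g - n_0) / (eps * t), and the exposure duration itself carries a
  relative uncertainty u_rel(t) (dominant concern for CD/DVD discs of
  imprecisely known age):

      U_D = k * sqrt[ (n_g + n_0) / (n_g - n_0)^2 + u_rel(eps)^2 + u_rel(t)^2 ]

U_D is a relative expanded uncertainty at coverage factor k (default 2,
~95% under the normal approximation that large-count Poisson statistics
justify).  u_rel(eps) is a single catch-all systematic covering calibration,
humidity, dust, ageing and fading.

A net signal at or below zero yields C = 0 with a below-background flag and
an undefined (infinite) relative uncertainty; no detection-threshold
machinery is provided, because under the conformity criterion a low
concentration never needs to be measured accurately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import NoSignalError

DEFAULT_COVERAGE_FACTOR = 2.0


# ----------------------------------------------------------------------
# data records
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DeviceCountData:
    """Counting-device record: gross and background counts with their times.

    Counts with times are the canonical form (Poisson statistics need them).
    Rates with explicit standard uncertainties may be supplied instead via
    :meth:`from_rates`.

    Attributes
    ----------
    n_g, n_0 : float
        Gross and background counted pulses (non-negative).
    t, t_0 : float
        Measurement and background durations, seconds.
    epsilon : float
        Sensitivity, net counts per second per Bq/m3.
    u_rel_epsilon : float
        Relative standard uncertainty of the sensitivity (fraction).
    k : float
        Coverage factor for the expanded uncertainty.
    """

    n_g: float
    t: float
    n_0: float
    t_0: float
    epsilon: float
    u_rel_epsilon: float = 0.0
    k: float = DEFAULT_COVERAGE_FACTOR
    u_r_g: Optional[float] = None  # explicit rate uncertainties (rate-based records)
    u_r_0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_g < 0 or self.n_0 < 0:
            raise ValueError("counts must be non-negative")
        if self.t <= 0 or self.t_0 <= 0:
            raise ValueError("measurement durations must be positive")
        if self.epsilon <= 0:
            raise ValueError("sensitivity must be positive")
        if not 0 <= self.u_rel_epsilon < 1:
            raise ValueError("u_rel(eps) must be a fraction in [0, 1)")
        if self.k <= 0:
            raise ValueError("coverage factor must be positive")

    @property
    def r_g(self) -> float:
        """Gross count rate, 1/s."""
        return self.n_g / self.t

    @property
    def r_0(self) -> float:
        """Background count rate, 1/s."""
        return self.n_0 / self.t_0

    @classmethod
    def from_rates(
        cls,
        r_g: float,
        r_0: float,
        epsilon: float,
        u_r_g: float,
        u_r_0: float,
        u_rel_epsilon: float = 0.0,
        k: float = DEFAULT_COVERAGE_FACTOR,
    ) -> "DeviceCountData":
        """Build a record from rates with explicit standard uncertainties.

        Times are set to 1 s so n = r numerically; the Poisson-implied rate
        uncertainties are overridden by the explicit ones.
        """
        return cls(
            n_g=r_g, t=1.0, n_0=r_0, t_0=1.0,
            epsilon=epsilon, u_rel_epsilon=u_rel_epsilon, k=k,
            u_r_g=u_r_g, u_r_0=u_r_0,
        )


@dataclass(frozen=True)
class TrackExposureData:
    """Track-etch record (SSNTD or CD/DVD): total etched tracks over an exposure.

    ``u_rel_t`` is the relative uncertainty of the exposure duration; it is
    zero for deployed SSNTDs with a logged exposure and becomes a free,
    device-specific input for retrospective CD/DVD measurements.
    """

    n_g: float
    n_0: float
    epsilon: float
    t: float
    u_rel_epsilon: float = 0.0
    u_rel_t: float = 0.0
    k: float = DEFAULT_COVERAGE_FACTOR

    def __post_init__(self) -> None:
        if self.n_g < 0 or self.n_0 < 0:
            raise ValueError("track counts must be non-negative")
        if self.epsilon <= 0 or self.t <= 0:
            raise ValueError("sensitivity and exposure duration must be positive")
        if not 0 <= self.u_rel_epsilon < 1:
            raise ValueError("u_rel(eps) must be a fraction in [0, 1)")
        if not 0 <= self.u_rel_t < 1:
            raise ValueError("u_rel(t) must be a fraction in [0, 1)")
        if self.k <= 0:
            raise ValueError("coverage factor must be positive")


@dataclass(frozen=True)
class Measurement:
    """A measured concentration with its expanded instrumental uncertainty."""

    C: float
    t_hours: float
    U_D: float
    u_C: float
    u_rel_random: float
    u_rel_systematic: float
    k: float
    below_background: bool = False
    undefined_uncertainty: bool = False

    def to_dict(self) -> dict:
        return {
            "concentration_bqm3": self.C,
            "duration_hours": self.t_hours,
            "U_D": self.U_D,
            "u_C_bqm3": self.u_C,
            "u_rel_random": self.u_rel_random,
            "u_rel_systematic": self.u_rel_systematic,
            "coverage_factor": self.k,
            "below_background": self.below_background,
            "undefined_uncertainty": self.undefined_uncertainty,
        }


# ----------------------------------------------------------------------
# counting devices
# ----------------------------------------------------------------------

def concentration_from_counts(d: DeviceCountData) -> float:
    """C = (r_g - r_0) / eps in Bq/m3; below-background results clip to 0."""
    c = (d.r_g - d.r_0) / d.epsilon
    return max(0.0, c)


def calibrate_sensitivity(r_g: float, r_0: float, c_ref: float) -> float:
    """Sensitivity from a measurement at a known reference concentration.

    eps = (r_g - r_0) / C_ref; round-trips with
    :func:`concentration_from_counts`.
    """
    if c_ref <= 0:
        raise ValueError(f"reference concentration must be positive, got {c_ref}")
    if r_g <= r_0:
        raise NoSignalError(
            f"gross rate {r_g} does not exceed background {r_0}; no net signal"
        )
    return (r_g - r_0) / c_ref


def rate_uncertainty(n: float, t: float) -> float:
    """Standard uncertainty of a count rate: u(r) = sqrt(n)/t = sqrt(r/t)."""
    if t <= 0:
        raise ValueError(f"counting time must be positive, got {t}")
    if n < 0:
        raise ValueError(f"counts must be non-negative, got {n}")
    return math.sqrt(n) / t


def counting_uncertainty_components(d: DeviceCountData) -> tuple[float, float]:
    """(random, systematic) relative standard components of a counting record.

    The random part propagates the Poisson rate uncertainties through the net
    rate; the systematic part is u_rel(eps).  Undefined (infinite) when the
    net rate is not positive.
    """
    net = d.r_g - d.r_0
    if net <= 0:
        return math.inf, d.u_rel_epsilon
    if d.u_r_g is not None or d.u_r_0 is not None:
        var = (d.u_r_g or 0.0) ** 2 + (d.u_r_0 or 0.0) ** 2
    else:
        var = d.r_g / d.t + d.r_0 / d.t_0
    return math.sqrt(var) / net, d.u_rel_epsilon


def expanded_uncertainty_counting(d: DeviceCountData) -> tuple[float, float]:
    """Expanded relative uncertainty U_D and absolute u(C) for a counting record.

    U_D = k * sqrt[(r_g/t + r_0/t_0)/(r_g - r_0)^2 + u_rel(eps)^2];
    u(C) = U_D * C / k.  Returns (inf, inf) flagged via :func:`measure_counting`
    when the net rate is not positive.
    """
    rand, syst = counting_uncertainty_components(d)
    if math.isinf(rand):
        return math.inf, math.inf
    u_d = d.k * math.sqrt(rand**2 + syst**2)
    c = concentration_from_counts(d)
    return u_d, u_d * c / d.k


def measure_counting(d: DeviceCountData, t_hours: float | None = None) -> Measurement:
    """Full measurement record: concentration, U_D and its component split."""
    c = (d.r_g - d.r_0) / d.epsilon
    below = c < 0
    rand, syst = counting_uncertainty_components(d)
    undefined = math.isinf(rand)
    u_d, u_c = expanded_uncertainty_counting(d)
    return Measurement(
        C=max(0.0, c),
        t_hours=d.t / 3600.0 if t_hours is None else t_hours,
        U_D=u_d,
        u_C=u_c,
        u_rel_random=rand,
        u_rel_systematic=syst,
        k=d.k,
        below_background=below,
        undefined_uncertainty=undefined,
    )


# ----------------------------------------------------------------------
# track-etch devices
# ----------------------------------------------------------------------

def track_concentration(d: TrackExposureData) -> float:
    """C = (n_g - n_0) / (eps * t); below-background results clip to 0."""
    c = (d.n_g - d.n_0) / (d.epsilon * d.t)
    return max(0.0, c)


def track_uncertainty_components(d: TrackExposureData) -> tuple[float, float]:
    """(random, systematic) relative components of a track-etch record.

    Systematic combines the sensitivity and exposure-duration terms in
    quadrature.
    """
    net = d.n_g - d.n_0
    syst = math.hypot(d.u_rel_epsilon, d.u_rel_t)
    if net <= 0:
        return math.inf, syst
    return math.sqrt(d.n_g + d.n_0) / net, syst


def expanded_uncertainty_track(d: TrackExposureData) -> float:
    """U_D = k * sqrt[(n_g + n_0)/(n_g - n_0)^2 + u_rel(eps)^2 + u_rel(t)^2]."""
    rand, syst = track_uncertainty_components(d)
    if math.isinf(rand):
        return math.inf
    return d.k * math.sqrt(rand**2 + syst**2)


def measure_track(d: TrackExposureData) -> Measurement:
    """Full measurement record for a track-etch exposure."""
    c_raw = (d.n_g - d.n_0) / (d.epsilon * d.t)
    rand, syst = track_uncertainty_components(d)
    u_d = expanded_uncertainty_track(d)
    c = max(0.0, c_raw)
    return Measurement(
        C=c,
        t_hours=d.t / 3600.0,
        U_D=u_d,
        u_C=(u_d * c / d.k) if math.isfinite(u_d) else math.inf,
        u_rel_random=rand,
        u_rel_systematic=syst,
        k=d.k,
        below_background=c_raw < 0,
        undefined_uncertainty=math.isinf(rand),
    )
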