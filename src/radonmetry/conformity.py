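"""The conformity-assessment decision rule and test-duration planning.

A room conforms to a reference level C_RL when

    C(t) * [1 + sqrt(U_V(t)^2 + U_D^2)] < C_RL        (strict inequality)

where C(t) is the concentration measured over duration t (>= 2 days),
U_V(t) the temporal uncertainty of a test of that duration, and U_D the
expanded relative instrumental uncertainty (coverage factor 2).  The two
components combine in quadrature because temporal variability and
instrumental error are independent.  With U_V the 95th percentile of the
deviation distribution, the rule keeps the false-negative rate (a room
judged compliant whose true annual average is at the reference level) at or
below 5%.

The negation is reported as "compliance not demonstrated", never as proven
exceedance: the rule is one-sided, and a failed short test is grounds for a
longer test, not for a verdict.  Decision accuracy is ultimately bounded by
year-to-year variations of indoor radon, typically 15-20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence, Union

from .errors import SpotMeasurementError
from .instrument import DeviceCountData
from .temporal import TemporalUncertaintyCurve

#: International recommendation for the maximum annual-average reference level.
DEFAULT_REFERENCE_LEVEL_BQM3 = 300.0

#: Conversion factor between the US customary and SI radon concentration units.
BQM3_PER_PCI_L = 37.0

#: The US Action Level, 4 pCi/L.
US_ACTION_LEVEL_PCI_L = 4.0

#: Year-to-year variations bound the achievable decision accuracy.
YEAR_TO_YEAR_NOTE = (
    "decision accuracy is bounded by year-to-year indoor radon variations, "
    "typically 15-20%"
)

UvLike = Union[float, TemporalUncertaintyCurve, Callable[[float], float]]


def pci_l_to_bqm3(pci_l: float) -> float:
    """Convert pCi/L to Bq/m3 (4 pCi/L is the 148 Bq/m3 US Action Level)."""
    return round(pci_l * BQM3_PER_PCI_L)


def combined_expansion(u_v: float, u_d: float) -> float:
    """Root-sum-square combination sqrt(U_V^2 + U_D^2) of the two independent
    relative expanded uncertainties."""
    if u_v < 0 or u_d < 0:
        raise ValueError(f"uncertainties must be non-negative, got {u_v}, {u_d}")
    return math.hypot(u_v, u_d)


@dataclass(frozen=True)
class ConformityDecision:
    """Auditable record of one application of the decision rule."""

    status: str  # "compliant" | "not_demonstrated"
    C: float
    t_hours: float
    U_V: float
    U_D: float
    combined_expansion: float
    upper_bound: float
    C_RL: float
    margin: float
    uv_source: str
    note: str = YEAR_TO_YEAR_NOTE

    @property
    def compliant(self) -> bool:
        return self.status == "compliant"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "concentration_bqm3": self.C,
            "duration_hours": self.t_hours,
            "U_V": self.U_V,
            "U_D": self.U_D,
            "combined_expansion": self.combined_expansion,
            "upper_bound_bqm3": self.upper_bound,
            "reference_level_bqm3": self.C_RL,
            "margin_bqm3": self.margin,
            "uv_source": self.uv_source,
            "note": self.note,
        }


def _resolve_uv(uv: UvLike, t_hours: float) -> tuple[float, str]:
    if isinstance(uv, TemporalUncertaintyCurve):
        return uv(t_hours), uv.source
    if callable(uv):
        return float(uv(t_hours)), "callable"
    return float(uv), "explicit"


def assess(
    C: float,
    t_hours: float,
    uv: UvLike,
    u_d: float,
    c_rl: float = DEFAULT_REFERENCE_LEVEL_BQM3,
) -> ConformityDecision:
    """Apply the decision rule to a measured concentration.

    Parameters
    ----------
    C : float
        Measured concentration over the test, Bq/m3.
    t_hours : float
        Test duration in hours; must be at least 48 h (2 days).
    uv : float, TemporalUncertaintyCurve or callable
        Temporal uncertainty at ``t_hours``: an explicit value, or a curve
        evaluated at the test duration.
    u_d : float
        Expanded relative instrumental uncertainty (coverage factor 2).
    c_rl : float
        Reference level, Bq/m3.

    Returns
    -------
    ConformityDecision
        ``compliant`` iff C * (1 + sqrt(U_V^2 + U_D^2)) < C_RL, strictly;
        ties and everything above report ``not_demonstrated``.
    """
    if C < 0:
        raise ValueError(f"concentration must be non-negative, got {C}")
    if c_rl <= 0:
        raise ValueError(f"reference level must be positive, got {c_rl}")
    if t_hours < 48.0:
        raise SpotMeasurementError(
            f"test duration {t_hours:g} h is below the 2-day minimum"
        )
    u_v, source = _resolve_uv(uv, t_hours)
    expansion = combined_expansion(u_v, u_d)
    upper = C * (1.0 + expansion)
    status = "compliant" if upper < c_rl else "not_demonstrated"
    return ConformityDecision(
        status=status,
        C=float(C),
        t_hours=float(t_hours),
        U_V=u_v,
        U_D=float(u_d),
        combined_expansion=expansion,
        upper_bound=upper,
        C_RL=float(c_rl),
        margin=float(c_rl) - upper,
        uv_source=source,
    )


# ----------------------------------------------------------------------
# duration planning
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DurationPlan:
    """Projected decisions at candidate test durations.

    ``projections`` holds one dict per candidate (duration, U_V, projected
    U_D, upper bound, decidable flag); ``chosen_hours`` is the smallest
    decidable duration or ``None`` when no candidate resolves — the
    projected concentration is too close to (or above) the reference level.
    """

    projections: tuple
    chosen_hours: float | None
    c_projected: float
    c_rl: float

    @property
    def resolvable(self) -> bool:
        return self.chosen_hours is not None

    def to_dict(self) -> dict:
        return {
            "projected_concentration_bqm3": self.c_projected,
            "reference_level_bqm3": self.c_rl,
            "resolvable": self.resolvable,
            "chosen_hours": self.chosen_hours,
            "projections": [dict(p) for p in self.projections],
        }


def project_device_ud(
    device: DeviceCountData, c_projected: float, t_hours: float
) -> float:
    """Projected U_D of a counting device measuring ``c_projected`` for
    ``t_hours``, from expected (not sampled) count rates.

    The expected gross rate is eps * C + r_0; the Poisson term uses the
    candidate duration, the template's background time, and the template's
    systematic u_rel(eps).
    """
    t_s = t_hours * 3600.0
    r_0 = device.r_0
    r_g = device.epsilon * c_projected + r_0
    net = r_g - r_0
    if net <= 0:
        return math.inf
    poisson_var = r_g / t_s + r_0 / device.t_0
    return device.k * math.sqrt(poisson_var / net**2 + device.u_rel_epsilon**2)


def plan_duration(
    c_projected: float,
    uv_curve: TemporalUncertaintyCurve,
    device: DeviceCountData,
    c_rl: float = DEFAULT_REFERENCE_LEVEL_BQM3,
    candidates_hours: Sequence[float] = (48.0, 96.0, 168.0, 336.0, 720.0, 2160.0),
) -> DurationPlan:
    """Smallest candidate duration at which a compliant decision is expected.

    Uses the same U_V curve and the same quadrature rule as the assessment
    itself, with U_D projected from the device template's expected counts at
    the candidate duration.  Candidates below 2 days are rejected.
    """
    if len(candidates_hours) == 0:
        raise ValueError("at least one candidate duration is required")
    cands = sorted(float(t) for t in candidates_hours)
    if cands[0] < 48.0:
        raise SpotMeasurementError(
            f"candidate duration {cands[0]:g} h is below the 2-day minimum"
        )
    projections = []
    chosen = None
    for t in cands:
        u_v = uv_curve(t)
        u_d = project_device_ud(device, c_projected, t)
        if math.isinf(u_d):
            upper = math.inf
        else:
            upper = c_projected * (1.0 + combined_expansion(u_v, u_d))
        decidable = upper < c_rl
        projections.append(
            {
                "t_hours": t,
                "U_V": u_v,
                "U_D": u_d,
                "upper_bound_bqm3": upper,
                "decidable": decidable,
            }
        )
        if decidable and chosen is None:
            chosen = t
    return DurationPlan(
        projections=tuple(projections),
        chosen_hours=chosen,
        c_projected=float(c_projected),
        c_rl=float(c_rl),
    )
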