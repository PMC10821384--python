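"""Parsing and formatting of test durations.

Durations are carried internally as hours (float).  User-facing strings accept
the suffixes ``h`` (hours), ``d`` (days), ``w`` (weeks, 7 d) and ``mo``
(months, 30 d by convention); a bare number is read as hours.
"""

from __future__ import annotations

import re

HOURS_PER_UNIT = {"h": 1.0, "d": 24.0, "w": 168.0, "mo": 720.0}

_DURATION_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*(h|d|w|mo)?\s*$", re.IGNORECASE)


def parse_duration_hours(value: str | float | int) -> float:
    """Parse a duration into hours.

    >>> parse_duration_hours("48h")
    48.0
    >>> parse_duration_hours("2d")
    48.0
    >>> parse_duration_hours("2mo")
    1440.0
    """
    if isinstance(value, (int, float)):
        hours = float(value)
    else:
        m = _DURATION_RE.match(value)
        if m is None:
            raise ValueError(f"cannot parse duration {value!r}")
        hours = float(m.group(1)) * HOURS_PER_UNIT[(m.group(2) or "h").lower()]
    if hours <= 0:
        raise ValueError(f"duration must be positive, got {value!r}")
    return hours


def format_duration(hours: float) -> str:
    """Render hours compactly, preferring whole days."""
    if hours % 24 == 0 and hours >= 24:
        return f"{int(hours // 24)}d"
    return f"{hours:g}h"
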