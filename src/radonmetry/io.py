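"""File formats: YLCM CSV, metadata sidecars, device configs, U_V tables.

YLCM CSV: header ``timestamp,concentration_bqm3``, ISO-8601 timestamps, one
row per registration interval.  Metadata (room id, operation mode,
occupancy, outdoor concentration) lives in a YAML sidecar next to the CSV
(``<name>.meta.yaml``) so the concentration file stays a plain two-column
table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataCompletenessError, YlcmParseError
from .instrument import DeviceCountData, TrackExposureData
from .series import MAX_GAP_FRACTION, RadonSeries
from .temporal import TemporalUncertaintyCurve

logger = logging.getLogger(__name__)

YLCM_COLUMNS = ["timestamp", "concentration_bqm3"]

DEVICE_CLASSES = ("CRM", "charcoal", "electret", "SSNTD", "CDDVD")


def sidecar_path(csv_path: str | Path) -> Path:
    p = Path(csv_path)
    return p.with_suffix(".meta.yaml")


def read_ylcm_csv(
    path: str | Path, max_gap_fraction: float = MAX_GAP_FRACTION
) -> RadonSeries:
    """Read a YLCM CSV (plus optional metadata sidecar) into a RadonSeries.

    Rows must be uniformly spaced in time; missing timestamps are treated as
    gaps and the gap policy of :meth:`RadonSeries.fill_gaps` applies (at most
    5% missing, linearly interpolated).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise YlcmParseError(f"{path}: empty file") from exc
    if list(df.columns) != YLCM_COLUMNS:
        raise YlcmParseError(
            f"{path}: header must be {','.join(YLCM_COLUMNS)}, got {list(df.columns)}"
        )
    if len(df) < 2:
        raise YlcmParseError(f"{path}: need at least two rows to infer the step")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise YlcmParseError(f"{path}: unparseable timestamp ({exc})") from exc
    values = pd.to_numeric(df["concentration_bqm3"], errors="coerce")
    bad = values.isna() & df["concentration_bqm3"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
        raise YlcmParseError(
            f"{path}: non-numeric concentration at line {line}"
        )

    steps = ts.diff().dropna()
    step = steps.mode().iloc[0]
    step_hours = step / pd.Timedelta(hours=1)
    if step_hours <= 0:
        raise YlcmParseError(f"{path}: timestamps are not increasing")
    if not ((steps % step) == pd.Timedelta(0)).all():
        raise YlcmParseError(f"{path}: non-uniform registration step")

    # re-grid onto the uniform axis; absent rows become NaN gaps
    grid = pd.date_range(ts.iloc[0], ts.iloc[-1], freq=step)
    regridded = pd.Series(values.values, index=ts).reindex(grid)

    meta = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = read_metadata(sp)
    series = RadonSeries(
        values=regridded.to_numpy(),
        step_hours=step_hours,
        start_time=grid[0].isoformat(),
        room_id=str(meta.get("room_id", path.stem)),
        mode=str(meta.get("mode", "normal")),
        occupancy_hours_per_day=meta.get("occupancy_hours_per_day"),
        outdoor_concentration=meta.get("outdoor_concentration_bqm3"),
    )
    return series.fill_gaps(max_gap_fraction)


def write_ylcm_csv(series: RadonSeries, path: str | Path) -> None:
    """Write a RadonSeries as YLCM CSV plus a metadata sidecar."""
    path = Path(path)
    index = pd.date_range(
        series.start_time, periods=series.n_samples,
        freq=pd.Timedelta(hours=series.step_hours),
    )
    pd.DataFrame(
        {"timestamp": index.strftime("%Y-%m-%dT%H:%M:%S"),
         "concentration_bqm3": np.round(series.values, 4)}
    ).to_csv(path, index=False)
    meta = {
        "room_id": series.room_id,
        "mode": series.mode,
        "occupancy_hours_per_day": series.occupancy_hours_per_day,
        "outdoor_concentration_bqm3": series.outdoor_concentration,
    }
    write_metadata(sidecar_path(path), meta)


def read_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise YlcmParseError(f"{path}: metadata must be a key-value mapping")
    return data


def write_metadata(path: str | Path, meta: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: v for k, v in meta.items() if v is not None}, fh)


# ----------------------------------------------------------------------
# U_V tables
# ----------------------------------------------------------------------

def read_uv_table(path: str | Path, source: str = "conservative") -> TemporalUncertaintyCurve:
    """Read a U_V curve from CSV with header ``duration_hours,uv``."""
    df = pd.read_csv(path)
    if list(df.columns) != ["duration_hours", "uv"]:
        raise YlcmParseError(
            f"{path}: header must be duration_hours,uv, got {list(df.columns)}"
        )
    knots = tuple(sorted((float(r.duration_hours), float(r.uv)) for r in df.itertuples()))
    return TemporalUncertaintyCurve(knots=knots, source=source)


def write_uv_table(curve: TemporalUncertaintyCurve, path: str | Path) -> None:
    pd.DataFrame(curve.to_rows(), columns=["duration_hours", "uv"]).to_csv(
        path, index=False
    )


# ----------------------------------------------------------------------
# device configs
# ----------------------------------------------------------------------

def read_device_config(path: str | Path):
    """Read a device description (YAML key-value file).

    Counting devices (class CRM/charcoal/electret) need: n_g, t_seconds,
    n_0, t0_seconds, epsilon, u_rel_epsilon [, k].  Track devices
    (SSNTD/CDDVD) need: n_g, n_0, epsilon, t_seconds, u_rel_epsilon,
    u_rel_t [, k].
    """
    cfg = read_metadata(path)
    cls = cfg.get("device_class", "CRM")
    if cls not in DEVICE_CLASSES:
        raise YlcmParseError(
            f"{path}: device_class must be one of {DEVICE_CLASSES}, got {cls!r}"
        )
    try:
        if cls in ("SSNTD", "CDDVD"):
            return TrackExposureData(
                n_g=float(cfg["n_g"]),
                n_0=float(cfg["n_0"]),
                epsilon=float(cfg["epsilon"]),
                t=float(cfg["t_seconds"]),
                u_rel_epsilon=float(cfg.get("u_rel_epsilon", 0.0)),
                u_rel_t=float(cfg.get("u_rel_t", 0.0)),
                k=float(cfg.get("k", 2.0)),
            )
        return DeviceCountData(
            n_g=float(cfg["n_g"]),
            t=float(cfg["t_seconds"]),
            n_0=float(cfg["n_0"]),
            t_0=float(cfg["t0_seconds"]),
            epsilon=float(cfg["epsilon"]),
            u_rel_epsilon=float(cfg.get("u_rel_epsilon", 0.0)),
            k=float(cfg.get("k", 2.0)),
        )
    except KeyError as exc:
        raise YlcmParseError(f"{path}: missing device parameter {exc}") from exc
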