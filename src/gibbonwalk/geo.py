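"""GPS preprocessing: projection, cleaning, segmentation, step series.

Raw relocations arrive as (group, timestamp, lon/lat) rows sampled on a
15-min field protocol.  This module projects them to planar UTM metres,
removes duplicate-timestamp and speed-implausible fixes, cuts each
group's time series into valid trajectory segments (>= 4 consecutive
fixes spanning >= 60 min, gaps bounded by a tolerance), and converts
each segment into the step-length / heading / turning-angle series the
movement models consume.

Conventions: planar metres after projection; headings are measured
anticlockwise from the +x (east) axis via the four-quadrant
arctangent; turning angles live in the half-open interval (-pi, pi]
with the +pi convention at the tie.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeedingPeriod",
    "TrajectorySegment",
    "StepSeries",
    "utm_from_lonlat",
    "lonlat_from_utm",
    "read_fixes",
    "project_to_utm",
    "remove_outliers",
    "segment_trajectory",
    "compute_step_series",
    "assign_period",
    "wrap_angle",
    "preprocess",
]


class FeedingPeriod(str, enum.Enum):
    """Dietary season: fruit-eating April-September, mixed October-March."""

    FRUIT = "fruit"
    MIXED = "mixed"


def assign_period(timestamp) -> FeedingPeriod:
    """Label a date by dietary season (month 4-9 fruit, 10-3 mixed)."""
    month = pd.Timestamp(timestamp).month
    return FeedingPeriod.FRUIT if 4 <= month <= 9 else FeedingPeriod.MIXED


# ---------------------------------------------------------------------------
# UTM projection (WGS84, Krüger series)
# ---------------------------------------------------------------------------
# Transverse-Mercator mapping in the 4th-order Krüger flattening series;
# within a UTM zone the series error is far below field-GPS noise (< 1 mm).

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_S = 10_000_000.0

_N = _WGS84_F / (2.0 - _WGS84_F)
_A_BAR = _WGS84_A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0)

_ALPHA = (
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 5.0 * _N**3 / 16.0 + 41.0 * _N**4 / 180.0,
    13.0 * _N**2 / 48.0 - 3.0 * _N**3 / 5.0 + 557.0 * _N**4 / 1440.0,
    61.0 * _N**3 / 240.0 - 103.0 * _N**4 / 140.0,
    49561.0 * _N**4 / 161280.0,
)
_BETA = (
    _N / 2.0 - 2.0 * _N**2 / 3.0 + 37.0 * _N**3 / 96.0 - _N**4 / 360.0,
    _N**2 / 48.0 + _N**3 / 15.0 - 437.0 * _N**4 / 1440.0,
    17.0 * _N**3 / 480.0 - 37.0 * _N**4 / 840.0,
    4397.0 * _N**4 / 161280.0,
)
_DELTA = (
    2.0 * _N - 2.0 * _N**2 / 3.0 - 2.0 * _N**3 + 116.0 * _N**4 / 45.0,
    7.0 * _N**2 / 3.0 - 8.0 * _N**3 / 5.0 - 227.0 * _N**4 / 45.0,
    56.0 * _N**3 / 15.0 - 136.0 * _N**4 / 35.0,
    4279.0 * _N**4 / 630.0,
)


def central_meridian(zone: int) -> float:
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return 6.0 * zone - 183.0


def utm_from_lonlat(lon, lat, zone: int, northern: bool = True):
    """Project WGS84 lon/lat (degrees) to UTM easting/northing (metres)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam = np.radians(lon - central_meridian(zone))
    phi = np.radians(lat)

    e2s = 2.0 * np.sqrt(_N) / (1.0 + _N)
    t = np.sinh(np.arctanh(np.sin(phi)) - e2s * np.arctanh(e2s * np.sin(phi)))
    xi = np.arctan2(t, np.cos(lam))
    eta = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    x = eta.copy()
    y = xi.copy()
    for j, aj in enumerate(_ALPHA, start=1):
        x += aj * np.cos(2 * j * xi) * np.sinh(2 * j * eta)
        y += aj * np.sin(2 * j * xi) * np.cosh(2 * j * eta)

    easting = _FALSE_EASTING + _K0 * _A_BAR * x
    northing = _K0 * _A_BAR * y
    if not northern:
        northing = northing + _FALSE_NORTHING_S
    return easting, northing


def lonlat_from_utm(easting, northing, zone: int, northern: bool = True):
    """Inverse UTM mapping back to WGS84 lon/lat degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    if not northern:
        northing = northing - _FALSE_NORTHING_S

    xi = northing / (_K0 * _A_BAR)
    eta = (easting - _FALSE_EASTING) / (_K0 * _A_BAR)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, bj in enumerate(_BETA, start=1):
        xi_p -= bj * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p -= bj * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
    phi = chi.copy()
    for j, dj in enumerate(_DELTA, start=1):
        phi += dj * np.sin(2 * j * chi)

    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    return np.degrees(lam) + central_meridian(zone), np.degrees(phi)


# ---------------------------------------------------------------------------
# fix tables
# ---------------------------------------------------------------------------

#: expected CSV columns; either (lon, lat) or (x, y) must be present
FIX_COLUMNS = ("group_id", "timestamp")


def read_fixes(path) -> pd.DataFrame:
    """Read a relocation table (CSV with group_id, timestamp, lon/lat or x/y)."""
    df = pd.read_csv(path)
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fix table missing columns {missing}")
    has_geo = {"lon", "lat"}.issubset(df.columns)
    has_xy = {"x", "y"}.issubset(df.columns)
    if not (has_geo or has_xy):
        raise ValueError("fix table needs either lon/lat or x/y columns")
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def project_to_utm(fixes: pd.DataFrame, zone: int = 49, northern: bool = True) -> pd.DataFrame:
    """Add projected x/y columns (UTM metres) to a fix table.

    Fixes already carrying x/y pass through unchanged.  Records with no
    usable coordinates are rejected; lon/lat outside the nominal zone
    width triggers a warning but is still projected (UTM remains
    well-defined slightly outside the zone).
    """
    df = fixes.copy()
    if {"x", "y"}.issubset(df.columns) and df[["x", "y"]].notna().all(axis=None):
        return df
    if not {"lon", "lat"}.issubset(df.columns):
        raise ValueError("no lon/lat columns to project")
    bad = df["lon"].isna() | df["lat"].isna()
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} fixes with missing coordinates")
        df = df.loc[~bad].copy()
    cm = central_meridian(zone)
    off = (df["lon"] - cm).abs()
    if (off > 3.0).any():
        warnings.warn(
            f"{int((off > 3.0).sum())} fixes lie outside the nominal width of "
            f"UTM zone {zone}; projecting anyway"
        )
    x, y = utm_from_lonlat(df["lon"].to_numpy(), df["lat"].to_numpy(), zone, northern)
    df["x"] = x
    df["y"] = y
    return df


def remove_outliers(
    fixes: pd.DataFrame,
    max_step_speed: float = 1000.0,
    base_interval_min: float = 15.0,
) -> pd.DataFrame:
    """Drop duplicate timestamps and speed-implausible fixes.

    ``max_step_speed`` is the largest credible displacement (metres) per
    ``base_interval_min`` of elapsed time; a fix whose displacement from
    the previously retained fix exceeds the linearly time-scaled cap is
    treated as a GPS blunder and dropped.  Operates per group; output is
    time-sorted.
    """
    if fixes.empty:
        return fixes.copy()
    if not {"x", "y"}.issubset(fixes.columns):
        raise ValueError("fixes must be projected before outlier removal")

    out = []
    for _, g in fixes.groupby("group_id", sort=False):
        g = g.sort_values("timestamp", kind="stable")
        g = g.drop_duplicates(subset="timestamp", keep="first")
        if not g["timestamp"].is_monotonic_increasing:
            raise ValueError("timestamps not strictly increasing after dedup")
        t = g["timestamp"].to_numpy()
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        keep = np.zeros(len(g), dtype=bool)
        keep[0] = True
        last = 0
        for i in range(1, len(g)):
            dt_min = (t[i] - t[last]) / np.timedelta64(60, "s")
            cap = max_step_speed * max(dt_min, base_interval_min) / base_interval_min
            if np.hypot(x[i] - x[last], y[i] - y[last]) <= cap:
                keep[i] = True
                last = i
        out.append(g.loc[keep])
    return pd.concat(out).reset_index(drop=True)


@dataclass
class TrajectorySegment:
    """A validated run of consecutive fixes for one group.

    Satisfies the field validity rule: at least ``min_fixes`` fixes,
    spanning at least ``min_span`` minutes, with no internal gap above
    the tolerance.  ``period`` is the dietary season of the first fix.
    """

    group_id: str
    fixes: pd.DataFrame
    segment_id: str = ""
    period: FeedingPeriod = field(default=FeedingPeriod.FRUIT)

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def start(self):
        return self.fixes["timestamp"].iloc[0]


def segment_trajectory(
    fixes: pd.DataFrame,
    min_fixes: int = 4,
    min_span_min: float = 60.0,
    gap_tolerance_min: float = 45.0,
) -> list[TrajectorySegment]:
    """Cut cleaned fixes into valid trajectory segments.

    Each group's time series is split wherever the gap between
    consecutive fixes exceeds ``gap_tolerance_min``; runs with fewer
    than ``min_fixes`` fixes or spanning less than ``min_span_min``
    minutes are discarded.
    """
    segments: list[TrajectorySegment] = []
    if fixes.empty:
        return segments
    for gid, g in fixes.groupby("group_id", sort=False):
        g = g.sort_values("timestamp", kind="stable").reset_index(drop=True)
        gaps = g["timestamp"].diff().dt.total_seconds().to_numpy() / 60.0
        breakpoints = np.flatnonzero(gaps[1:] > gap_tolerance_min) + 1
        for k, run in enumerate(np.split(np.arange(len(g)), breakpoints)):
            if len(run) < min_fixes:
                continue
            sub = g.iloc[run]
            span = (
                sub["timestamp"].iloc[-1] - sub["timestamp"].iloc[0]
            ).total_seconds() / 60.0
            if span < min_span_min:
                continue
            seg = TrajectorySegment(
                group_id=str(gid),
                fixes=sub.reset_index(drop=True),
                segment_id=f"{gid}-{len(segments):04d}",
                period=assign_period(sub["timestamp"].iloc[0]),
            )
            segments.append(seg)
    return segments


def wrap_angle(theta):
    """Wrap angles into (-pi, pi], sending the -pi tie to +pi."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.arctan2(np.sin(theta), np.cos(theta))
    return np.where(np.isclose(wrapped, -np.pi), np.pi, wrapped)


@dataclass
class StepSeries:
    """Per-segment step lengths L_t (m), headings phi_t and turning angles theta_t.

    ``turning_angles`` has one entry per interior fix; entries are NaN
    where an adjacent zero-length step leaves the heading undefined.
    """

    segment_id: str
    step_lengths: np.ndarray
    headings: np.ndarray
    turning_angles: np.ndarray

    def __post_init__(self):
        if len(self.step_lengths) != len(self.headings):
            raise ValueError("one heading per step required")
        if len(self.turning_angles) != max(len(self.step_lengths) - 1, 0):
            raise ValueError("turning-angle count must be n_steps - 1")


def compute_step_series(segment: TrajectorySegment) -> StepSeries:
    """Euclidean step lengths, atan2 headings, wrapped turning angles."""
    x = segment.fixes["x"].to_numpy(dtype=float)
    y = segment.fixes["y"].to_numpy(dtype=float)
    dx = np.diff(x)
    dy = np.diff(y)
    steps = np.hypot(dx, dy)
    headings = np.arctan2(dy, dx)
    headings[steps == 0] = np.nan  # heading undefined for zero-length steps
    theta = wrap_angle(headings[1:] - headings[:-1])
    theta[np.isnan(headings[1:]) | np.isnan(headings[:-1])] = np.nan
    return StepSeries(
        segment_id=segment.segment_id,
        step_lengths=steps,
        headings=headings,
        turning_angles=theta,
    )


def preprocess(
    fixes: pd.DataFrame,
    zone: int = 49,
    max_step_speed: float = 1000.0,
    min_fixes: int = 4,
    min_span_min: float = 60.0,
    gap_tolerance_min: float = 45.0,
):
    """Full preprocessing chain: project, clean, segment.

    Returns ``(segments, log)`` where ``log`` is a per-group dataframe
    of fixes read / dropped / retained, the machine twin of a field
    segmentation log.
    """
    projected = project_to_utm(fixes, zone=zone)
    cleaned = remove_outliers(projected, max_step_speed=max_step_speed)
    segments = segment_trajectory(
        cleaned,
        min_fixes=min_fixes,
        min_span_min=min_span_min,
        gap_tolerance_min=gap_tolerance_min,
    )
    rows = []
    for gid in projected["group_id"].unique():
        n_read = int((fixes["group_id"] == gid).sum())
        n_clean = int((cleaned["group_id"] == gid).sum())
        n_valid = int(sum(s.n_fixes for s in segments if s.group_id == str(gid)))
        rows.append(
            {
                "group_id": gid,
                "fixes_read": n_read,
                "fixes_after_cleaning": n_clean,
                "fixes_in_valid_segments": n_valid,
                "n_segments": sum(1 for s in segments if s.group_id == str(gid)),
            }
        )
    return segments, pd.DataFrame(rows)
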