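"""Geodesic feature engineering for animal telemetry tracks.

Converts raw longitude/latitude fix sequences into the step features a
sequence model consumes — great-circle step length ``d_t`` (km) and movement
angle ``theta_t`` (radians) — and back again via spherical dead reckoning.

Angle conventions
-----------------
``bearing`` (default)
    ``theta_t`` is the forward azimuth of the step ``P_t -> P_{t+1}``,
    clockwise from true north, in ``(-pi, pi]``.  With this convention
    ``(d cos theta, d sin theta)`` are the north and east displacement
    components of the step, and a track is exactly recoverable from the
    features by dead reckoning.
``turning``
    ``theta_t`` is the signed change of azimuth from segment
    ``P_{t-1} P_t`` to segment ``P_t P_{t+1}``, in ``(-pi, pi]`` with an
    exact reversal mapped to ``+pi``.  Recovering positions then requires
    the azimuth of the first segment (``start_azimuth`` in
    :func:`dead_reckon`).

Indexing: a track of ``n`` fixes defines ``n - 1`` segments; the feature
series covers steps ``t = 1 .. n-2`` (0-based) so that every step also has a
preceding segment and hence a defined turning angle — its length is
``n - 2`` under either convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

Convention = Literal["bearing", "turning"]
ZeroStepPolicy = Literal["drop", "carry"]


class GeoValidationError(ValueError):
    """Raised for out-of-range coordinates or malformed tracks/windows."""


class AngleUndefinedError(GeoValidationError):
    """Raised when consecutive fixes coincide and no fill policy applies."""


def wrap_angle(a):
    """Map angle(s) to the half-open interval ``(-pi, pi]``."""
    a = np.asarray(a, dtype=np.float64)
    w = -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)
    return w if w.ndim else float(w)


def _check_lonlat(lon, lat) -> None:
    lon = np.asarray(lon, dtype=np.float64)
    lat = np.asarray(lat, dtype=np.float64)
    if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
        raise GeoValidationError("non-finite coordinate")
    if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
        raise GeoValidationError("coordinate out of range: lon in [-180, 180], lat in [-90, 90]")


def haversine_km(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between two points (degrees in, km out).

    Vectorized over array inputs.  Uses the haversine formula on a sphere of
    mean radius ``radius``.
    """
    _check_lonlat(lon1, lat1)
    _check_lonlat(lon2, lat2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(np.asarray(lon2, dtype=np.float64) - np.asarray(lon1, dtype=np.float64))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if np.ndim(d) else float(d)


def initial_bearing(lon1, lat1, lon2, lat2):
    """Forward azimuth of the great-circle segment, radians in ``(-pi, pi]``.

    Measured clockwise from true north.  Undefined (returns nan) for
    coincident points.
    """
    _check_lonlat(lon1, lat1)
    _check_lonlat(lon2, lat2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, dtype=np.float64) - np.asarray(lon1, dtype=np.float64))
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    same = (np.asarray(y) == 0.0) & (np.asarray(x) == 0.0)
    b = wrap_angle(np.arctan2(y, x))
    b = np.where(same, np.nan, b)
    return b if np.ndim(b) else float(b)


def destination_point(lon, lat, bearing_rad, d_km, radius: float = EARTH_RADIUS_KM):
    """Point reached from (lon, lat) travelling ``d_km`` on azimuth ``bearing_rad``.

    Spherical direct geodesic.  Longitudes wrap to ``(-180, 180]``; a step
    over a pole comes back down the far meridian (no crash, continuous
    great-circle behaviour).
    """
    _check_lonlat(lon, lat)
    delta = np.asarray(d_km, dtype=np.float64) / radius
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    phi2 = np.arcsin(
        np.clip(np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(bearing_rad), -1.0, 1.0)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(bearing_rad) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lon2 = -np.degrees(wrap_angle(-lam2))  # (-180, 180]
    lat2 = np.degrees(phi2)
    if np.ndim(lon2):
        return lon2, lat2
    return float(lon2), float(lat2)


def step_angle(p_prev, p_curr, p_next, convention: Convention = "bearing") -> float:
    """Movement angle at ``p_curr`` given the surrounding fixes.

    Parameters are (lon, lat) pairs in degrees.  See the module docstring
    for the two conventions.  Raises :class:`AngleUndefinedError` when the
    fixes needed by the convention coincide.
    """
    az_out = initial_bearing(p_curr[0], p_curr[1], p_next[0], p_next[1])
    if np.isnan(az_out):
        raise AngleUndefinedError("coincident fixes: outgoing azimuth undefined")
    if convention == "bearing":
        return float(az_out)
    if convention == "turning":
        az_in = initial_bearing(p_prev[0], p_prev[1], p_curr[0], p_curr[1])
        if np.isnan(az_in):
            raise AngleUndefinedError("coincident fixes: incoming azimuth undefined")
        return float(wrap_angle(az_out - az_in))
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawTrack:
    """One individual's ordered sequence of satellite fixes."""

    individual_id: str
    times: np.ndarray  # datetime64[ns] or numeric, strictly increasing
    lons: np.ndarray
    lats: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.lons = np.asarray(self.lons, dtype=np.float64)
        self.lats = np.asarray(self.lats, dtype=np.float64)
        n = len(self.times)
        if not (len(self.lons) == len(self.lats) == n):
            raise GeoValidationError("times/lons/lats length mismatch")
        if n < 1:
            raise GeoValidationError("a track needs at least one fix")
        _check_lonlat(self.lons, self.lats)
        if n > 1 and not np.all(self.times[1:] > self.times[:-1]):
            raise GeoValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def warn_if_irregular(self, tol: float = 0.5) -> None:
        """Warn when sampling intervals vary by more than ``tol`` (fraction
        of the median interval); the feature model assumes even sampling."""
        if len(self) < 3:
            return
        dt = np.diff(self.times).astype("timedelta64[s]").astype(float) if np.issubdtype(
            self.times.dtype, np.datetime64
        ) else np.diff(self.times).astype(float)
        med = np.median(dt)
        if med > 0 and np.any(np.abs(dt - med) > tol * med):
            warnings.warn(
                f"track {self.individual_id!r}: sampling interval varies by more "
                f"than {tol:.0%} of the median; step features assume even sampling",
                stacklevel=2,
            )


@dataclass
class StepSeries:
    """Per-step distances, angles and the 3-column feature matrix.

    ``features`` columns are ``(d cos theta, d sin theta, theta)``.
    """

    d: np.ndarray
    theta: np.ndarray
    features: np.ndarray
    convention: Convention = "bearing"
    individual_id: str | None = None
    step_index: np.ndarray | None = None  # index of each step in the parent track

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        if np.any(self.d < 0):
            raise GeoValidationError("step distances must be non-negative")
        if self.features.shape != (len(self.d), 3):
            raise GeoValidationError("features must be T x 3")

    def __len__(self) -> int:
        return len(self.d)


@dataclass
class SegmentPair:
    """One supervised example: input window ``x`` and target ``y``.

    ``source_indices`` holds the 0-based window-row positions of the x rows
    and y rows; in user-facing subcase notation (``T7P1`` etc.) rows are
    1-based, matching the convention of the tables this layout mirrors.
    """

    x: np.ndarray  # T_in x 3
    y: np.ndarray  # T_out x 2, columns (d cos theta, d sin theta)
    mode: Literal["prediction", "imputation"]
    source_indices: tuple[np.ndarray, np.ndarray] = field(default=None)
    individual_id: str | None = None
    window_start: int | None = None  # step index of window row 0 in the parent series


def featurize(
    track: RawTrack,
    convention: Convention = "bearing",
    zero_step: ZeroStepPolicy = "drop",
) -> StepSeries:
    """Derive the step-feature series from a track of ``n >= 3`` fixes.

    Returns a series of length ``n - 2`` (fewer if zero-length steps are
    dropped).  ``zero_step`` controls steps whose azimuth is undefined
    because consecutive fixes coincide: ``"drop"`` removes them, ``"carry"``
    reuses the previous defined azimuth (distance stays 0).
    """
    n = len(track)
    if n < 3:
        raise GeoValidationError("featurize needs at least 3 fixes")
    # per-segment distance and azimuth, segments i = 0 .. n-2
    d_seg = haversine_km(track.lons[:-1], track.lats[:-1], track.lons[1:], track.lats[1:])
    az_seg = initial_bearing(track.lons[:-1], track.lats[:-1], track.lons[1:], track.lats[1:])
    az_seg = np.atleast_1d(az_seg).astype(np.float64)
    d_seg = np.atleast_1d(d_seg).astype(np.float64)

    az_filled = az_seg.copy()
    if zero_step == "carry":
        for i in range(len(az_filled)):
            if np.isnan(az_filled[i]) and i > 0:
                az_filled[i] = az_filled[i - 1]

    idx, d, theta = [], [], []
    for t in range(1, n - 1):  # steps with a preceding segment
        if convention == "bearing":
            th = az_filled[t]
        else:
            th = wrap_angle(az_filled[t] - az_filled[t - 1])
        if np.isnan(th):
            if zero_step == "drop":
                continue
            raise AngleUndefinedError(f"step {t}: azimuth undefined and no previous azimuth to carry")
        idx.append(t)
        d.append(d_seg[t])
        theta.append(float(th))

    d = np.asarray(d, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    feats = np.column_stack([d * np.cos(theta), d * np.sin(theta), theta]) if len(d) else np.empty((0, 3))
    return StepSeries(
        d=d,
        theta=theta,
        features=feats,
        convention=convention,
        individual_id=track.individual_id,
        step_index=np.asarray(idx, dtype=np.int64),
    )


def dead_reckon(
    start: tuple[float, float],
    start_azimuth: float,
    steps,
    convention: Convention = "bearing",
    individual_id: str = "dead-reckoned",
    t0=None,
    interval=np.timedelta64(1, "h"),
) -> RawTrack:
    """Reconstruct a track from ``(d cos theta, d sin theta)`` step pairs.

    The inverse of :func:`featurize` up to the first step: applying
    :func:`featurize` to the result recovers ``steps[1:]`` (the leading step
    has no preceding segment and therefore no feature row).

    ``start_azimuth`` seeds the heading recursion for the ``turning``
    convention; it is ignored under ``bearing``.  Timestamps are synthesized
    at a fixed ``interval`` from ``t0`` (default: epoch).
    """
    steps = np.asarray(steps, dtype=np.float64).reshape(-1, 2)
    if not np.all(np.isfinite(steps)):
        raise GeoValidationError("steps must be finite")
    lons = [float(start[0])]
    lats = [float(start[1])]
    az = float(start_azimuth)
    for dc, ds in steps:
        d = float(np.hypot(dc, ds))
        local = float(np.arctan2(ds, dc))
        az = local if convention == "bearing" else wrap_angle(az + local)
        lon, lat = destination_point(lons[-1], lats[-1], az, d)
        lons.append(lon)
        lats.append(lat)
    if t0 is None:
        t0 = np.datetime64("2000-01-01T00:00:00")
    times = t0 + np.arange(len(lons)) * interval
    return RawTrack(individual_id=individual_id, times=times, lons=np.array(lons), lats=np.array(lats))


# ---------------------------------------------------------------------------
# segmentation


def slide_segments(features: np.ndarray | StepSeries, window: int, stride: int = 1) -> list[np.ndarray]:
    """Slice a feature series into contiguous windows.

    Returns ``floor((T - window)/stride) + 1`` windows when ``T >= window``,
    else an empty list.  Windows are read-only views in temporal order.
    """
    if window < 1 or stride < 1:
        raise GeoValidationError("window and stride must be >= 1")
    arr = features.features if isinstance(features, StepSeries) else np.asarray(features)
    T = arr.shape[0]
    if T < window:
        return []
    starts = range(0, T - window + 1, stride)
    return [arr[s : s + window] for s in starts]


def make_prediction_pair(window: np.ndarray, t_in: int, t_out: int, **meta) -> SegmentPair:
    """Forecasting layout: first ``t_in`` rows in, last ``t_out`` rows out.

    The target keeps only the two displacement columns.
    """
    window = np.asarray(window, dtype=np.float64)
    if t_in < 1 or t_out < 1:
        raise GeoValidationError("t_in and t_out must be >= 1")
    if window.shape[0] != t_in + t_out:
        raise GeoValidationError(f"window has {window.shape[0]} rows, expected t_in + t_out = {t_in + t_out}")
    x_idx = np.arange(t_in)
    y_idx = np.arange(t_in, t_in + t_out)
    return SegmentPair(
        x=window[x_idx],
        y=window[y_idx, :2],
        mode="prediction",
        source_indices=(x_idx, y_idx),
        **meta,
    )


def make_imputation_pair(window: np.ndarray, k: int, **meta) -> SegmentPair:
    """Interleaved layout: odd 1-based rows in, even 1-based rows out.

    A ``2k``-row window yields ``k`` input rows at 1-based positions
    ``{1, 3, ..., 2k-1}`` and ``k`` target rows at ``{2, 4, ..., 2k}``.
    """
    window = np.asarray(window, dtype=np.float64)
    if k < 1:
        raise GeoValidationError("k must be >= 1")
    if window.shape[0] != 2 * k:
        raise GeoValidationError(f"window has {window.shape[0]} rows, expected 2k = {2 * k}")
    x_idx = np.arange(0, 2 * k, 2)  # 0-based evens == 1-based odds
    y_idx = np.arange(1, 2 * k, 2)
    return SegmentPair(
        x=window[x_idx],
        y=window[y_idx, :2],
        mode="imputation",
        source_indices=(x_idx, y_idx),
        **meta,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_tracks_csv(path) -> list[RawTrack]:
    """Read a track table (columns ``id, timestamp, lon, lat``; ISO-8601
    timestamps) into per-individual tracks, sorted by time."""
    df = pd.read_csv(path)
    required = {"id", "timestamp", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise GeoValidationError(f"track CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    tracks = []
    for ind, g in df.groupby("id", sort=True):
        g = g.sort_values("timestamp")
        tracks.append(
            RawTrack(
                individual_id=str(ind),
                times=g["timestamp"].to_numpy(),
                lons=g["lon"].to_numpy(),
                lats=g["lat"].to_numpy(),
            )
        )
    return tracks


def write_tracks_csv(tracks: Sequence[RawTrack], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "id": t.individual_id,
                "timestamp": pd.to_datetime(t.times).strftime("%Y-%m-%dT%H:%M:%S"),
                "lon": t.lons,
                "lat": t.lats,
            }
        )
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_features_csv(series_list: Sequence[StepSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "id": s.individual_id,
                "step_index": s.step_index,
                "d_km": s.d,
                "theta_rad": s.theta,
                "dcos": s.features[:, 0],
                "dsin": s.features[:, 1],
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
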