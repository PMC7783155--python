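"""Trajectory statistics for spheroid invasion assays.

Works on track tables — tidy DataFrames with columns ``track_id``,
``time_s``, ``x_um``, ``y_um`` — as exported from nucleus tracking
(TrackMate spots CSV) or produced by the simulator. The central statistic
is the mean relative radial migration (RRM): the mean radial distance of
all tracked cells from the spheroid's initial centroid, normalized by its
value at time zero, so a spheroid that stays clustered reads 1 and one
whose cells doubled their mean distance reads 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRACK_COLUMNS = ("track_id", "time_s", "x_um", "y_um")
#: default acquisition cadence of the time-lapse assay, seconds
DEFAULT_INTERVAL_S = 600.0
#: diameter threshold separating small and large spheroids, um
SIZE_THRESHOLD_UM = 100.0
#: window of the linear invasion regime used for velocity fits, hours
VELOCITY_WINDOW_H = 7.5

_TRACKMATE_COLS = {
    "track_id": "TRACK_ID",
    "x_um": "POSITION_X",
    "y_um": "POSITION_Y",
}


def validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Check track-table structure; returns the table sorted by track, time."""
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing column(s): {missing}")
    if len(tracks) == 0:
        raise ValueError("track table is empty")
    num = tracks[["time_s", "x_um", "y_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(num)):
        raise ValueError("track table contains non-finite values")
    out = tracks.sort_values(["track_id", "time_s"], kind="stable", ignore_index=True)
    dt = out.groupby("track_id")["time_s"].diff().dropna()
    if (dt <= 0).any():
        raise ValueError("per-track times must be strictly increasing")
    return out


@dataclass
class RRMSeries:
    """Mean relative radial migration over time (dimensionless, 1 at t0)."""

    times_h: np.ndarray
    values: np.ndarray

    def final(self) -> float:
        return float(self.values[-1])


@dataclass
class SpheroidRecord:
    """One spheroid: initial diameter, fixed centroid, and its tracks."""

    id: str
    diameter_um: float
    centroid_um: tuple[float, float]
    tracks: pd.DataFrame
    rrm: RRMSeries | None = None

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if not np.all(np.isfinite(self.centroid_um)):
            raise ValueError("centroid must be finite")

    def compute_rrm(self) -> RRMSeries:
        self.rrm = mean_rrm(self.tracks, self.centroid_um)
        return self.rrm


def mean_rrm(
    tracks: pd.DataFrame, centroid_um: tuple[float, float]
) -> RRMSeries:
    """Mean relative radial migration series from a track table.

    At each time point the radial distance from the *fixed* centroid is
    averaged over the cells present at that time (cells lost by tracking
    simply drop out of later averages), then normalized by the mean at the
    first time point, which makes the first value exactly 1. The average
    runs over cells, never over time.
    """
    tracks = validate_tracks(tracks)
    xc, yc = centroid_um
    radial = np.hypot(tracks["x_um"] - xc, tracks["y_um"] - yc)
    by_time = radial.groupby(tracks["time_s"]).mean()
    times = by_time.index.to_numpy(dtype=float)
    means = by_time.to_numpy(dtype=float)
    denom = means[0]
    if denom == 0.0:
        raise ValueError(
            "all cells sit at the centroid at t0: mean RRM is undefined"
        )
    values = means / denom
    values[0] = 1.0
    return RRMSeries(times_h=times / 3600.0, values=values)


def estimate_dcell(track: pd.DataFrame, T_s: float | None = None) -> float:
    """Single-track diffusion-coefficient estimate, um^2/s.

    d_cell = (1 / 4T) * sum_j [(x_j - x_{j-1})^2 + (y_j - y_{j-1})^2]
    over the track's consecutive positions, with T the total duration of
    the trajectory (by default its observed time span).
    """
    track = track.sort_values("time_s", kind="stable")
    x = track["x_um"].to_numpy(dtype=float)
    y = track["y_um"].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("a track needs at least two time points")
    if T_s is None:
        t = track["time_s"].to_numpy(dtype=float)
        T_s = float(t[-1] - t[0])
    if T_s <= 0:
        raise ValueError("total duration must be positive")
    sq = np.diff(x) ** 2 + np.diff(y) ** 2
    return float(sq.sum() / (4.0 * T_s))


def population_dcell(tracks: pd.DataFrame) -> tuple[float, float]:
    """Mean and SEM of per-track diffusion estimates across a cohort."""
    tracks = validate_tracks(tracks)
    est = np.array(
        [estimate_dcell(g) for _, g in tracks.groupby("track_id")]
    )
    if len(est) < 2:
        raise ValueError("need at least two tracks for a population SEM")
    return float(est.mean()), float(est.std(ddof=1) / np.sqrt(len(est)))


def invasion_velocity(rrm: RRMSeries, window_h: float = VELOCITY_WINDOW_H) -> float:
    """Slope (RRM units per hour) of an OLS line over the early linear regime.

    Only points with t <= window_h enter the fit; the intercept is free
    (not pinned at RRM = 1).
    """
    mask = rrm.times_h <= window_h
    t = rrm.times_h[mask]
    v = rrm.values[mask]
    if len(t) < 2:
        raise ValueError(f"need at least two points within {window_h} h")
    return float(np.polyfit(t, v, 1)[0])


def split_by_size(
    records: list[SpheroidRecord], threshold_um: float = SIZE_THRESHOLD_UM
) -> tuple[list[SpheroidRecord], list[SpheroidRecord]]:
    """Partition spheroids into small (< threshold) and large (>= threshold)."""
    small = [r for r in records if r.diameter_um < threshold_um]
    large = [r for r in records if r.diameter_um >= threshold_um]
    return small, large


def group_mean_rrm(series: list[RRMSeries]) -> RRMSeries:
    """Pointwise average of RRM curves sharing a common time grid."""
    if not series:
        raise ValueError("no series to average")
    t0 = series[0].times_h
    for s in series[1:]:
        if len(s.times_h) != len(t0) or not np.allclose(s.times_h, t0):
            raise ValueError("series must share a common time grid")
    return RRMSeries(t0.copy(), np.mean([s.values for s in series], axis=0))


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of cumulative distributions.

    Returns (statistic, asymptotic p-value); the statistic is the supremum
    distance between the two empirical CDFs.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def read_tracks(path, interval_s: float = DEFAULT_INTERVAL_S) -> pd.DataFrame:
    """Read a TrackMate-spots-style CSV into a track table.

    Requires TRACK_ID, POSITION_X, POSITION_Y and either POSITION_T
    (seconds) or FRAME (converted via ``interval_s``). Non-numeric header
    padding rows, as in newer TrackMate exports, are dropped.
    """
    raw = pd.read_csv(path)
    for key, col in _TRACKMATE_COLS.items():
        if col not in raw.columns:
            raise ValueError(f"tracks file {path} is missing column {col!r}")
    if "POSITION_T" not in raw.columns and "FRAME" not in raw.columns:
        raise ValueError(
            f"tracks file {path} needs a POSITION_T or FRAME column"
        )
    cols = ["TRACK_ID", "POSITION_X", "POSITION_Y"] + [
        c for c in ("POSITION_T", "FRAME") if c in raw.columns
    ]
    num = raw[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if "POSITION_T" in num.columns:
        time_s = num["POSITION_T"].to_numpy(dtype=float)
    else:
        time_s = num["FRAME"].to_numpy(dtype=float) * interval_s
    out = pd.DataFrame(
        {
            "track_id": num["TRACK_ID"].astype(int),
            "time_s": time_s,
            "x_um": num["POSITION_X"].astype(float),
            "y_um": num["POSITION_Y"].astype(float),
        }
    )
    return validate_tracks(out)


def write_tracks(
    tracks: pd.DataFrame, path, interval_s: float = DEFAULT_INTERVAL_S
) -> None:
    """Write a track table as a TrackMate-spots-style CSV (um, seconds)."""
    tracks = validate_tracks(tracks)
    out = pd.DataFrame(
        {
            "TRACK_ID": tracks["track_id"],
            "FRAME": np.rint(tracks["time_s"] / interval_s).astype(int),
            "POSITION_X": tracks["x_um"],
            "POSITION_Y": tracks["y_um"],
            "POSITION_T": tracks["time_s"],
        }
    )
    out.to_csv(path, index=False)
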