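"""Cell-track filtering, directionality, and region/phase velocity summaries.

Tracks (one ordered (frame, x, y) sample list per cell) are windowed into
two condensation phases, split into head and tail halves of the tissue,
and summarized by the angle of each start-to-end vector (zero set on the
horizontal head-to-tail axis), a polar histogram of those angles, and the
mean average velocity (path length over duration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Phase windows in minutes from the start of condensation:
#: 0-3 h (phase 1) and 7-10 h (phase 2).
DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 180.0), (420.0, 600.0))

#: A track is kept only if its within-window portion is longer than this
#: many frames (strictly greater, i.e. at least 11 samples at 10 min/frame).
DEFAULT_MIN_FRAMES = 10


@dataclass
class TrackDirectionalitySummary:
    """Start-to-end directionality of a track set.

    ``angles`` are in [0, 2*pi), measured from the head-to-tail axis
    (x increasing head to tail); a track moving tail-to-head therefore has
    angle pi. Tracks with zero net displacement have no defined angle and
    are counted in ``n_undefined``.
    """

    angles: np.ndarray
    histogram: np.ndarray
    bin_edges: np.ndarray
    n_tracks: int
    n_undefined: int
    mean_average_velocity: float  # um/min

    @property
    def mean_resultant_length(self) -> float:
        """Circular concentration of the angle distribution (0 = isotropic)."""
        if len(self.angles) == 0:
            return 0.0
        return float(
            np.hypot(np.cos(self.angles).mean(), np.sin(self.angles).mean())
        )


def load_tracks(path) -> pd.DataFrame:
    """Read a track table CSV with columns track_id, frame, x_um, y_um."""
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"track table must have columns {sorted(required)}")
    return df


def filter_and_window_tracks(
    tracks: pd.DataFrame,
    frame_interval: float = 10.0,
    min_frames: int = DEFAULT_MIN_FRAMES,
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS,
    region_boundary: float | None = None,
) -> dict[tuple[str, tuple[float, float]], pd.DataFrame]:
    """Split tracks by (region, time window) and drop short fragments.

    A track enters a set iff its portion inside the window has more than
    ``min_frames`` samples. The region is assigned from the track's mean
    x position relative to ``region_boundary`` (head = smaller x; default
    boundary is the midline of the observed x range).
    """
    if region_boundary is None:
        region_boundary = float(
            (tracks["x_um"].min() + tracks["x_um"].max()) / 2.0
        )
    t_max = tracks["frame"].max() * frame_interval
    out: dict[tuple[str, tuple[float, float]], pd.DataFrame] = {}
    for window in windows:
        t0, t1 = window
        if t0 > t_max:
            warnings.warn(f"window {window} lies outside the recording", stacklevel=2)
        times = tracks["frame"] * frame_interval
        sub = tracks[(times >= t0) & (times <= t1)]
        for region in ("head", "tail"):
            kept = []
            for tid, grp in sub.groupby("track_id"):
                if len(grp) <= min_frames:
                    continue
                mean_x = grp["x_um"].mean()
                r = "head" if mean_x < region_boundary else "tail"
                if r == region:
                    kept.append(grp.sort_values("frame"))
            out[(region, window)] = (
                pd.concat(kept, ignore_index=True)
                if kept
                else tracks.iloc[0:0].copy()
            )
    return out


def track_directionality(
    track_set: pd.DataFrame,
    frame_interval: float = 10.0,
    bin_width_deg: float = 20.0,
) -> TrackDirectionalitySummary:
    """Angles of start-to-end vectors, their polar histogram, and mean velocity.

    The mean average velocity is the mean over tracks of total path length
    divided by track duration (the tracking-software "average speed"
    convention), in um/min.
    """
    angles = []
    n_undefined = 0
    speeds = []
    n_tracks = 0
    for tid, grp in track_set.groupby("track_id"):
        grp = grp.sort_values("frame")
        if len(grp) < 2:
            continue
        n_tracks += 1
        xy = grp[["x_um", "y_um"]].to_numpy()
        net = xy[-1] - xy[0]
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        duration = (grp["frame"].iloc[-1] - grp["frame"].iloc[0]) * frame_interval
        if duration > 0:
            speeds.append(steps.sum() / duration)
        if np.allclose(net, 0.0):
            n_undefined += 1
            continue
        angles.append(np.arctan2(net[1], net[0]) % (2 * np.pi))
    angles = np.asarray(angles)
    n_bins = int(round(360.0 / bin_width_deg))
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    hist, _ = np.histogram(angles, bins=edges)
    return TrackDirectionalitySummary(
        angles=angles,
        histogram=hist,
        bin_edges=edges,
        n_tracks=n_tracks,
        n_undefined=n_undefined,
        mean_average_velocity=float(np.mean(speeds)) if speeds else 0.0,
    )


def polar_histogram_figure(summary: TrackDirectionalitySummary):
    """Render the polar histogram; returns a matplotlib Figure."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = (summary.bin_edges[:-1] + summary.bin_edges[1:]) / 2
    width = summary.bin_edges[1] - summary.bin_edges[0]
    ax.bar(centers, summary.histogram, width=width, bottom=0.0, alpha=0.7)
    ax.set_title(
        f"n={summary.n_tracks}, mean speed "
        f"{summary.mean_average_velocity:.3f} um/min"
    )
    return fig
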