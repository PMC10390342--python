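"""Core in-memory containers shared across the pipeline.

Coordinate convention: image axis 0 is y, axis 1 is x; x increases along
the anterior-posterior (AP) axis from head to tail unless a stage is
explicitly told otherwise. Positions are in micrometres, time in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class ImageStack:
    """A single-channel time-lapse stack with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Intensity values, any float or integer dtype.
    pixel_size : float
        Micrometres per pixel (isotropic in x and y).
    frame_interval : float
        Minutes between consecutive frames.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be (T, H, W), got shape {self.data.shape}")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of a frame in micrometres."""
        h, w = self.frame_shape
        return w * self.pixel_size, h * self.pixel_size

    def save_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(
            str(path),
            np.asarray(self.data, dtype=np.float32),
            photometric="minisblack",
            metadata={
                "pixel_size_um": self.pixel_size,
                "frame_interval_min": self.frame_interval,
            },
        )

    @classmethod
    def from_tiff(
        cls, path: str | Path, pixel_size: float, frame_interval: float
    ) -> "ImageStack":
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        return cls(data=data, pixel_size=pixel_size, frame_interval=frame_interval)


@dataclass
class DisplacementFieldSeries:
    """Per-frame-pair displacement vectors on a regular spatial grid.

    ``u`` and ``v`` are in micrometres per frame (x- and y-components);
    entries where ``valid`` is False carry no meaning and are excluded
    from every downstream statistic.
    """

    x: np.ndarray  # (nx,) grid x positions, um
    y: np.ndarray  # (ny,) grid y positions, um
    u: np.ndarray  # (T, ny, nx) um/frame
    v: np.ndarray  # (T, ny, nx)
    valid: np.ndarray  # (T, ny, nx) bool
    frame_interval: float  # min
    corr: np.ndarray | None = None  # (T, ny, nx) peak correlation
    interpolated: bool = False

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.u.shape == self.v.shape == self.valid.shape):
            raise ValueError("u, v and valid must share a shape")
        if self.u.ndim != 3:
            raise ValueError("fields must be (T, ny, nx)")
        if self.u.shape[1:] != (len(self.y), len(self.x)):
            raise ValueError("grid axes inconsistent with field shape")

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    @property
    def grid_spacing(self) -> float:
        if len(self.x) > 1:
            return float(self.x[1] - self.x[0])
        if len(self.y) > 1:
            return float(self.y[1] - self.y[0])
        return 0.0

    def speed_um_per_min(self) -> np.ndarray:
        """(T, ny, nx) vector magnitude converted to um/min; NaN where invalid."""
        s = np.hypot(self.u, self.v) / self.frame_interval
        return np.where(self.valid, s, np.nan)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (frame, x_um, y_um, u_um_per_frame, v_um_per_frame, corr, valid)."""
        xx, yy = np.meshgrid(self.x, self.y)
        rows = []
        for t in range(self.n_frames):
            df = pd.DataFrame(
                {
                    "frame": t,
                    "x_um": xx.ravel(),
                    "y_um": yy.ravel(),
                    "u_um_per_frame": self.u[t].ravel(),
                    "v_um_per_frame": self.v[t].ravel(),
                    "corr": (self.corr[t].ravel() if self.corr is not None else np.nan),
                    "valid": self.valid[t].ravel(),
                }
            )
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def save_csv(self, directory: str | Path, prefix: str = "piv") -> list[Path]:
        """One CSV per frame pair, as ``<prefix>_frame<t>.csv``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        df = self.to_dataframe()
        paths = []
        for t, sub in df.groupby("frame"):
            p = directory / f"{prefix}_frame{t:04d}.csv"
            sub.drop(columns="frame").to_csv(p, index=False)
            paths.append(p)
        return paths


@dataclass
class ForceCurve:
    """An AFM force-spectroscopy approach curve.

    ``z`` is the piezo extension toward the sample and ``deflection`` the
    cantilever deflection, both in nanometres and sampled together.
    """

    z: np.ndarray  # nm, increasing toward the sample
    deflection: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z.shape != self.deflection.shape or self.z.ndim != 1:
            raise ValueError("z and deflection must be matching 1-D arrays")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"z_nm": self.z, "deflection_nm": self.deflection})

    @classmethod
    def from_csv(cls, path: str | Path) -> "ForceCurve":
        df = pd.read_csv(path)
        return cls(z=df["z_nm"].to_numpy(), deflection=df["deflection_nm"].to_numpy())
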