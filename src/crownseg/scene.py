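"""Scene containers: LiDAR point records and multi-channel raster scenes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid

__all__ = ["LidarPoint", "PointCloud", "MultiChannelScene", "TITAN_WAVELENGTHS"]

#: Channel wavelengths (nm) of the three-channel airborne configuration this
#: toolkit emulates: 1550 nm (channel 1), 1064 nm (channel 2), 532 nm (channel 3).
TITAN_WAVELENGTHS: tuple[float, float, float] = (1550.0, 1064.0, 532.0)


@dataclass(frozen=True)
class LidarPoint:
    """A single LiDAR return record."""

    x: float
    y: float
    z: float
    intensity: float
    channel: int
    return_number: int = 1

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.return_number < 1:
            raise ValueError("return_number must be positive")


class PointCloud:
    """Column-oriented collection of LiDAR points.

    Stores the six per-point fields as flat arrays; iterating yields
    :class:`LidarPoint` records.  Built either from arrays or from any
    iterable of points/tuples.
    """

    FIELDS = ("x", "y", "z", "intensity", "channel", "return_number")

    def __init__(self, x, y, z, intensity, channel, return_number) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.z = np.asarray(z, dtype=float)
        self.intensity = np.asarray(intensity, dtype=float)
        self.channel = np.asarray(channel, dtype=int)
        self.return_number = np.asarray(return_number, dtype=int)
        n = len(self.x)
        for name in self.FIELDS:
            if len(getattr(self, name)) != n:
                raise ValueError("point-cloud columns have unequal lengths")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if np.any(self.return_number < 1):
            raise ValueError("return_number must be positive")

    @classmethod
    def from_points(cls, points) -> "PointCloud":
        rows = [
            (p.x, p.y, p.z, p.intensity, p.channel, p.return_number)
            if isinstance(p, LidarPoint)
            else tuple(p)
            for p in points
        ]
        if not rows:
            return cls([], [], [], [], [], [])
        cols = list(zip(*rows))
        return cls(*cols)

    def __len__(self) -> int:
        return len(self.x)

    def __iter__(self):
        for i in range(len(self)):
            yield LidarPoint(
                float(self.x[i]),
                float(self.y[i]),
                float(self.z[i]),
                float(self.intensity[i]),
                int(self.channel[i]),
                int(self.return_number[i]),
            )

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(*(getattr(self, f)[mask] for f in self.FIELDS))


@dataclass
class MultiChannelScene:
    """A canopy height model with co-registered per-channel intensity rasters.

    All rasters share dimensions, cell size and origin.  ``tree_mask`` flags
    vegetation pixels retained by the preprocessing mask; when absent it is
    all-True.
    """

    chm: RasterGrid
    intensity: list[RasterGrid]
    channel_wavelengths: tuple[float, ...] = TITAN_WAVELENGTHS
    tree_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for band in self.intensity:
            self.chm.require_same_geometry(band, "scene intensity band")
        if len(self.channel_wavelengths) != len(self.intensity):
            raise ValueError("one wavelength per intensity band required")
        if self.tree_mask is None:
            self.tree_mask = np.ones(self.chm.shape, dtype=bool)
        self.tree_mask = np.asarray(self.tree_mask, dtype=bool)
        if self.tree_mask.shape != self.chm.shape:
            raise ValueError("tree_mask shape differs from rasters")
        valid_chm = self.chm.values[self.chm.valid]
        if valid_chm.size and valid_chm.min() < -1e-9:
            raise ValueError("CHM must be non-negative at valid pixels")

    @property
    def n_channels(self) -> int:
        return len(self.intensity)

    def channel_index(self, wavelength: float) -> int:
        """Index of the band closest to ``wavelength`` (nm)."""
        diffs = [abs(w - wavelength) for w in self.channel_wavelengths]
        return int(np.argmin(diffs))

    def intensity_stack(self) -> np.ndarray:
        """Intensities as an array of shape (n_channels, nrows, ncols)."""
        return np.stack([band.values for band in self.intensity])
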