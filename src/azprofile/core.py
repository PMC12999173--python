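"""Core in-memory containers shared by every pipeline stage.

Conventions used throughout the package:

* Voxel arrays are indexed ``(z, y, x)`` (page order of a multi-page TIFF).
* ``spacing`` is the physical voxel size in micrometres per axis, stored in
  the same ``(dz, dy, dx)`` order as the array axes.  Confocal stacks are
  typically anisotropic (e.g. 0.079 x 0.079 um laterally, 0.370 um axially),
  so every physical distance in the package is computed with the anisotropic
  spacing, never in index space.
* Physical point coordinates in tables are ``(x_um, y_um, z_um)`` with the
  position of voxel ``(iz, iy, ix)`` at ``(ix*dx, iy*dy, iz*dz)`` (voxel
  centres; the origin voxel sits at 0).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

Spacing = tuple[float, float, float]

#: column order of a cluster table CSV
CLUSTER_COLUMNS = [
    "id", "x_um", "y_um", "z_um", "volume_vox", "intensity",
    "seed_z", "seed_y", "seed_x", "compartment",
]

#: column order of a ground-truth CSV written by the synthetic generator
TRUTH_COLUMNS = [
    "id", "x_um", "y_um", "z_um", "intensity",
    "sigma_xy_um", "sigma_z_um", "compartment",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named random stream: one top-level seed, one independent stream per
    pipeline stage, so stages can be regenerated without replaying others."""
    key = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _check_spacing(spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values (dz, dy, dx), got {spacing}")
    return spacing


@dataclass
class VolumetricImage:
    """A 3D voxel array with physical spacing (um), axis order (z, y, x)."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D array, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def physical_size(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def copy_with(self, data: np.ndarray) -> "VolumetricImage":
        return VolumetricImage(data=data, spacing=self.spacing)


@dataclass
class LabelVolume:
    """Integer compartment labels on the voxel grid; 0 is background."""

    labels: np.ndarray
    spacing: Spacing
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label array, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer typed")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def foreground_fraction(self) -> float:
        return float(np.count_nonzero(self.labels)) / self.labels.size

    def foreground_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return float(np.count_nonzero(self.labels)) * dz * dy * dx

    def name_of(self, label: int) -> str:
        return self.names.get(int(label), str(int(label)))

    def label_at_points(self, points_um: np.ndarray) -> np.ndarray:
        """Label under each (x, y, z) um point (nearest voxel; outside -> 0)."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        dz, dy, dx = self.spacing
        iz = np.rint(pts[:, 2] / dz).astype(int)
        iy = np.rint(pts[:, 1] / dy).astype(int)
        ix = np.rint(pts[:, 0] / dx).astype(int)
        nz, ny, nx = self.labels.shape
        inside = (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        out = np.zeros(len(pts), dtype=self.labels.dtype)
        out[inside] = self.labels[iz[inside], iy[inside], ix[inside]]
        return out

    def names_of_points(self, points_um: np.ndarray) -> list[str]:
        return [self.name_of(l) if l else "" for l in self.label_at_points(points_um)]


@dataclass
class PointSpreadFunction:
    """Small normalized blur kernel estimated from sub-resolution beads."""

    kernel: np.ndarray
    spacing: Spacing
    n_beads_averaged: int = 1

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 3:
            raise ValueError("PSF kernel must be 3D")
        if np.any(self.kernel < 0):
            raise ValueError("PSF kernel must be non-negative")
        total = float(self.kernel.sum())
        if total <= 0:
            raise ValueError("PSF kernel must have positive sum")
        self.kernel = self.kernel / total
        self.spacing = _check_spacing(self.spacing)

    def centroid_offset_vox(self) -> np.ndarray:
        """Intensity centroid minus geometric centre, in voxels per axis."""
        grids = np.indices(self.kernel.shape)
        c = np.array([float((g * self.kernel).sum()) for g in grids])
        geo = (np.array(self.kernel.shape) - 1) / 2.0
        return c - geo


@dataclass
class ClusterTable:
    """Per-sample table of segmented clusters plus derived spatial statistics.

    ``df`` always carries :data:`CLUSTER_COLUMNS`; the spatial-statistics
    stage appends ``nnd_um``, ``az_density`` and ``local_intensity`` columns
    and fills ``mean_nnd`` / ``radius_r`` (defined only for >= 2 clusters).
    """

    df: pd.DataFrame
    sample_id: str = ""
    condition: str = ""
    spacing: Optional[Spacing] = None
    mean_nnd: Optional[float] = None
    radius_r: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [c for c in CLUSTER_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cluster table missing column(s): {', '.join(missing)}")
        if self.df["id"].duplicated().any():
            raise ValueError("cluster ids must be unique")
        if self.spacing is not None:
            self.spacing = _check_spacing(self.spacing)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of (x, y, z) centroids in um."""
        return self.df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return self.df["intensity"].to_numpy(dtype=float)

    def copy(self) -> "ClusterTable":
        return replace(self, df=self.df.copy())


def empty_cluster_df() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        CLUSTER_COLUMNS,
        [int, float, float, float, int, float, int, int, int, object],
    )})
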