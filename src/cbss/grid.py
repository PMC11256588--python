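"""Spatial carriers: scalar/label voxel grids and low-b diffusion series.

Everything downstream works on a common 3-D grid with physical voxel
spacing in millimetres; distances are always computed in mm so that the
anisotropic 2 x 2 x 4 mm acquisition geometry is honoured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "AcquisitionScheme", "DiffusionSeries", "default_low_b_scheme"]

#: b-values (s/mm^2) of the low-b acquisition emulated by the phantom.
LOW_B_VALUES = (0, 10, 20, 30, 50, 70, 90, 110, 130, 150, 170, 200, 500, 800, 1000, 1500)


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D scalar or label field with physical voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"VoxelGrid expects a 3-D array, got shape {arr.shape}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def like(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid with the same spacing carrying ``data``."""
        if np.shape(data)[:3] != self.shape:
            raise ValueError("shape mismatch with template grid")
        return VoxelGrid(np.asarray(data), self.spacing)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values and gradient directions of a diffusion series.

    Parameters
    ----------
    bvals : array of shape (n_volumes,)
        b-value of each volume in s/mm^2.
    bvecs : array of shape (n_volumes, 3)
        Unit gradient direction per volume; zero vectors for b=0.
    b_max : float
        Low-b cutoff; only volumes with b <= b_max enter the
        pseudodiffusivity fit (default 200 s/mm^2, below which signal
        attenuation is dominated by intravoxel incoherent motion).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b_max: float = 200.0

    def __post_init__(self) -> None:
        b = np.asarray(self.bvals, dtype=float).ravel()
        v = np.asarray(self.bvecs, dtype=float)
        if v.shape != (b.size, 3):
            raise ValueError(f"bvecs must be (n, 3) matching {b.size} b-values, got {v.shape}")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if self.b_max <= 0:
            raise ValueError("b_max must be positive")
        if np.unique(b[b <= self.b_max]).size < 2:
            raise ValueError("need at least 2 distinct b-values at or below the cutoff")
        object.__setattr__(self, "bvals", b)
        object.__setattr__(self, "bvecs", v)

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    def low_b_mask(self, b_max: float | None = None) -> np.ndarray:
        cutoff = self.b_max if b_max is None else float(b_max)
        return self.bvals <= cutoff

    def n_distinct_low_b(self, b_max: float | None = None) -> int:
        return int(np.unique(self.bvals[self.low_b_mask(b_max)]).size)


@dataclass(frozen=True)
class DiffusionSeries:
    """4-D signal field plus its acquisition table."""

    data: np.ndarray
    scheme: AcquisitionScheme
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 4:
            raise ValueError(f"DiffusionSeries expects a 4-D array, got shape {arr.shape}")
        if arr.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"series has {arr.shape[3]} volumes but the scheme lists "
                f"{self.scheme.n_volumes} b-values"
            )
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def default_low_b_scheme(n_b0: int = 5, b_max: float = 200.0) -> AcquisitionScheme:
    """The emulated low-b scheme: ``n_b0`` b=0 volumes followed by every
    nonzero b-value acquired under 3 gradient directions (x, y, z)."""
    dirs = np.eye(3)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for b in LOW_B_VALUES:
        if b == 0:
            continue
        for d in dirs:
            bvals.append(float(b))
            bvecs.append(d)
    return AcquisitionScheme(np.array(bvals), np.array(bvecs), b_max=b_max)
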