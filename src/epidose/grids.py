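"""Voxel-grid and planar-map containers.

All 3D grids share one convention: ``values`` has shape ``(nx, ny, nz)``,
``spacing_cm`` is per-axis, and ``origin_cm`` is the physical position (cm)
of the *center* of voxel ``(0, 0, 0)``.  The isocenter sits at the
coordinate origin.  2D fluence maps use the analogous ``(nx, ny)``
convention in the plane perpendicular to the beam axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["Grid3D", "DensityGrid", "TermaGrid", "DoseGrid", "FluenceMap"]


def _as_triplet(x) -> np.ndarray:
    a = np.broadcast_to(np.asarray(x, dtype=float), (3,)).copy()
    return a


@dataclass
class Grid3D:
    """A scalar field on a regular 3D lattice."""

    values: np.ndarray
    spacing_cm: np.ndarray
    origin_cm: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise InvalidArgumentError("grid values must be 3D")
        self.spacing_cm = _as_triplet(self.spacing_cm)
        self.origin_cm = _as_triplet(self.origin_cm)
        if np.any(self.spacing_cm <= 0):
            raise InvalidArgumentError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("grid values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing_cm))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (cm) of voxel centers along ``axis``."""
        n = self.values.shape[axis]
        return self.origin_cm[axis] + self.spacing_cm[axis] * np.arange(n)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )

    def same_lattice(self, other: "Grid3D", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing_cm, other.spacing_cm, atol=tol)
            and np.allclose(self.origin_cm, other.origin_cm, atol=tol)
        )

    def with_values(self, values: np.ndarray):
        return replace(self, values=values)


@dataclass
class DensityGrid(Grid3D):
    """Relative electron density (water = 1)."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(self.values < 0):
            raise InvalidArgumentError("density must be non-negative")


@dataclass
class TermaGrid(Grid3D):
    """Total energy released per unit mass (arbitrary calibrated units)."""


@dataclass
class DoseGrid(Grid3D):
    """Absorbed dose (Gy-proportional units carried from calibration)."""


@dataclass
class FluenceMap:
    """2D incident-energy-fluence grid in the beam frame.

    ``plane_distance_cm`` records the source distance of the plane the map
    lives on (100 for the isocenter plane, the SDD for detector-plane maps).
    ``origin_cm`` is the in-plane position of pixel (0, 0) center relative
    to the beam central axis.
    """

    values: np.ndarray
    spacing_cm: float
    origin_cm: tuple = field(default=None)  # type: ignore[assignment]
    plane_distance_cm: float = 100.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidArgumentError("fluence map must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("fluence values must be finite")
        self.spacing_cm = float(self.spacing_cm)
        if self.spacing_cm <= 0:
            raise InvalidArgumentError("spacing must be positive")
        if self.origin_cm is None:
            # default: map centered on the beam axis
            nx, ny = self.values.shape
            self.origin_cm = (
                -0.5 * (nx - 1) * self.spacing_cm,
                -0.5 * (ny - 1) * self.spacing_cm,
            )
        self.origin_cm = (float(self.origin_cm[0]), float(self.origin_cm[1]))

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin_cm[axis] + self.spacing_cm * np.arange(n)

    def sample_bilinear(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Bilinear lookup at in-plane coordinates (cm); outside -> 0."""
        from scipy.ndimage import map_coordinates

        iu = (np.asarray(u, float) - self.origin_cm[0]) / self.spacing_cm
        iv = (np.asarray(v, float) - self.origin_cm[1]) / self.spacing_cm
        return map_coordinates(
            self.values, [iu, iv], order=1, mode="constant", cval=0.0
        )
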