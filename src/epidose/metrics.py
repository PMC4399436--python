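"""Structure-based QA metrics: water override, DVH, dose-difference report."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyStructureError, InvalidArgumentError
from .grids import DensityGrid, DoseGrid, Grid3D

__all__ = [
    "StructureMask",
    "DVHCurve",
    "StructureDiff",
    "DoseDiffReport",
    "override_to_water",
    "compute_dvh",
    "dose_difference_metrics",
]


@dataclass(frozen=True)
class StructureMask:
    name: str
    mask: np.ndarray  # boolean, on the dose lattice

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.dtype != bool:
            m = m.astype(bool)
        if m.ndim != 3:
            raise InvalidArgumentError("mask must be 3D")
        object.__setattr__(self, "mask", m)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram: volume-% receiving >= dose."""

    dose_bin_edges_Gy: np.ndarray
    cumulative_volume_pct: np.ndarray

    def volume_at(self, dose_Gy: float) -> float:
        return float(
            np.interp(dose_Gy, self.dose_bin_edges_Gy, self.cumulative_volume_pct)
        )


@dataclass(frozen=True)
class StructureDiff:
    name: str
    d_mean_epid: float
    d_mean_tps: float
    d_max_epid: float
    d_max_tps: float
    diff_mean_pct: float
    diff_max_pct: float


@dataclass(frozen=True)
class DoseDiffReport:
    prescribed_Gy: float
    structures: tuple  # of StructureDiff


def _check_lattice(grid: Grid3D, mask: StructureMask):
    if grid.values.shape != mask.mask.shape:
        raise InvalidArgumentError(
            f"mask {mask.name!r} not on the grid lattice "
            f"({mask.mask.shape} vs {grid.values.shape})"
        )


def override_to_water(density: DensityGrid, body: StructureMask) -> DensityGrid:
    """Set density to 1.0 (water) inside the body mask; idempotent."""
    _check_lattice(density, body)
    values = density.values.copy()
    values[body.mask] = 1.0
    return DensityGrid(values, density.spacing_cm.copy(), density.origin_cm.copy())


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width_Gy: float = 0.05
) -> DVHCurve:
    """Cumulative DVH of the masked voxels; V(0) = 100%."""
    _check_lattice(dose, mask)
    if bin_width_Gy <= 0:
        raise InvalidArgumentError("bin width must be positive")
    if mask.n_voxels == 0:
        raise EmptyStructureError(f"structure {mask.name!r} is empty")
    d = dose.values[mask.mask]
    top = max(float(d.max()), bin_width_Gy)
    edges = np.arange(0.0, top + 2 * bin_width_Gy, bin_width_Gy)
    # volume fraction receiving at least each edge dose
    vol = np.array([(d >= e).sum() for e in edges]) * (100.0 / d.size)
    vol[0] = 100.0
    return DVHCurve(dose_bin_edges_Gy=edges, cumulative_volume_pct=vol)


def dose_difference_metrics(
    d_epid: DoseGrid,
    d_tps: DoseGrid,
    masks,
    prescribed_Gy: float,
) -> DoseDiffReport:
    """Mean/max dose differences per structure, in % of the prescription:

        diff_mean = (Dmean_epid - Dmean_tps) / D_prescribed * 100
        diff_max  = (Dmax_epid  - Dmax_tps)  / D_prescribed * 100
    """
    if prescribed_Gy <= 0:
        raise InvalidArgumentError("prescribed dose must be positive")
    if not d_epid.same_lattice(d_tps):
        raise InvalidArgumentError("dose grids are not co-registered")
    if isinstance(masks, StructureMask):
        masks = [masks]
    out = []
    for m in masks:
        _check_lattice(d_epid, m)
        if m.n_voxels == 0:
            raise EmptyStructureError(f"structure {m.name!r} is empty")
        de = d_epid.values[m.mask]
        dt = d_tps.values[m.mask]
        mean_e, mean_t = float(de.mean()), float(dt.mean())
        max_e, max_t = float(de.max()), float(dt.max())
        out.append(
            StructureDiff(
                name=m.name,
                d_mean_epid=mean_e,
                d_mean_tps=mean_t,
                d_max_epid=max_e,
                d_max_tps=max_t,
                diff_mean_pct=(mean_e - mean_t) / prescribed_Gy * 100.0,
                diff_max_pct=(max_e - max_t) / prescribed_Gy * 100.0,
            )
        )
    return DoseDiffReport(prescribed_Gy=float(prescribed_Gy), structures=tuple(out))
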