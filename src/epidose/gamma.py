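"""3D gamma-index comparison with resampling, thresholding, and an oracle.

gamma(r) = min over evaluated positions e of
    sqrt(|e - r|^2 / dist_crit^2 + (D_eval(e) - D_ref(r))^2 / dD^2),
dD = dose_crit_pct/100 * max(D_ref) (global normalization).  Voxels of the
*reference* grid below the dose threshold are excluded (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from . import _traverse
from .errors import (
    CostGuardError,
    EmptyResultError,
    InvalidArgumentError,
)
from .grids import DoseGrid, Grid3D

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "resample_trilinear",
    "gamma_3d",
    "gamma_bruteforce_oracle",
]


@dataclass(frozen=True)
class GammaCriteria:
    dose_crit_pct: float = 3.0
    dist_crit_mm: float = 3.0
    threshold_pct: float = 10.0
    gamma_cap: float = 2.0

    def __post_init__(self):
        if min(self.dose_crit_pct, self.dist_crit_mm, self.threshold_pct) <= 0:
            raise InvalidArgumentError("criteria must be positive")
        if self.gamma_cap < 1.0:
            raise InvalidArgumentError("gamma_cap must be >= 1")


@dataclass(frozen=True)
class GammaResult:
    gamma: np.ndarray  # NaN where excluded
    pass_rate_pct: float
    n_evaluated: int
    criteria: GammaCriteria

    @property
    def passed(self) -> np.ndarray:
        return np.asarray(self.gamma <= 1.0 + 1e-9)


def resample_trilinear(grid: Grid3D, new_spacing_cm) -> Grid3D:
    """Trilinear resample preserving the physical extent and corner centers."""
    new_sp = np.broadcast_to(np.asarray(new_spacing_cm, float), (3,)).copy()
    if np.any(new_sp <= 0):
        raise InvalidArgumentError("spacing must be positive")
    if min(grid.values.shape) < 2:
        raise InvalidArgumentError("grid must have >= 2 voxels per axis")
    old_sp = grid.spacing_cm
    if np.allclose(new_sp, old_sp):
        return grid.with_values(grid.values.copy())
    n_old = np.array(grid.values.shape)
    extent = (n_old - 1) * old_sp
    n_new = np.floor(extent / new_sp + 1e-9).astype(int) + 1
    coords = np.meshgrid(
        *[np.arange(n) * new_sp[a] / old_sp[a] for a, n in enumerate(n_new)],
        indexing="ij",
    )
    vals = map_coordinates(grid.values, coords, order=1, mode="nearest")
    return type(grid)(vals, new_sp, grid.origin_cm.copy())


def _sorted_offsets(radius_mm: float, step_mm: float, spacing_mm: np.ndarray):
    """Offsets within the sphere, in evaluated-grid index units, distance-sorted."""
    n = int(np.floor(radius_mm / step_mm))
    ax = np.arange(-n, n + 1) * step_mm
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    d2 = ox**2 + oy**2 + oz**2
    keep = d2 <= radius_mm**2 + 1e-12
    offs_mm = np.column_stack([ox[keep], oy[keep], oz[keep]])
    d2 = d2[keep]
    order = np.argsort(d2, kind="stable")
    offs_mm = offs_mm[order]
    d2 = d2[order]
    offs_idx = offs_mm / spacing_mm[None, :]
    return np.ascontiguousarray(offs_idx), d2


def _prepare(reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria):
    if not np.allclose(reference.origin_cm, evaluated.origin_cm, atol=1e-6):
        raise InvalidArgumentError("reference and evaluated frames differ (origin)")
    ref = resample_trilinear(reference, 0.1)
    evl = resample_trilinear(evaluated, 0.1)
    if ref.values.shape != evl.values.shape:
        raise InvalidArgumentError("grids cover different physical extents")
    ref_max = float(ref.values.max())
    if ref_max <= 0:
        raise EmptyResultError("reference dose is non-positive everywhere")
    dd_abs = criteria.dose_crit_pct / 100.0 * ref_max
    mask = ref.values > criteria.threshold_pct / 100.0 * ref_max
    if not mask.any():
        raise EmptyResultError("all voxels fall below the dose threshold")
    return ref, evl, dd_abs, mask


def _finalize(gamma_vals, mask, ref, criteria) -> GammaResult:
    # pass condition is inclusive (gamma <= 1); the 1e-9 slack only absorbs
    # float rounding of points constructed exactly on the criterion boundary
    n_eval = int(mask.sum())
    passed = np.sum(gamma_vals[mask] <= 1.0 + 1e-9)
    return GammaResult(
        gamma=gamma_vals,
        pass_rate_pct=100.0 * float(passed) / n_eval,
        n_evaluated=n_eval,
        criteria=criteria,
    )


def gamma_3d(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria = GammaCriteria(),
    search_step_mm: float = 0.2,
) -> GammaResult:
    """Shell-search gamma on grids internally resampled to 1 mm.

    Offsets are scanned in order of increasing distance and the scan stops
    once the geometric term alone exceeds the running minimum (admissible
    termination); the search radius is gamma_cap * dist_crit.
    """
    ref, evl, dd_abs, mask = _prepare(reference, evaluated, criteria)
    spacing_mm = ref.spacing_cm * 10.0
    radius = criteria.gamma_cap * criteria.dist_crit_mm
    offs_idx, d2 = _sorted_offsets(radius, search_step_mm, spacing_mm)
    geom = d2 / criteria.dist_crit_mm**2
    gamma_vals = _traverse.gamma_shell_search(
        np.ascontiguousarray(ref.values),
        np.ascontiguousarray(evl.values),
        mask,
        offs_idx,
        geom,
        dd_abs,
        criteria.gamma_cap**2,
        spacing_mm,
        criteria.dist_crit_mm,
        search_step_mm,
    )
    return _finalize(gamma_vals, mask, ref, criteria)


def gamma_bruteforce_oracle(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria = GammaCriteria(),
    search_step_mm: float = 0.1,
    max_voxels: int = 25**3,
) -> GammaResult:
    """Exhaustive gamma over a dense 0.1 mm offset lattice (test oracle)."""
    if int(np.prod(reference.values.shape)) > max_voxels:
        raise CostGuardError(f"oracle limited to {max_voxels} voxels")
    ref, evl, dd_abs, mask = _prepare(reference, evaluated, criteria)
    spacing_mm = ref.spacing_cm * 10.0
    radius = criteria.gamma_cap * criteria.dist_crit_mm
    offs_idx, d2 = _sorted_offsets(radius, search_step_mm, spacing_mm)
    gamma_vals = _traverse.gamma_exhaustive(
        np.ascontiguousarray(ref.values),
        np.ascontiguousarray(evl.values),
        mask,
        offs_idx,
        d2,
        criteria.dist_crit_mm,
        dd_abs,
        criteria.gamma_cap**2,
    )
    return _finalize(gamma_vals, mask, ref, criteria)
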