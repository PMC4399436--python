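"""3D dose computation: TERMA ray tracing and collapsed-cone superposition.

Beam geometry convention (IEC-style gantry about the +y axis):

* gantry 0: source at ``isocenter + (0, 0, +sad)``, beam propagating -z;
* gantry ``g`` (deg): source at ``isocenter + sad * (sin g, 0, cos g)``;
* beam-frame transverse axes ``e_u = (cos g, 0, -sin g)``, ``e_v = (0, 1, 0)``.

Cone-set directions are given in the beam frame with +z along the beam
propagation direction and are rotated into the grid frame before marching.
The kernel axes stay aligned to the beam axis (no tilting with divergence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _traverse
from .beam_model import (
    AttenuationTable,
    BeamModel,
    CCKTable,
    ConeSet,
    PointKernel,
    Spectrum,
    attenuation_lookup,
)
from .errors import CostGuardError, InvalidArgumentError
from .grids import DensityGrid, DoseGrid, FluenceMap, TermaGrid

__all__ = [
    "BeamGeometry",
    "radiological_depth",
    "compute_terma",
    "collapsed_cone_superpose",
    "point_kernel_superpose_oracle",
    "reconstruct_plan_dose",
]


@dataclass
class BeamGeometry:
    """Source/beam-frame description of one treatment field."""

    fluence: FluenceMap
    gantry_deg: float = 0.0
    sad_cm: float = 100.0
    isocenter_cm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.sad_cm <= 0:
            raise InvalidArgumentError("sad_cm must be positive")

    @property
    def source_cm(self) -> np.ndarray:
        g = math.radians(self.gantry_deg)
        iso = np.asarray(self.isocenter_cm, float)
        return iso + self.sad_cm * np.array([math.sin(g), 0.0, math.cos(g)])

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(e_u, e_v, b_hat): transverse axes and propagation direction."""
        g = math.radians(self.gantry_deg)
        e_u = np.array([math.cos(g), 0.0, -math.sin(g)])
        e_v = np.array([0.0, 1.0, 0.0])
        b_hat = -np.array([math.sin(g), 0.0, math.cos(g)])
        return e_u, e_v, b_hat

    def rotation(self) -> np.ndarray:
        """3x3 matrix taking beam-frame vectors into the grid frame."""
        e_u, e_v, b_hat = self.frame()
        return np.column_stack([e_u, e_v, b_hat])


def radiological_depth(density: DensityGrid, source_cm, target_cm) -> float:
    """Water-equivalent depth along the segment source -> target (cm)."""
    p0 = np.asarray(source_cm, float)
    p1 = np.asarray(target_cm, float)
    if not (np.all(np.isfinite(p0)) and np.all(np.isfinite(p1))):
        raise InvalidArgumentError("segment endpoints must be finite")
    return float(
        _traverse.seg_raddepth(
            np.ascontiguousarray(density.values),
            density.spacing_cm,
            density.origin_cm,
            p0,
            p1,
        )
    )


def compute_terma(
    fluence: FluenceMap,
    density: DensityGrid,
    spectrum: Spectrum,
    table: AttenuationTable,
    geom: BeamGeometry | None = None,
) -> TermaGrid:
    """TERMA by one divergent ray per voxel center.

    Per voxel: bilinear fluence lookup at the isocenter-plane projection of
    the voxel along its ray, scaled by inverse square from the source, times
    sum_E w_E (mu/rho)(E) exp(-(mu/rho)(E) * d_rad) with d_rad the
    radiological depth from the grid entry to the voxel center.
    """
    if geom is None:
        geom = BeamGeometry(fluence=fluence)
    if geom.fluence is not fluence:
        geom = BeamGeometry(
            fluence=fluence,
            gantry_deg=geom.gantry_deg,
            sad_cm=geom.sad_cm,
            isocenter_cm=geom.isocenter_cm,
        )
    mu = np.array(
        [attenuation_lookup(table, e) for e in spectrum.energies_MeV], dtype=float
    )
    w = spectrum.weights

    rho = np.ascontiguousarray(density.values)
    src = geom.source_cm
    e_u, e_v, b_hat = geom.frame()

    X, Y, Z = density.voxel_centers()
    wx = X - src[0]
    wy = Y - src[1]
    wz = Z - src[2]
    dist2 = wx * wx + wy * wy + wz * wz
    t_axis = wx * b_hat[0] + wy * b_hat[1] + wz * b_hat[2]
    # voxels upstream of (or at) the source get no primary fluence
    valid = t_axis > 1e-6
    t_safe = np.where(valid, t_axis, 1.0)
    u = (wx * e_u[0] + wy * e_u[1] + wz * e_u[2]) * geom.sad_cm / t_safe
    v = (wx * e_v[0] + wy * e_v[1] + wz * e_v[2]) * geom.sad_cm / t_safe
    f = fluence.sample_bilinear(u, v)
    f = np.where(valid, f, 0.0)

    d_rad = _traverse.raddepth_to_centers(
        rho, density.spacing_cm, density.origin_cm, src
    )
    # sum over spectrum bins (water mass density 1 g/cm^3 for d_rad scaling)
    attn = np.zeros_like(d_rad)
    for mu_e, w_e in zip(mu, w):
        attn += w_e * mu_e * np.exp(-mu_e * d_rad)

    values = f * (geom.sad_cm**2 / dist2) * attn
    return TermaGrid(values, density.spacing_cm.copy(), density.origin_cm.copy())


def collapsed_cone_superpose(
    terma: TermaGrid,
    density: DensityGrid,
    cck: CCKTable,
    cones: ConeSet,
    rotation: np.ndarray | None = None,
) -> DoseGrid:
    """Superpose TERMA through the CCK tables along the collapsed cones.

    ``rotation`` takes beam-frame directions into the grid frame; identity
    means the beam propagates along +z of the grid.
    """
    if not terma.same_lattice(density):
        raise InvalidArgumentError("terma and density lattices differ")
    if cck.K.shape[0] != np.unique(cones.zenith_band).size:
        raise InvalidArgumentError("CCK bands do not match the cone set")
    R = np.eye(3) if rotation is None else np.asarray(rotation, float)
    # transport directions in grid frame; receivers march upstream (-omega)
    omega = cones.directions @ R.T
    march = np.ascontiguousarray(-omega)
    values = _traverse.cone_superpose(
        np.ascontiguousarray(terma.values),
        np.ascontiguousarray(density.values),
        density.spacing_cm,
        density.origin_cm,
        march,
        cones.zenith_band,
        np.ascontiguousarray(cck.C),
        cck.step_cm,
        cck.r_cut_cm,
        cones.n_azimuth,
    )
    return DoseGrid(values, density.spacing_cm.copy(), density.origin_cm.copy())


def point_kernel_superpose_oracle(
    terma: TermaGrid,
    density: DensityGrid,
    kernel: PointKernel,
    beam_axis=(0.0, 0.0, 1.0),
    max_voxels: int = 31**3,
    n_sub: int = 10,
) -> DoseGrid:
    """Brute-force point-kernel superposition (test oracle, O(N^6))."""
    if not terma.same_lattice(density):
        raise InvalidArgumentError("terma and density lattices differ")
    n = int(np.prod(terma.values.shape))
    if n > max_voxels:
        raise CostGuardError(f"oracle limited to {max_voxels} voxels, got {n}")
    axis = np.asarray(beam_axis, float)
    axis = axis / np.linalg.norm(axis)
    zedges = np.deg2rad(kernel.zenith_bin_edges_deg)
    # all-band cumulative radial mass for source-voxel self dose
    gcum_v = np.concatenate([[0.0], np.cumsum(kernel.energy_fraction.sum(axis=0))])
    values = _traverse.brute_force_superpose(
        np.ascontiguousarray(terma.values),
        np.ascontiguousarray(density.values),
        density.spacing_cm,
        density.origin_cm,
        axis,
        zedges,
        kernel.radial_bin_edges_cm,
        np.ascontiguousarray(kernel.energy_fraction),
        np.ascontiguousarray(kernel.bin_volumes_cm3()),
        kernel.radial_bin_edges_cm,
        gcum_v,
        n_sub,
    )
    return DoseGrid(values, density.spacing_cm.copy(), density.origin_cm.copy())


def reconstruct_plan_dose(
    fields: list[tuple[FluenceMap, BeamGeometry] | BeamGeometry],
    density: DensityGrid,
    beam_model: BeamModel,
) -> DoseGrid:
    """Sum per-field TERMA + superposition over all fields of a plan."""
    if not fields:
        raise InvalidArgumentError("at least one field is required")
    total = None
    for f in fields:
        if isinstance(f, BeamGeometry):
            geom = f
        else:
            fluence, geom = f
            geom = BeamGeometry(
                fluence=fluence,
                gantry_deg=geom.gantry_deg,
                sad_cm=geom.sad_cm,
                isocenter_cm=geom.isocenter_cm,
            )
        terma = compute_terma(
            geom.fluence, density, beam_model.spectrum, beam_model.attenuation, geom
        )
        dose = collapsed_cone_superpose(
            terma, density, beam_model.cck, beam_model.cone_set, geom.rotation()
        )
        total = dose.values if total is None else total + dose.values
    return DoseGrid(total, density.spacing_cm.copy(), density.origin_cm.copy())
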