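"""Synthetic inputs: slab phantoms, square fields, forward-simulated EPID images.

Everything the pipeline consumes can be generated here, deterministically
under a fixed seed, so no external data is ever required.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import erf

from .epid import CorrectionModel, EPIDImage, KernelParams, epid_scatter_kernel, _kernel_shape_for
from .errors import InvalidArgumentError
from .grids import DensityGrid, FluenceMap

__all__ = [
    "MATERIAL_DENSITIES",
    "SlabSpec",
    "slab30_preset",
    "make_slab_phantom",
    "make_square_fluence",
    "simulate_epid_image",
]

#: mass densities (g/cm^3) of the simulated tissues; stored as relative
#: electron density with an identity mapping (documented approximation)
MATERIAL_DENSITIES = {
    "adipose": 0.920,
    "muscle": 1.040,
    "bone": 1.850,
    "lung": 0.250,
    "water": 1.000,
}


@dataclass(frozen=True)
class SlabSpec:
    """Ordered material layers stacked along the beam (z) axis."""

    layers: tuple  # of (material, thickness_cm)
    lateral_cm: float = 30.0
    spacing_cm: float = 0.3
    surface_z_cm: float = 15.0  # z of the entrance surface (SSD 85 for SAD 100)

    def __post_init__(self):
        if not self.layers:
            raise InvalidArgumentError("at least one layer required")
        for mat, th in self.layers:
            if mat not in MATERIAL_DENSITIES:
                raise InvalidArgumentError(f"unknown material {mat!r}")
            if th <= 0:
                raise InvalidArgumentError("layer thickness must be positive")
        if self.lateral_cm <= 0 or self.spacing_cm <= 0:
            raise InvalidArgumentError("extent and spacing must be positive")

    @property
    def total_thickness_cm(self) -> float:
        return sum(th for _, th in self.layers)


def slab30_preset(spacing_cm: float = 0.3, lateral_cm: float = 30.0) -> SlabSpec:
    """30 cm heterogeneous slab stack (documented plausible arrangement).

    The layer order/thicknesses fill muscle / bone / muscle / lung / muscle
    over 30 cm total; entrance surface at SSD 85 cm.
    """
    return SlabSpec(
        layers=(
            ("muscle", 4.0),
            ("bone", 4.0),
            ("muscle", 6.0),
            ("lung", 8.0),
            ("muscle", 8.0),
        ),
        lateral_cm=lateral_cm,
        spacing_cm=spacing_cm,
    )


def make_slab_phantom(spec: SlabSpec) -> DensityGrid:
    """Voxelize a slab stack; layer boundaries snap to the nearest voxel face."""
    sp = spec.spacing_cm
    nxy = max(int(round(spec.lateral_cm / sp)), 1)
    nz = max(int(round(spec.total_thickness_cm / sp)), 1)
    values = np.empty((nxy, nxy, nz))

    # z axis: surface (entrance) at high z, beam travels toward -z
    z_top = spec.surface_z_cm
    boundaries = np.cumsum([0.0] + [th for _, th in spec.layers])
    snapped = np.round(boundaries / sp) * sp
    if not np.allclose(snapped, boundaries, atol=1e-9):
        warnings.warn(
            "layer thicknesses not commensurate with voxel spacing; "
            "boundaries snapped to nearest voxel face",
            RuntimeWarning,
        )
    depth_centers = (np.arange(nz) + 0.5) * sp  # depth below surface
    layer_idx = np.searchsorted(snapped[1:], depth_centers, side="left")
    layer_idx = np.clip(layer_idx, 0, len(spec.layers) - 1)
    dens = np.array([MATERIAL_DENSITIES[m] for m, _ in spec.layers])
    values[:, :, :] = dens[layer_idx][None, None, ::-1]  # z ascending upward

    origin = np.array(
        [
            -0.5 * (nxy - 1) * sp,
            -0.5 * (nxy - 1) * sp,
            z_top - (nz - 0.5) * sp,
        ]
    )
    return DensityGrid(values, np.array([sp, sp, sp]), origin)


def make_square_fluence(
    side_cm: float,
    spacing_cm: float = 0.1,
    penumbra_sigma_cm: float = 0.0,
    extent_cm: float | None = None,
) -> FluenceMap:
    """Unit-height square field with error-function (Gaussian-blurred) edges.

    The 50% level sits exactly on the nominal field edge for any sigma.
    """
    if side_cm <= 0:
        raise InvalidArgumentError("side must be positive")
    if spacing_cm <= 0:
        raise InvalidArgumentError("spacing must be positive")
    if penumbra_sigma_cm < 0:
        raise InvalidArgumentError("penumbra sigma must be >= 0")
    if extent_cm is None:
        extent_cm = side_cm + max(6.0 * penumbra_sigma_cm, 4.0)
    if side_cm > extent_cm:
        raise InvalidArgumentError("side larger than the map extent")
    n = int(round(extent_cm / spacing_cm)) | 1  # odd: center pixel on axis
    x = (np.arange(n) - n // 2) * spacing_cm
    h = 0.5 * side_cm
    if penumbra_sigma_cm == 0.0:
        prof = ((x >= -h) & (x <= h)).astype(float)
    else:
        s = penumbra_sigma_cm * math.sqrt(2.0)
        prof = 0.5 * (erf((x + h) / s) - erf((x - h) / s))
    values = prof[:, None] * prof[None, :]
    return FluenceMap(values=values, spacing_cm=spacing_cm, plane_distance_cm=100.0)


def simulate_epid_image(
    fluence: FluenceMap,
    params: KernelParams,
    model: CorrectionModel,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    add_backscatter_ghost: bool = False,
) -> EPIDImage:
    """Forward model: P = (F / c_ad) (x) K_EPID at the detector plane.

    ``fluence`` must already live on the detector-plane lattice (pass a map
    with ``plane_distance_cm`` = SDD).  Optionally adds the arm backscatter
    ghost and Gaussian noise from a seeded generator.
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    f = fluence.values / model.c_ad
    kshape = _kernel_shape_for(f.shape)
    kernel = epid_scatter_kernel(params, kshape, fluence.spacing_cm)
    p = fftconvolve(f, kernel, mode="same")
    flags = set()
    if add_backscatter_ghost and model.backscatter_amplitude > 0:
        from scipy.ndimage import gaussian_filter

        sigma_px = model.backscatter_sigma_cm / fluence.spacing_cm
        ghost = model.backscatter_amplitude * gaussian_filter(p, sigma_px, mode="constant")
        if model.backscatter_support == "arm":
            w = np.zeros(p.shape[0])
            w[p.shape[0] // 2 :] = 1.0
            ghost = ghost * w[:, None]
        p = p + ghost
    else:
        flags.add("backscatter")
    flags.add("displacement")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, noise_sd, size=p.shape)
    p = np.clip(p, 0.0, None)
    return EPIDImage(
        pixels=p,
        pixel_pitch_cm=fluence.spacing_cm,
        sdd_cm=fluence.plane_distance_cm,
        corrected_flags=frozenset(flags),
    )
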