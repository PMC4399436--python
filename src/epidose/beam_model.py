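"""Beam-model fixtures and kernel tables for the superposition engine.

Bundles the photon energy spectrum, the water mass-attenuation table, an
analytic point energy-deposition kernel tabulated on zenith bands, the
collapsed-cone direction set, and the cumulative / cumulative-cumulative
kernel (CK/CCK) tables derived from them.

The point kernel is an analytic two-exponential fixture,

    h(r, theta) = (A(theta) e^{-a(theta) r} + B(theta) e^{-b(theta) r}) / r^2

(energy fraction per unit volume in water), tabulated per zenith band and
radial bin.  Engine accuracy is always tested against a brute-force
superposition of the *same* table, so the engine checks are decoupled from
how realistic this fixture is.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, RangeError

__all__ = [
    "Spectrum",
    "AttenuationTable",
    "PointKernel",
    "ConeSet",
    "CCKTable",
    "BeamModel",
    "load_spectrum",
    "water_attenuation",
    "attenuation_lookup",
    "make_point_kernel",
    "build_cone_set",
    "build_cck_table",
    "default_beam_model",
]

#: zenith band edges (deg): 22 uniform on [0,44], one band [44,50],
#: 9 uniform on [50,95], one band [95,120], 3 uniform on [120,180].
ZENITH_BAND_EDGES_DEG = np.concatenate(
    [
        np.linspace(0.0, 44.0, 23),
        [50.0],
        np.linspace(55.0, 95.0, 9),
        [120.0],
        np.linspace(140.0, 180.0, 3),
    ]
)

N_AZIMUTH = 8


@dataclass(frozen=True)
class Spectrum:
    energies_MeV: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies_MeV, float)
        w = np.asarray(self.weights, float)
        if e.ndim != 1 or e.shape != w.shape:
            raise InvalidArgumentError("spectrum arrays must be 1D and equal length")
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise InvalidArgumentError("energies must be positive and ascending")
        if np.any(w < 0):
            raise InvalidArgumentError("weights must be non-negative")
        s = w.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise InvalidArgumentError(f"weights must sum to 1 (got {s})")
        object.__setattr__(self, "energies_MeV", e)
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class AttenuationTable:
    energies_MeV: np.ndarray
    mu_over_rho_cm2_per_g: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies_MeV, float)
        m = np.asarray(self.mu_over_rho_cm2_per_g, float)
        if e.shape != m.shape or e.ndim != 1:
            raise InvalidArgumentError("table arrays must be 1D and equal length")
        if np.any(e <= 0) or np.any(m <= 0) or np.any(np.diff(e) <= 0):
            raise InvalidArgumentError("table must be positive with ascending energies")
        object.__setattr__(self, "energies_MeV", e)
        object.__setattr__(self, "mu_over_rho_cm2_per_g", m)


def _read_two_column_csv(name: str) -> tuple[np.ndarray, np.ndarray]:
    ref = importlib.resources.files("epidose.data") / name
    rows = []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split(",")
        rows.append((float(a), float(b)))
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1]


def load_spectrum(energy_label: str = "6MV") -> Spectrum:
    """Load a bundled representative spectrum ('6MV' or '10MV') or a CSV path."""
    label = energy_label.upper()
    if label in ("6MV", "10MV"):
        e, w = _read_two_column_csv(f"spectrum_{label.lower()}.csv")
    else:
        arr = np.loadtxt(energy_label, delimiter=",", comments="#")
        e, w = arr[:, 0], arr[:, 1]
    return Spectrum(e, w / w.sum())


def water_attenuation() -> AttenuationTable:
    """Bundled water mass-attenuation table (NIST values)."""
    e, m = _read_two_column_csv("water_mu_over_rho.csv")
    return AttenuationTable(e, m)


def attenuation_lookup(table: AttenuationTable, energy_MeV) -> np.ndarray:
    """Log-log linear interpolation of mu/rho at ``energy_MeV``.

    Raises :class:`RangeError` outside the tabulated support.
    """
    e = np.asarray(energy_MeV, dtype=float)
    lo, hi = table.energies_MeV[0], table.energies_MeV[-1]
    if np.any(e < lo) or np.any(e > hi):
        raise RangeError(
            f"energy outside table support [{lo}, {hi}] MeV"
        )
    out = np.exp(
        np.interp(
            np.log(e), np.log(table.energies_MeV), np.log(table.mu_over_rho_cm2_per_g)
        )
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PointKernel:
    """Energy-deposition kernel tabulated on (zenith band, radial bin)."""

    zenith_bin_edges_deg: np.ndarray
    radial_bin_edges_cm: np.ndarray
    energy_fraction: np.ndarray  # [n_bands, n_radial]

    def __post_init__(self):
        z = np.asarray(self.zenith_bin_edges_deg, float)
        r = np.asarray(self.radial_bin_edges_cm, float)
        f = np.asarray(self.energy_fraction, float)
        if f.shape != (z.size - 1, r.size - 1):
            raise InvalidArgumentError("energy_fraction shape mismatch")
        if np.any(f < 0):
            raise InvalidArgumentError("kernel fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-6:
            raise InvalidArgumentError("kernel must be normalized to unit total")
        object.__setattr__(self, "zenith_bin_edges_deg", z)
        object.__setattr__(self, "radial_bin_edges_cm", r)
        object.__setattr__(self, "energy_fraction", f)

    def band_solid_angles_sr(self) -> np.ndarray:
        th = np.deg2rad(self.zenith_bin_edges_deg)
        return 2.0 * np.pi * (np.cos(th[:-1]) - np.cos(th[1:]))

    def bin_volumes_cm3(self) -> np.ndarray:
        """Volume of each (band, radial shell) sector, shape [n_bands, n_radial]."""
        omega = self.band_solid_angles_sr()
        r = self.radial_bin_edges_cm
        shell = (r[1:] ** 3 - r[:-1] ** 3) / 3.0
        return omega[:, None] * shell[None, :]


def _default_radial_edges() -> np.ndarray:
    return np.concatenate(
        [
            np.arange(0.0, 1.0, 0.05),
            np.arange(1.0, 5.0, 0.1),
            np.arange(5.0, 15.0, 0.5),
            np.arange(15.0, 60.0 + 1e-9, 1.0),
        ]
    )


def make_point_kernel(
    primary_amp_decay: float = 3.0,
    primary_mu0: float = 4.0,
    primary_mu_slope: float = 2.0,
    scatter_frac0: float = 0.12,
    scatter_amp_decay: float = 0.5,
    scatter_mu0: float = 1.0,
    scatter_mu_slope: float = 0.4,
    radial_bin_edges_cm: np.ndarray | None = None,
    zenith_bin_edges_deg: np.ndarray | None = None,
) -> PointKernel:
    """Analytic two-exponential point-kernel fixture, forward peaked.

    Amplitudes and attenuation coefficients vary with the band-center zenith
    angle ``t`` (radians):

        A(t) = exp(-primary_amp_decay * t),   a(t) = primary_mu0 + primary_mu_slope * t
        B(t) = scatter_frac0 * exp(-scatter_amp_decay * t),
        b(t) = scatter_mu0 + scatter_mu_slope * t
    """
    z = (
        ZENITH_BAND_EDGES_DEG
        if zenith_bin_edges_deg is None
        else np.asarray(zenith_bin_edges_deg, float)
    )
    r = (
        _default_radial_edges()
        if radial_bin_edges_cm is None
        else np.asarray(radial_bin_edges_cm, float)
    )
    th = np.deg2rad(z)
    centers = 0.5 * (th[:-1] + th[1:])
    omega = 2.0 * np.pi * (np.cos(th[:-1]) - np.cos(th[1:]))

    A = np.exp(-primary_amp_decay * centers)
    a = primary_mu0 + primary_mu_slope * centers
    B = scatter_frac0 * np.exp(-scatter_amp_decay * centers)
    b = scatter_mu0 + scatter_mu_slope * centers

    # radial integral of (A e^{-a r} + B e^{-b r}) over each bin, per band
    r1, r2 = r[:-1][None, :], r[1:][None, :]
    ia = (A / a)[:, None] * (np.exp(-a[:, None] * r1) - np.exp(-a[:, None] * r2))
    ib = (B / b)[:, None] * (np.exp(-b[:, None] * r1) - np.exp(-b[:, None] * r2))
    frac = omega[:, None] * (ia + ib)
    frac /= frac.sum()
    return PointKernel(z, r, frac)


@dataclass(frozen=True)
class ConeSet:
    """Discrete collapsed-cone directions in the beam frame (+z = propagation)."""

    directions: np.ndarray  # [n, 3] unit vectors
    zenith_band: np.ndarray  # [n] index into the zenith bands
    azimuth_index: np.ndarray  # [n]
    solid_angle_weight: np.ndarray  # [n], sums to 4*pi
    zenith_band_edges_deg: np.ndarray

    @property
    def n_azimuth(self) -> int:
        return int(self.azimuth_index.max()) + 1


def build_cone_set(
    zenith_band_edges_deg: np.ndarray | None = None, n_azimuth: int = N_AZIMUTH
) -> ConeSet:
    """Cross the zenith bands with uniformly spaced azimuths.

    With the default bands this yields 36 zenith samples x 8 azimuths = 288
    directions, each weighted by its exact band solid angle divided by the
    azimuth count.
    """
    z = (
        ZENITH_BAND_EDGES_DEG
        if zenith_band_edges_deg is None
        else np.asarray(zenith_band_edges_deg, float)
    )
    th_edges = np.deg2rad(z)
    centers = 0.5 * (th_edges[:-1] + th_edges[1:])
    omega = 2.0 * np.pi * (np.cos(th_edges[:-1]) - np.cos(th_edges[1:]))
    phis = 2.0 * np.pi * np.arange(n_azimuth) / n_azimuth

    dirs, bands, azi, wts = [], [], [], []
    for ib, th in enumerate(centers):
        for ja, ph in enumerate(phis):
            dirs.append(
                (np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th))
            )
            bands.append(ib)
            azi.append(ja)
            wts.append(omega[ib] / n_azimuth)
    return ConeSet(
        directions=np.asarray(dirs, float),
        zenith_band=np.asarray(bands, np.int64),
        azimuth_index=np.asarray(azi, np.int64),
        solid_angle_weight=np.asarray(wts, float),
        zenith_band_edges_deg=z,
    )


@dataclass(frozen=True)
class CCKTable:
    """Cumulative (CK) and cumulative-cumulative (CCK) kernels per zenith band.

    ``K[b, i]`` is the band-total energy fraction deposited within
    radiological radius ``r[i]`` along the collapsed axis; ``C`` is its
    running integral.  Energy received by a voxel of radiological extent
    ``delta`` from TERMA T constant on an upstream segment [r1, r2] is

        T * (Kbar(r2) - Kbar(r1)),
        Kbar(r) = (C(min(r + delta/2, rmax)) - C(max(r - delta/2, 0))) / delta

    i.e. the receiver-extent average of K via CCK differences (Lu-style
    voxel integration).  Per collapsed direction the contribution divides by
    the azimuth count.
    """

    r_cm: np.ndarray  # [n_r], uniform step
    K: np.ndarray  # [n_bands, n_r]
    C: np.ndarray  # [n_bands, n_r]
    band_totals: np.ndarray  # [n_bands]
    r_cut_cm: np.ndarray  # [n_bands] radius beyond which K is ~ total

    @property
    def step_cm(self) -> float:
        return float(self.r_cm[1] - self.r_cm[0])


def build_cck_table(
    kernel: PointKernel,
    cone_set: ConeSet,
    radial_step_cm: float = 0.05,
    r_max_cm: float = 60.0,
) -> CCKTable:
    """Collapse the point kernel onto the cone axes and integrate.

    The differential line kernel of band b is piecewise constant over the
    point kernel's radial bins, k_b(r) = F[b, k] / dr_k; K is its exact
    running integral (piecewise linear) and C the trapezoid integral of K.
    """
    if radial_step_cm <= 0:
        raise InvalidArgumentError("radial_step_cm must be positive")
    if abs(kernel.energy_fraction.sum() - 1.0) > 1e-6:
        raise InvalidArgumentError("point kernel must be unit-normalized")
    if kernel.zenith_bin_edges_deg.size - 1 != np.unique(cone_set.zenith_band).size:
        raise InvalidArgumentError("cone set bands do not match kernel bands")
    if r_max_cm < kernel.radial_bin_edges_cm[-1]:
        raise InvalidArgumentError("r_max_cm must cover the kernel support")

    redges = kernel.radial_bin_edges_cm
    F = kernel.energy_fraction
    r = np.arange(0.0, r_max_cm + 0.5 * radial_step_cm, radial_step_cm)

    # K_b(r): piecewise-linear cumulative of the bin masses.  C_b is its
    # exact integral: trapezoid on the union of the output grid and the
    # kernel bin edges (K is linear between consecutive union points).
    cumF = np.concatenate([np.zeros((F.shape[0], 1)), np.cumsum(F, axis=1)], axis=1)
    r_union = np.union1d(np.round(r, 12), np.round(redges[redges <= r[-1]], 12))
    idx = np.searchsorted(r_union, np.round(r, 12))
    K = np.empty((F.shape[0], r.size))
    C = np.empty((F.shape[0], r.size))
    for b in range(F.shape[0]):
        k_u = np.interp(r_union, redges, cumF[b], right=cumF[b, -1])
        c_u = np.concatenate(
            [[0.0], np.cumsum(0.5 * (k_u[1:] + k_u[:-1]) * np.diff(r_union))]
        )
        K[b] = k_u[idx]
        C[b] = c_u[idx]
    totals = K[:, -1].copy()
    r_cut = np.empty(F.shape[0])
    for b in range(F.shape[0]):
        tot = totals[b]
        if tot <= 0:
            r_cut[b] = 0.0
        else:
            idx = np.searchsorted(K[b], tot * (1.0 - 1e-5))
            r_cut[b] = r[min(idx, r.size - 1)]
    return CCKTable(r_cm=r, K=K, C=C, band_totals=totals, r_cut_cm=r_cut)


@dataclass(frozen=True)
class BeamModel:
    """Everything the dose engine needs, bundled."""

    spectrum: Spectrum
    attenuation: AttenuationTable
    point_kernel: PointKernel
    cone_set: ConeSet
    cck: CCKTable
    energy_label: str = "6MV"


def default_beam_model(energy_label: str = "6MV", **kernel_kwargs) -> BeamModel:
    spectrum = load_spectrum(energy_label)
    atten = water_attenuation()
    pk = make_point_kernel(**kernel_kwargs)
    cones = build_cone_set()
    cck = build_cck_table(pk, cones)
    return BeamModel(spectrum, atten, pk, cones, cck, energy_label=energy_label)
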