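"""Portal-image (EPID) to fluence-map conversion.

The detector scatter model is a two-exponential radial kernel

    K(d) = (1 - c) exp(-mu_S d) + c exp(-mu_L d)

(short-range primary + long-range scatter component), fitted against
in-air ion-chamber central doses over a range of square field sizes.  A
corrected portal image is deconvolved by K in Fourier space, low-pass
filtered by a unit-sum exponential noise kernel, projected from the
detector plane to the isocenter plane, and flattened by a radial "horn"
correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    NumericDomainError,
    StateError,
)
from .grids import FluenceMap

__all__ = [
    "EPIDImage",
    "KernelParams",
    "CorrectionModel",
    "FitResult",
    "scatter_kernel_value",
    "epid_scatter_kernel",
    "golden_section_minimize",
    "aperture_kernel_mass",
    "fit_epid_kernel",
    "correct_backscatter",
    "correct_gantry_displacement",
    "deconvolve_to_fluence",
    "horn_correct",
    "project_to_isocenter",
    "epid_to_fluence",
]

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0  # 0.618...

#: default 1-D search brackets for the kernel fit
FIT_BRACKETS = {"c": (0.0, 1.0), "mu_S": (0.05, 5.0), "mu_L": (0.001, 0.5)}


@dataclass(frozen=True)
class KernelParams:
    """Two-exponential detector scatter-kernel parameters."""

    c: float
    mu_S: float  # 1/cm
    mu_L: float  # 1/cm

    def __post_init__(self):
        if not (0.0 <= self.c <= 1.0):
            raise InvalidArgumentError("c must lie in [0, 1]")
        if self.mu_S <= 0 or self.mu_L <= 0:
            raise InvalidArgumentError("attenuation coefficients must be positive")


@dataclass(frozen=True)
class CorrectionModel:
    """Acquisition/calibration corrections around the deconvolution.

    All default parameter values are placeholders, not physically
    commissioned numbers; a real installation must fit them.
    """

    backscatter_amplitude: float = 0.0
    backscatter_sigma_cm: float = 2.0
    backscatter_support: str = "arm"  # 'arm' (one-sided) or 'full'
    horn_amplitude: float = 0.0
    horn_sigma_cm: float = 8.0
    noise_filter_range_cm: float = 0.1
    displacement_table: dict = field(default_factory=lambda: {0.0: (0.0, 0.0)})
    c_ad: float = 1.0  # absolute dose-calibration scalar

    def __post_init__(self):
        if self.backscatter_sigma_cm <= 0 or self.horn_sigma_cm <= 0:
            raise InvalidArgumentError("sigmas must be positive")
        if self.c_ad <= 0:
            raise InvalidArgumentError("c_ad must be positive")
        if self.noise_filter_range_cm < 0:
            raise InvalidArgumentError("noise_filter_range_cm must be >= 0")
        if self.backscatter_support not in ("arm", "full"):
            raise InvalidArgumentError("backscatter_support must be 'arm' or 'full'")
        tab = {float(k): (float(v[0]), float(v[1])) for k, v in self.displacement_table.items()}
        if 0.0 not in tab:
            raise InvalidArgumentError("displacement table must cover gantry 0")
        if tab[0.0] != (0.0, 0.0):
            raise InvalidArgumentError("displacement at gantry 0 must be (0, 0)")
        object.__setattr__(self, "displacement_table", tab)


@dataclass(frozen=True)
class EPIDImage:
    """Corrected portal pixel matrix with detector geometry."""

    pixels: np.ndarray
    pixel_pitch_cm: float = 0.04
    sdd_cm: float = 140.0
    gantry_deg: float = 0.0
    corrected_flags: frozenset = frozenset()

    def __post_init__(self):
        p = np.asarray(self.pixels, float)
        if p.ndim != 2:
            raise InvalidArgumentError("pixels must be a 2D matrix")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise InvalidArgumentError("pixels must be finite and non-negative")
        if self.pixel_pitch_cm <= 0 or self.sdd_cm <= 0:
            raise InvalidArgumentError("pitch and SDD must be positive")
        object.__setattr__(self, "pixels", p)
        object.__setattr__(self, "gantry_deg", float(self.gantry_deg) % 360.0)
        object.__setattr__(self, "corrected_flags", frozenset(self.corrected_flags))


def scatter_kernel_value(params: KernelParams, d_cm) -> np.ndarray:
    """Raw (unnormalized) kernel value at radial distance ``d_cm``."""
    d = np.asarray(d_cm, float)
    return (1.0 - params.c) * np.exp(-params.mu_S * d) + params.c * np.exp(
        -params.mu_L * d
    )


def epid_scatter_kernel(params: KernelParams, shape, pitch_cm: float) -> np.ndarray:
    """Evaluate the radial scatter kernel on a centered grid, unit-sum normalized."""
    if pitch_cm <= 0:
        raise InvalidArgumentError("pitch must be positive")
    nx, ny = int(shape[0]), int(shape[1])
    if nx % 2 == 0 or ny % 2 == 0:
        raise InvalidArgumentError("kernel shape must be odd in both dims")
    x = (np.arange(nx) - nx // 2) * pitch_cm
    y = (np.arange(ny) - ny // 2) * pitch_cm
    d = np.hypot(x[:, None], y[None, :])
    k = scatter_kernel_value(params, d)
    s = k.sum()
    if not np.isfinite(s) or s <= 0:
        raise NumericDomainError("kernel evaluated to a degenerate (all-zero) grid")
    return k / s


def golden_section_minimize(objective, lo: float, hi: float, tol: float) -> float:
    """Golden-section search for the minimum of a unimodal scalar function."""
    if lo >= hi:
        raise InvalidArgumentError("need lo < hi")
    if tol <= 0:
        raise InvalidArgumentError("tol must be positive")
    a, b = float(lo), float(hi)
    x1 = b - GOLDEN * (b - a)
    x2 = a + GOLDEN * (b - a)
    f1, f2 = objective(x1), objective(x2)
    if not (np.isfinite(f1) and np.isfinite(f2)):
        raise NumericDomainError("objective returned a non-finite value")
    while (b - a) > tol:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - GOLDEN * (b - a)
            f1 = objective(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + GOLDEN * (b - a)
            f2 = objective(x2)
        if not (np.isfinite(f1) and np.isfinite(f2)):
            raise NumericDomainError("objective returned a non-finite value")
    return 0.5 * (a + b)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _square_mass(mu: float, half_cm: float) -> float:
    """Integral of exp(-mu d) over a square aperture of half-side h (2D).

    Radial decomposition: the circle of radius d lies fully inside the
    square for d <= h (analytic piece) and partially inside for
    h < d <= h*sqrt(2), with in-square arc fraction
    (2/pi)(asin(h/d) - acos(h/d)) (Gauss-Legendre piece).
    """
    h = half_cm
    m1 = (1.0 - math.exp(-mu * h) * (1.0 + mu * h)) / mu**2
    a, b = h, h * math.sqrt(2.0)
    d = 0.5 * (b - a) * _GL_NODES + 0.5 * (a + b)
    ratio = np.minimum(h / d, 1.0)
    w = (2.0 / math.pi) * (np.arcsin(ratio) - np.arccos(ratio))
    m2 = 0.5 * (b - a) * np.sum(_GL_WEIGHTS * np.exp(-mu * d) * d * w)
    return 2.0 * math.pi * (m1 + m2)


def aperture_kernel_mass(params: KernelParams, side_cm: float) -> float:
    """Fraction of the unit-normalized kernel inside a square field aperture."""
    if side_cm <= 0:
        raise InvalidArgumentError("side must be positive")
    h = 0.5 * side_cm
    c, ms, ml = params.c, params.mu_S, params.mu_L
    num = (1.0 - c) * _square_mass(ms, h) + c * _square_mass(ml, h)
    den = 2.0 * math.pi * ((1.0 - c) / ms**2 + c / ml**2)
    return num / den


@dataclass(frozen=True)
class FitResult:
    params: KernelParams
    objective: float
    boundary: tuple  # names of parameters that landed on a bracket edge


def _fit_objective(field_sizes, epid_vals, chamber_vals, i_ref):
    fs = np.asarray(field_sizes, float)
    ev = np.asarray(epid_vals, float)
    cv = np.asarray(chamber_vals, float)

    def objective(c, mu_s, mu_l):
        p = KernelParams(min(max(c, 0.0), 1.0), mu_s, mu_l)
        g = np.array([aperture_kernel_mass(p, s) for s in fs])
        ratio = (ev / g) / cv
        ratio = ratio / ratio[i_ref]
        return float(np.var(ratio))

    return objective


def fit_epid_kernel(
    field_sizes,
    epid_central_values,
    chamber_central_doses,
    brackets: dict | None = None,
    tol: float = 1e-4,
    max_sweeps: int = 50,
    n_starts: int = 4,
) -> FitResult:
    """Fit (c, mu_S, mu_L) by cyclic coordinate descent.

    Each coordinate sweep is a 1-D golden-section search within its bracket;
    sweeps stop when the variance objective improves by less than 1e-8.  The
    objective is the variance across field sizes of the ratio
    (deconvolved EPID central value) / (chamber central dose), with both
    series normalized at the field size closest to 10 cm.  The deconvolved
    central value of a (flat) square field is taken as the measured value
    divided by the kernel mass inside the field aperture.
    """
    fs = np.asarray(field_sizes, float)
    ev = np.asarray(epid_central_values, float)
    cv = np.asarray(chamber_central_doses, float)
    if not (fs.size == ev.size == cv.size):
        raise InvalidArgumentError("input lists must have equal length")
    if np.unique(fs).size < 3:
        raise InsufficientDataError("need at least 3 distinct field sizes")
    if np.any(fs <= 0) or np.any(ev <= 0) or np.any(cv <= 0):
        raise InvalidArgumentError("field sizes and values must be positive")

    br = dict(FIT_BRACKETS)
    if brackets:
        br.update(brackets)
    i_ref = int(np.argmin(np.abs(fs - 10.0)))
    objective = _fit_objective(fs, ev, cv, i_ref)
    names = ("c", "mu_S", "mu_L")

    # deterministic coarse-grid scan picks the starting points
    grid = [
        (c0, ms0, ml0)
        for c0 in np.linspace(br["c"][0], br["c"][1], 7)[1:-1]
        for ms0 in np.geomspace(br["mu_S"][0], br["mu_S"][1], 6)
        for ml0 in np.geomspace(br["mu_L"][0], br["mu_L"][1], 6)
    ]
    scored = sorted(grid, key=lambda x: objective(*x))
    starts = scored[: max(n_starts, 1)]

    def descend(x, local_br, sweeps):
        f_prev = objective(*x)
        for _ in range(sweeps):
            for i in range(3):
                lo, hi = local_br[names[i]]

                def f1d(v, i=i):
                    xi = list(x)
                    xi[i] = v
                    return objective(*xi)

                x[i] = golden_section_minimize(f1d, lo, hi, tol * (hi - lo))
            f_now = objective(*x)
            if f_prev - f_now < 1e-8 and f_now < 1e-8:
                return x, f_now
            f_prev = f_now
        return x, f_prev

    best = None
    for x0 in starts:
        x, f_now = descend(list(x0), br, max_sweeps)
        # refinement: re-center shrinking brackets on the current estimate
        # (plain cyclic descent zigzags in the curved valley of this
        # objective; trust-region shrinking restores tight convergence)
        width = 0.5
        for _ in range(12):
            local = {}
            for i, name in enumerate(names):
                lo, hi = br[name]
                span = width * (hi - lo)
                local[name] = (max(lo, x[i] - span), min(hi, x[i] + span))
            x, f_now = descend(x, local, 3)
            width *= 0.5
        if best is None or f_now < best[0]:
            best = (f_now, tuple(x))
    f_best, x_best = best
    boundary = tuple(
        name
        for name, v in zip(("c", "mu_S", "mu_L"), x_best)
        if min(v - br[name][0], br[name][1] - v) <= 2 * tol * (br[name][1] - br[name][0])
    )
    return FitResult(
        params=KernelParams(*x_best), objective=f_best, boundary=boundary
    )


def correct_backscatter(image: EPIDImage, model: CorrectionModel) -> EPIDImage:
    """Subtract the modeled robot-arm backscatter ghost from the image."""
    if "backscatter" in image.corrected_flags:
        raise StateError("backscatter correction already applied")
    p = image.pixels
    if model.backscatter_amplitude != 0.0:
        sigma_px = model.backscatter_sigma_cm / image.pixel_pitch_cm
        ghost = model.backscatter_amplitude * gaussian_filter(
            p, sigma_px, mode="constant"
        )
        if model.backscatter_support == "arm":
            # arm sits under the half of the panel at high row index
            w = np.zeros(p.shape[0])
            w[p.shape[0] // 2 :] = 1.0
            ghost = ghost * w[:, None]
        p = np.clip(p - ghost, 0.0, None)
    return replace(
        image, pixels=p, corrected_flags=image.corrected_flags | {"backscatter"}
    )


def _displacement_at(table: dict, gantry_deg: float) -> tuple:
    angles = np.array(sorted(table))
    dx = np.array([table[a][0] for a in angles])
    dy = np.array([table[a][1] for a in angles])
    g = gantry_deg % 360.0
    # periodic linear interpolation
    angles_ext = np.concatenate([angles, [angles[0] + 360.0]])
    dx_ext = np.concatenate([dx, [dx[0]]])
    dy_ext = np.concatenate([dy, [dy[0]]])
    return (
        float(np.interp(g, angles_ext, dx_ext)),
        float(np.interp(g, angles_ext, dy_ext)),
    )


def correct_gantry_displacement(image: EPIDImage, table: dict | None = None) -> EPIDImage:
    """Translate the image by minus the tabulated panel displacement.

    The displacement at the image's gantry angle is linearly interpolated
    (periodically) between tabulated angles; resampling is bilinear.
    """
    if "displacement" in image.corrected_flags:
        raise StateError("displacement correction already applied")
    if table is None:
        table = {0.0: (0.0, 0.0)}
    dx, dy = _displacement_at(table, image.gantry_deg)
    p = image.pixels
    if dx != 0.0 or dy != 0.0:
        p = nd_shift(
            p,
            (-dx / image.pixel_pitch_cm, -dy / image.pixel_pitch_cm),
            order=1,
            mode="constant",
            cval=0.0,
        )
        p = np.clip(p, 0.0, None)
    return replace(
        image, pixels=p, corrected_flags=image.corrected_flags | {"displacement"}
    )


def _kernel_shape_for(image_shape) -> tuple:
    return (image_shape[0] | 1, image_shape[1] | 1)


def deconvolve_to_fluence(
    image: EPIDImage,
    params: KernelParams,
    model: CorrectionModel,
    spectral_floor: float = 1e-6,
    require_corrections: bool = True,
) -> FluenceMap:
    """Fourier deconvolution of the scatter kernel; detector-plane output.

    Division happens on a zero-padded grid (padding covers the kernel
    support); kernel-transform magnitudes below ``spectral_floor`` of their
    maximum are clamped (with a warning).  The unit-sum exponential noise
    kernel is applied as a multiplicative low-pass after the division.
    Values are scaled by ``c_ad``; use :func:`project_to_isocenter` to move
    the map to the SAD plane.
    """
    if require_corrections:
        missing = {"backscatter", "displacement"} - set(image.corrected_flags)
        if missing:
            raise StateError(f"corrections not applied: {sorted(missing)}")
    p = image.pixels
    pitch = image.pixel_pitch_cm
    kshape = _kernel_shape_for(p.shape)
    kernel = epid_scatter_kernel(params, kshape, pitch)

    pad_shape = (
        sp_fft.next_fast_len(p.shape[0] + kshape[0] - 1),
        sp_fft.next_fast_len(p.shape[1] + kshape[1] - 1),
    )
    pf = sp_fft.fft2(p, pad_shape)
    kpad = np.zeros(pad_shape)
    cx, cy = kshape[0] // 2, kshape[1] // 2
    kpad[: kshape[0], : kshape[1]] = kernel
    kpad = np.roll(np.roll(kpad, -cx, axis=0), -cy, axis=1)
    kf = sp_fft.fft2(kpad)

    mag = np.abs(kf)
    floor = spectral_floor * mag.max()
    low = mag < floor
    if np.any(low):
        warnings.warn(
            "kernel transform below spectral floor at "
            f"{int(low.sum())} frequencies; regularization floor applied",
            RuntimeWarning,
        )
        kf = np.where(low, floor * np.exp(1j * np.angle(kf)), kf)

    ff = pf / kf
    if model.noise_filter_range_cm > 0:
        nkernel = _exponential_kernel(kshape, pitch, model.noise_filter_range_cm)
        npad = np.zeros(pad_shape)
        npad[: kshape[0], : kshape[1]] = nkernel
        npad = np.roll(np.roll(npad, -cx, axis=0), -cy, axis=1)
        ff = ff * sp_fft.fft2(npad)
    out = sp_fft.ifft2(ff).real[: p.shape[0], : p.shape[1]]
    return FluenceMap(
        values=model.c_ad * out,
        spacing_cm=pitch,
        plane_distance_cm=image.sdd_cm,
    )


def _exponential_kernel(shape, pitch_cm: float, range_cm: float) -> np.ndarray:
    nx, ny = shape
    x = (np.arange(nx) - nx // 2) * pitch_cm
    y = (np.arange(ny) - ny // 2) * pitch_cm
    d = np.hypot(x[:, None], y[None, :])
    k = np.exp(-d / range_cm)
    return k / k.sum()


def horn_correct(fluence: FluenceMap, model: CorrectionModel) -> FluenceMap:
    """Flatten profile horns: divide by 1 + A (1 - exp(-r^2 / 2 sigma^2))."""
    if model.horn_amplitude == 0.0:
        return fluence
    x = fluence.axis_coords(0)
    y = fluence.axis_coords(1)
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    factor = 1.0 + model.horn_amplitude * (
        1.0 - np.exp(-r2 / (2.0 * model.horn_sigma_cm**2))
    )
    return FluenceMap(
        values=fluence.values / factor,
        spacing_cm=fluence.spacing_cm,
        origin_cm=fluence.origin_cm,
        plane_distance_cm=fluence.plane_distance_cm,
    )


def project_to_isocenter(fluence: FluenceMap, sad_cm: float = 100.0) -> FluenceMap:
    """Rescale a plane map from its source distance to the SAD plane.

    Coordinates shrink by sad/sdd about the central axis; intensities grow
    by (sdd/sad)^2 (inverse square).
    """
    if sad_cm <= 0:
        raise InvalidArgumentError("sad_cm must be positive")
    sdd = fluence.plane_distance_cm
    if sdd < sad_cm:
        raise InvalidArgumentError("plane distance must be >= SAD")
    scale = sad_cm / sdd
    return FluenceMap(
        values=fluence.values * (sdd / sad_cm) ** 2,
        spacing_cm=fluence.spacing_cm * scale,
        origin_cm=(fluence.origin_cm[0] * scale, fluence.origin_cm[1] * scale),
        plane_distance_cm=sad_cm,
    )


def epid_to_fluence(
    image: EPIDImage,
    params: KernelParams,
    model: CorrectionModel,
    sad_cm: float = 100.0,
) -> FluenceMap:
    """Full chain: backscatter, displacement, deconvolution, projection, horns."""
    img = image
    if "backscatter" not in img.corrected_flags:
        img = correct_backscatter(img, model)
    if "displacement" not in img.corrected_flags:
        img = correct_gantry_displacement(img, model.displacement_table)
    f = deconvolve_to_fluence(img, params, model)
    f = project_to_isocenter(f, sad_cm)
    return horn_correct(f, model)
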