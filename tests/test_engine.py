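import numpy as np
import pytest

from conftest import make_point_terma, make_uniform_grid
from epidose.beam_model import Spectrum, attenuation_lookup, water_attenuation
from epidose.engine import (
    BeamGeometry,
    collapsed_cone_superpose,
    compute_terma,
    point_kernel_superpose_oracle,
    radiological_depth,
    reconstruct_plan_dose,
)
from epidose.errors import CostGuardError, InvalidArgumentError
from epidose.grids import DensityGrid, DoseGrid, FluenceMap, TermaGrid


class TestRadiologicalDepth:
    def test_uniform_water_straight_path(self):
        den = make_uniform_grid(n=41, spacing=0.5)  # 20.5 cm extent
        d = radiological_depth(den, (-5.0, 0.0, 0.0), (5.0, 0.0, 0.0))
        assert d == pytest.approx(10.0, abs=1e-9)

    def test_water_then_lung(self):
        # 5 cm water then 10 cm lung (0.25): 5 + 2.5 = 7.5 cm
        vals = np.ones((60, 9, 9))
        vals[20:, :, :] = 0.25  # lung beyond x = 5 cm
        sp = 0.25
        origin = np.array([sp / 2, -1.0, -1.0])  # first face at x=0
        den = DensityGrid(vals, sp * np.ones(3), origin)
        d = radiological_depth(den, (0.0, 0.0, 0.0), (15.0, 0.0, 0.0))
        assert d == pytest.approx(7.5, abs=1e-9)

    def test_random_rays_vs_dense_sampling(self):
        # midpoint-rule oracle; its own quantization error scales with the
        # sampling step times the density contrast, hence the fine step
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.9, 1.1, (15, 15, 15))
        sp = np.array([0.3, 0.25, 0.4])
        origin = -0.5 * (np.array(vals.shape) - 1) * sp
        den = DensityGrid(vals, sp, origin)
        lo = origin - 0.5 * sp
        hi = origin + (np.array(vals.shape) - 0.5) * sp
        for _ in range(200):
            p0 = rng.uniform(-4, 4, 3)
            p1 = rng.uniform(-4, 4, 3)
            got = radiological_depth(den, p0, p1)
            L = np.linalg.norm(p1 - p0)
            n = max(int(L / 0.0005), 1)
            t = (np.arange(n) + 0.5) / n
            pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
            inside = np.all((pts >= lo) & (pts <= hi), axis=1)
            idx = np.clip(
                np.floor((pts - lo) / sp).astype(int), 0, np.array(vals.shape) - 1
            )
            rho = np.where(inside, vals[idx[:, 0], idx[:, 1], idx[:, 2]], 0.0)
            want = rho.sum() * L / n
            assert got == pytest.approx(want, abs=1e-3)

    def test_zero_length_segment(self):
        den = make_uniform_grid(n=5)
        assert radiological_depth(den, (0, 0, 0), (0, 0, 0)) == 0.0

    def test_nonfinite_rejected(self):
        den = make_uniform_grid(n=5)
        with pytest.raises(InvalidArgumentError):
            radiological_depth(den, (np.nan, 0, 0), (1, 0, 0))

    def test_miss_returns_zero(self):
        den = make_uniform_grid(n=5, spacing=0.2)
        assert radiological_depth(den, (10, 10, 10), (10, 10, 11)) == 0.0


def _flat_fluence(value=1.0, extent=30.0, spacing=0.25):
    n = int(extent / spacing) | 1
    return FluenceMap(np.full((n, n), value), spacing, plane_distance_cm=100.0)


class TestComputeTerma:
    def test_vacuum_inverse_square_only(self):
        den = make_uniform_grid(n=15, spacing=0.5, density=0.0)
        spec = Spectrum(np.array([2.0]), np.array([1.0]))
        table = water_attenuation()
        fl = _flat_fluence()
        geom = BeamGeometry(fluence=fl)
        terma = compute_terma(fl, den, spec, table, geom)
        mu = attenuation_lookup(table, 2.0)
        X, Y, Z = den.voxel_centers()
        dist2 = X**2 + Y**2 + (Z - 100.0) ** 2
        want = (100.0**2 / dist2) * mu
        assert np.allclose(terma.values, want, rtol=1e-9)

    def test_monoenergetic_closed_form(self):
        # T(d) = T0 exp(-mu d) (SSD/(SSD+d))^2 on the central axis
        sp = 0.25
        nz, nxy = 81, 5
        z_top = 15.0 - sp / 2  # surface at z = +15 (SSD 85)
        origin = np.array(
            [-(nxy - 1) / 2 * sp, -(nxy - 1) / 2 * sp, z_top - (nz - 1) * sp]
        )
        den = DensityGrid(np.ones((nxy, nxy, nz)), sp * np.ones(3), origin)
        spec = Spectrum(np.array([2.0]), np.array([1.0]))
        table = water_attenuation()
        mu = attenuation_lookup(table, 2.0)
        fl = _flat_fluence()
        terma = compute_terma(fl, den, spec, table, BeamGeometry(fluence=fl))
        z = den.axis_coords(2)
        depth = 15.0 - z
        dist = 100.0 - z
        want = mu * np.exp(-mu * depth) * (100.0 / dist) ** 2
        got = terma.values[nxy // 2, nxy // 2, :]
        assert np.max(np.abs(got - want) / want) <= 1e-4

    def test_zero_fluence_zero_terma(self):
        den = make_uniform_grid(n=9)
        spec = Spectrum(np.array([2.0]), np.array([1.0]))
        fl = _flat_fluence(value=0.0)
        terma = compute_terma(fl, den, spec, water_attenuation(), BeamGeometry(fluence=fl))
        assert np.all(terma.values == 0.0)

    def test_spectrum_outside_table_rejected(self):
        from epidose.errors import RangeError

        den = make_uniform_grid(n=5)
        spec = Spectrum(np.array([50.0]), np.array([1.0]))
        fl = _flat_fluence()
        with pytest.raises(RangeError):
            compute_terma(fl, den, spec, water_attenuation(), BeamGeometry(fluence=fl))


class TestCollapsedCone:
    def test_zero_terma_zero_dose(self, beam_model):
        den = make_uniform_grid(n=9)
        terma = TermaGrid(np.zeros((9, 9, 9)), den.spacing_cm, den.origin_cm)
        dose = collapsed_cone_superpose(terma, den, beam_model.cck, beam_model.cone_set)
        assert np.all(dose.values == 0.0)

    def test_matches_bruteforce_oracle(self, water21):
        _, _, dose_cc, dose_or = water21
        c = dose_cc.values.shape[0] // 2
        mask = np.ones(dose_cc.values.shape, bool)
        mask[c, c, c] = False  # away from the source voxel
        diff = np.abs(dose_cc.values - dose_or.values) / dose_or.values.max()
        assert diff[mask].max() <= 0.03
        assert diff[mask].mean() <= 0.01

    def test_density_scaled_lattice_equivalence(self, beam_model):
        # rho = 0.5 on spacing h reproduces water on spacing h/2 exactly
        # (identical radiological geometry) - O'Connor scaling
        n, sp, rho = 15, 0.25, 0.5
        t = np.zeros((n, n, n))
        t[n // 2, n // 2, n // 2] = 1.0

        def run(spacing, dens):
            orig = -(n - 1) / 2 * spacing * np.ones(3)
            den = DensityGrid(dens * np.ones((n, n, n)), spacing * np.ones(3), orig)
            terma = TermaGrid(t, spacing * np.ones(3), orig)
            return collapsed_cone_superpose(
                terma, den, beam_model.cck, beam_model.cone_set
            ).values

        d_med = run(sp, rho)
        d_wat = run(sp * rho, 1.0)
        assert np.allclose(d_med, d_wat, rtol=1e-12, atol=1e-15)

    def test_mismatched_lattices_rejected(self, beam_model):
        den = make_uniform_grid(n=9)
        terma = TermaGrid(np.zeros((7, 7, 7)), den.spacing_cm, den.origin_cm)
        with pytest.raises(InvalidArgumentError):
            collapsed_cone_superpose(terma, den, beam_model.cck, beam_model.cone_set)


class TestOracle:
    def test_single_voxel_spherical_banding(self, water21, beam_model):
        # homogeneous water + point source: dose depends only on (r, theta)
        _, _, _, dose_or = water21
        v = dose_or.values
        c = v.shape[0] // 2
        # mirror symmetry about the beam axis (x <-> -x, y <-> -y)
        assert np.allclose(v, v[::-1, :, :], rtol=1e-9)
        assert np.allclose(v, v[:, ::-1, :], rtol=1e-9)
        assert np.allclose(v, v.transpose(1, 0, 2), rtol=1e-9)

    def test_energy_conservation(self, beam_model):
        # grid large enough to contain (nearly all of) the kernel
        den = make_uniform_grid(n=31, spacing=0.5)
        terma = make_point_terma(den)
        dose = point_kernel_superpose_oracle(terma, den, beam_model.point_kernel)
        vv = den.voxel_volume_cm3()
        released = float((terma.values * den.values).sum()) * vv
        deposited = float((dose.values * den.values).sum()) * vv
        assert deposited / released == pytest.approx(1.0, abs=0.01)

    def test_cost_guard(self, beam_model):
        den = make_uniform_grid(n=33)
        terma = make_point_terma(den)
        with pytest.raises(CostGuardError):
            point_kernel_superpose_oracle(terma, den, beam_model.point_kernel)


class TestReconstructPlanDose:
    def _geom(self, gantry=0.0, side=4.0):
        fl = FluenceMap(
            np.ones((41, 41)), 0.25, plane_distance_cm=100.0
        )
        return BeamGeometry(fluence=fl, gantry_deg=gantry)

    def test_duplicated_field_doubles(self, beam_model):
        den = make_uniform_grid(n=11, spacing=0.5)
        g = self._geom()
        d1 = reconstruct_plan_dose([g], den, beam_model)
        d2 = reconstruct_plan_dose([g, g], den, beam_model)
        assert np.allclose(d2.values, 2 * d1.values, rtol=1e-12)

    def test_parallel_opposed_symmetry(self, beam_model):
        den = make_uniform_grid(n=11, spacing=0.5)
        d = reconstruct_plan_dose(
            [self._geom(0.0), self._geom(180.0)], den, beam_model
        )
        v = d.values
        assert np.allclose(v, v[:, :, ::-1], rtol=1e-6, atol=1e-9 * v.max())

    def test_five_field_additivity_bitwise(self, beam_model):
        den = make_uniform_grid(n=9, spacing=0.5)
        gantries = [0.0, 72.0, 144.0, 216.0, 288.0]
        fields = [self._geom(g) for g in gantries]
        total = reconstruct_plan_dose(fields, den, beam_model)
        summed = sum(
            reconstruct_plan_dose([f], den, beam_model).values for f in fields
        )
        assert np.array_equal(total.values, summed)

    def test_empty_plan_rejected(self, beam_model):
        den = make_uniform_grid(n=5)
        with pytest.raises(InvalidArgumentError):
            reconstruct_plan_dose([], den, beam_model)


class TestEngineProperties:
    def test_energy_conservation_engine(self, beam_model):
        den = make_uniform_grid(n=31, spacing=0.5)
        terma = make_point_terma(den)
        dose = collapsed_cone_superpose(terma, den, beam_model.cck, beam_model.cone_set)
        vv = den.voxel_volume_cm3()
        released = float((terma.values * den.values).sum()) * vv
        deposited = float((dose.values * den.values).sum()) * vv
        assert deposited / released == pytest.approx(1.0, abs=0.02)

    def test_dose_linear_in_fluence(self, beam_model):
        den = make_uniform_grid(n=9, spacing=0.5)
        fl1 = FluenceMap(np.ones((21, 21)), 0.5, plane_distance_cm=100.0)
        fl2 = FluenceMap(3.0 * np.ones((21, 21)), 0.5, plane_distance_cm=100.0)
        d1 = reconstruct_plan_dose([BeamGeometry(fluence=fl1)], den, beam_model)
        d2 = reconstruct_plan_dose([BeamGeometry(fluence=fl2)], den, beam_model)
        assert np.allclose(d2.values, 3.0 * d1.values, rtol=1e-12)
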