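"""Voxel FE verification: material mapping, patch test, bars, energy,
manufactured-solution convergence, load calibration."""

import numpy as np
import pytest
import sympy

from rehabmech import fe, geometry
from rehabmech.fe import (
    MINERALIZED_MODULUS_THRESHOLD,
    REGION,
    MaterialField,
    SOFT_TISSUE_MODULUS,
    assemble_system,
    classify_mineralized,
    energy_balance,
    map_intensity_to_modulus_values,
    solve,
    strain_summary,
)


def uniform_material(shape, E=100.0, nu=0.3, h=1.0, region=REGION.CORTICAL):
    return MaterialField(
        modulus=np.full(shape, E),
        poisson=np.full(shape, nu),
        region=np.full(shape, region, dtype=np.uint8),
        mineralized=np.zeros(shape, dtype=bool),
        voxel_size=h,
    )


class TestIntensityMapping:
    def test_soft_tissue_branch(self):
        assert map_intensity_to_modulus_values(np.array([50.0]))[0] == 0.022
        assert map_intensity_to_modulus_values(np.array([99.9]))[0] == 0.022

    def test_power_law_against_high_precision_evaluation(self):
        # independent arbitrary-precision evaluation of the mapping at
        # 1000 HU
        I = sympy.Float(1000, 50)
        expected = sympy.Float("4.49e-4", 50) * (
            I - sympy.Float("19.5", 50)
        ) ** sympy.Float("1.87", 50)
        got = map_intensity_to_modulus_values(np.array([1000.0]))[0]
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_monotone_above_cutoff(self):
        E = map_intensity_to_modulus_values(np.array([100.0, 500.0, 1000.0]))
        assert E[0] < E[1] < E[2]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            map_intensity_to_modulus_values(np.array([np.nan]))


class TestMineralization:
    def _field(self, moduli):
        shape = (len(moduli), 1, 1)
        m = uniform_material(shape, region=REGION.DEFECT)
        m.modulus = np.asarray(moduli, float).reshape(shape)
        return m

    def test_uniform_soft_field_has_no_mineral(self):
        m = self._field([SOFT_TISSUE_MODULUS] * 4)
        assert classify_mineralized(m).sum() == 0

    def test_threshold_is_strict(self):
        m = self._field([MINERALIZED_MODULUS_THRESHOLD,
                         MINERALIZED_MODULUS_THRESHOLD + 1e-9])
        flags = classify_mineralized(m).ravel()
        assert not flags[0] and flags[1]

    def test_random_field_matches_brute_force(self, rng):
        vals = rng.uniform(0, 2000, size=(6, 5, 4))
        m = self._field(vals.ravel())
        m.modulus = vals
        m.region = np.full(vals.shape, REGION.DEFECT, dtype=np.uint8)
        m.mineralized = np.zeros(vals.shape, bool)
        m.poisson = np.full(vals.shape, 0.3)
        expected = sum(
            1 for v in vals.ravel() if v > MINERALIZED_MODULUS_THRESHOLD
        )
        assert classify_mineralized(m).sum() == expected

    def test_applies_to_defect_voxels_only(self):
        m = uniform_material((3, 3, 3), E=5000.0, region=REGION.CORTICAL)
        assert classify_mineralized(m).sum() == 0


class TestSolver:
    def test_patch_test_exact(self):
        # uniform block, linear displacement on all boundary nodes ->
        # uniform interior strain, exact to 1e-10
        mat = uniform_material((6, 6, 6), E=200.0, nu=0.3, h=0.5)
        system = assemble_system(mat)
        A = np.array([[1e-3, 2e-4, 0.0],
                      [0.0, -5e-4, 1e-4],
                      [3e-4, 0.0, 8e-4]])
        system.set_dirichlet(
            system.boundary_node_mask(), lambda x: A @ x
        )
        u, field = solve(system, solver="direct")
        expected = 0.5 * (A + A.T)
        err = np.abs(field.tensors - expected[None]).max()
        assert err < 1e-10

    def test_uniaxial_bar_strain(self):
        # slender bar, end pressure, free sides: mean axial strain p/E
        E, p = 150.0, 0.3
        mat = uniform_material((4, 4, 32), E=E, nu=0.3, h=0.5)
        system = assemble_system(mat)
        distal = np.abs(
            system.node_coords[:, 2] - system.node_coords[:, 2].max()
        ) < 1e-12
        system.set_dirichlet(distal, 0.0)
        prox = system.elems[:, 2] == 0
        system.add_face_pressure(prox, 2, 0, p, np.array([0.0, 0.0, 1.0]))
        u, field = solve(system, solver="direct")
        ezz = field.tensors[:, 2, 2]
        assert abs(abs(ezz.mean()) - p / E) / (p / E) < 0.02

    def test_two_material_series_bar(self):
        # series bar of E and 2E: element strains in ratio 2:1
        E = 80.0
        mat = uniform_material((3, 3, 16), E=E, nu=0.0, h=0.5)
        mat.modulus[:, :, 8:] = 2 * E
        system = assemble_system(mat)
        distal = np.abs(
            system.node_coords[:, 2] - system.node_coords[:, 2].max()
        ) < 1e-12
        system.set_dirichlet(distal, 0.0)
        prox = system.elems[:, 2] == 0
        system.add_face_pressure(prox, 2, 0, 0.5, np.array([0.0, 0.0, 1.0]))
        u, field = solve(system, solver="direct")
        soft = np.abs(field.tensors[system.elems[:, 2] < 8, 2, 2]).mean()
        stiff = np.abs(field.tensors[system.elems[:, 2] >= 8, 2, 2]).mean()
        assert soft / stiff == pytest.approx(2.0, rel=0.02)

    def test_zero_load_zero_strain(self):
        mat = uniform_material((4, 4, 4))
        system = assemble_system(mat)
        system.set_dirichlet(system.boundary_node_mask(), 0.0)
        u, field = solve(system, solver="direct")
        assert np.abs(u).max() == 0.0
        assert np.abs(field.tensors).max() == 0.0

    def test_linearity_under_load_doubling(self):
        mat = uniform_material((4, 4, 8))
        system = assemble_system(mat)
        distal = np.abs(
            system.node_coords[:, 2] - system.node_coords[:, 2].max()
        ) < 1e-12
        system.set_dirichlet(distal, 0.0)
        prox = system.elems[:, 2] == 0
        system.add_face_pressure(prox, 2, 0, 0.2, np.array([0.0, 0.0, 1.0]))
        _, f1 = solve(system, solver="direct")
        system.f *= 2.0
        _, f2 = solve(system, solver="direct")
        np.testing.assert_allclose(
            f2.tensors, 2 * f1.tensors, rtol=1e-9, atol=1e-15
        )

    def test_energy_balance(self):
        mat = uniform_material((5, 5, 10), E=300.0, nu=0.25)
        system = assemble_system(mat)
        distal = np.abs(
            system.node_coords[:, 2] - system.node_coords[:, 2].max()
        ) < 1e-12
        system.set_dirichlet(distal, 0.0)
        prox = system.elems[:, 2] == 0
        system.add_face_pressure(prox, 2, 0, 1.0, np.array([0.0, 0.0, 1.0]))
        u, _ = solve(system, solver="direct")
        work, energy = energy_balance(system, u)
        assert abs(work - energy) / abs(energy) < 1e-6

    def test_manufactured_solution_convergence(self):
        # sinusoidal displacement field (polynomial fields are nodally
        # exact on this uniform tensor grid and cannot measure an order);
        # the body force is the symbolic -div(sigma) of the field
        E, nu = 100.0, 0.3
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        A, pi = 1e-3, np.pi
        s, c = np.sin, np.cos

        def u_exact(x):
            return np.array(
                [A * s(pi * x[0]) * s(pi * x[1]) * s(pi * x[2]), 0.0, 0.0]
            )

        def body(x):
            X, Y, Z = x
            k = pi**2 * A
            return np.array(
                [
                    (lam + 4 * mu) * k * s(pi * X) * s(pi * Y) * s(pi * Z),
                    -(lam + mu) * k * c(pi * X) * c(pi * Y) * s(pi * Z),
                    -(lam + mu) * k * c(pi * X) * s(pi * Y) * c(pi * Z),
                ]
            )

        errs = []
        for n in (4, 8, 16):
            h = 1.0 / n
            mat = uniform_material((n, n, n), E=E, nu=nu, h=h)
            system = assemble_system(mat)
            system.set_dirichlet(system.boundary_node_mask(), u_exact)
            system.add_body_force(body)
            u, _ = solve(system, solver="direct")
            U = u.reshape(-1, 3)
            exact = np.array([u_exact(x) for x in system.node_coords])
            errs.append(np.sqrt(((U - exact) ** 2).sum(1)).mean())
        assert errs[0] > errs[1] > errs[2]
        orders = np.log2(errs[0] / errs[1]), np.log2(errs[1] / errs[2])
        # order tends to 2; the coarsest pair is still pre-asymptotic
        assert orders[1] > 1.6
        assert orders[1] > orders[0]

    def test_floating_substructure_reported(self):
        mat = uniform_material((7, 3, 3))
        mat.region[3, :, :] = REGION.VOID
        with pytest.raises(ValueError, match="floating substructure"):
            assemble_system(mat)


class TestStrainSummary:
    def _field(self, comp, vol):
        n = len(comp)
        t = np.zeros((n, 3, 3))
        principal = np.zeros((n, 3))
        comp = np.asarray(comp, float)
        return fe.StrainField(
            tensors=t,
            principal=principal,
            compressive=comp,
            shear=comp / 2.0,
            element_volume=vol,
            elems=np.zeros((n, 3), int),
        )

    def test_uniform_field(self):
        f = self._field([0.02] * 5, 1.0)
        s = strain_summary(f, np.ones(5, bool))
        assert s.compressive_mean == pytest.approx(0.02)
        assert s.compressive_sd == 0.0

    def test_volume_weighted_hand_example(self):
        # volumes {1, 3}, strains {0.04, 0.0} -> mean 0.01
        f = self._field([0.04, 0.0], np.array([1.0, 3.0]))
        s = strain_summary(f, np.ones(2, bool))
        assert s.compressive_mean == pytest.approx(0.01)

    def test_uniform_volumes_reduce_to_plain_mean(self, rng):
        vals = rng.random(10)
        f = self._field(vals, 2.0)
        s = strain_summary(f, np.ones(10, bool))
        assert s.compressive_mean == pytest.approx(vals.mean())

    def test_empty_mask_flagged_missing(self):
        f = self._field([0.01], 1.0)
        s = strain_summary(f, np.zeros(1, bool))
        assert s.missing
        assert np.isnan(s.compressive_mean)


@pytest.fixture(scope="module")
def model():
    spec = geometry.GeometrySpec(voxel_size=0.5, bone_grid=10)
    material = geometry.build_material_field(spec)
    system = geometry.build_model(spec, material)
    return spec, material, system


class TestCalibration:
    def test_zero_target_zero_force(self, model):
        spec, material, system = model
        sol = geometry.calibrate_load(system, 0.0)
        assert sol.force == 0.0

    def test_force_scales_linearly_with_target(self, model):
        spec, material, _ = model
        s1 = geometry.solve_calibrated(spec, material, 200.0)
        s2 = geometry.solve_calibrated(spec, material, 400.0)
        assert s2.force == pytest.approx(2 * s1.force, rel=1e-9)

    def test_calibrated_plate_strain_matches_target(self, model):
        spec, material, system = model
        sol = geometry.calibrate_load(system, 300.0, tol=1e-3)
        assert sol.plate_strain * 1e6 == pytest.approx(300.0, rel=1e-3)

    def test_defect_strain_dwarfs_cortical(self, model):
        # unbridged defect: soft gap concentrates deformation
        spec, material, _ = model
        sol = geometry.solve_calibrated(spec, material, 400.0)
        ratio = (
            sol.summaries["defect"].compressive_mean
            / sol.summaries["cortical"].compressive_mean
        )
        assert ratio >= 10.0
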