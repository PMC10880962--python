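"""Finite-element jaw mechanics: elasticity, stress fields, calibration."""

import numpy as np
import pytest

from jawmorph import config
from jawmorph.mechanics import (BoundaryConditionSet, ElasticSystem,
                                MaterialModel, StressHistory,
                                average_hydrostatic, calibrate_muscle_forces,
                                compressive_clamp, default_jaw_bcs,
                                default_muscle_loads, hydrostatic,
                                jaw_opening_displacement, nodal_gradient,
                                simulate_jaw_cycle)

from conftest import kuhn_box_mesh


def _uniaxial_compression_setup(h=0.5, p=10.0, side=2.0):
    """Block with roller supports and a uniform top pressure."""
    m = kuhn_box_mesh(side, side, side, h)
    pts = m.points
    bcs = BoundaryConditionSet()
    bcs.add(np.nonzero(pts[:, 2] < 1e-9)[0], (2,))
    bcs.add(np.nonzero(pts[:, 0] < 1e-9)[0], (0,))
    bcs.add(np.nonzero(pts[:, 1] < 1e-9)[0], (1,))
    # consistent nodal loads for uniform pressure on the top face
    tris = m.boundary_triangles()
    top = [t for t in tris if np.all(pts[t, 2] > side - 1e-9)]
    loads = {}
    for t in top:
        a = 0.5 * abs(np.cross(pts[t[1]] - pts[t[0]], pts[t[2]] - pts[t[0]])[2])
        for n in t:
            loads[n] = loads.get(n, 0.0) + a / 3.0
    load_list = [(n, np.array([0.0, 0.0, -p * a])) for n, a in loads.items()]
    return m, bcs, load_list


class TestElasticity:
    def test_uniaxial_patch_test_with_study_modulus(self):
        """σ_zz = −p and σ_h = −p/3 at every node of the loaded block."""
        p = 10.0
        m, bcs, loads = _uniaxial_compression_setup(p=p)
        mat = MaterialModel(cartilage_E=142.01, poisson=0.3)
        sys_ = ElasticSystem(m, mat, bcs)
        u = sys_.solve(loads)
        sig = sys_.nodal_stresses(u)
        sh = hydrostatic(sig)
        assert np.allclose(sig[:, 2, 2], -p, rtol=1e-6)
        assert np.allclose(sh, -p / 3.0, rtol=1e-6)
        # compression convention: σ_h < 0 everywhere in the loaded column
        assert np.all(sh < 0)
        # closed-form top displacement
        top = m.points[:, 2] > 2.0 - 1e-9
        assert np.allclose(u[top, 2], -p / 142.01 * 2.0, rtol=1e-6)

    def test_zero_loads_zero_solution(self):
        m, bcs, _ = _uniaxial_compression_setup()
        sys_ = ElasticSystem(m, MaterialModel(), bcs)
        u = sys_.solve([])
        assert np.allclose(u, 0.0)
        assert np.allclose(sys_.nodal_stresses(u), 0.0)

    def test_linearity_in_load_factor(self):
        m, bcs, loads = _uniaxial_compression_setup()
        sys_ = ElasticSystem(m, MaterialModel(), bcs)
        u1 = sys_.solve(loads, load_factor=1.0)
        u3 = sys_.solve(loads, load_factor=3.0)
        assert np.allclose(u3, 3.0 * u1, rtol=1e-12)

    def test_missing_constraints_rejected(self):
        m, _, loads = _uniaxial_compression_setup()
        sys_ = ElasticSystem(m, MaterialModel(), BoundaryConditionSet())
        with pytest.raises(ValueError):
            sys_.solve(loads)

    def test_cantilever_beam_converges_to_euler_bernoulli(self):
        """Tip deflection extrapolates to the closed form within 5%."""
        E, nu, P = 142.01, 0.3, 0.01
        L, W, H = 20.0, 2.0, 2.0
        deltas = []
        for h in (0.5, 0.25):
            m = kuhn_box_mesh(L, W, H, h)
            bcs = BoundaryConditionSet()
            bcs.add(np.nonzero(m.points[:, 0] < 1e-9)[0], (0, 1, 2))
            tip = np.nonzero(m.points[:, 0] > L - 1e-9)[0]
            loads = [(int(n), np.array([0, 0, -P / len(tip)])) for n in tip]
            sys_ = ElasticSystem(m, MaterialModel(cartilage_E=E, poisson=nu),
                                 bcs)
            u = sys_.solve(loads)
            deltas.append(-u[tip, 2].mean())
        # Richardson extrapolation (second-order) of the two refinements
        extrapolated = deltas[1] + (deltas[1] - deltas[0]) / 3.0
        eb = P * L**3 / (3 * E * (W * H**3 / 12))
        assert abs(extrapolated - eb) / eb < 0.05

    def test_hydrostatic_frame_objectivity(self):
        # rotating the whole problem by an axis permutation leaves σ_h
        # unchanged nodewise
        p = 4.0
        m, bcs, loads = _uniaxial_compression_setup(p=p)
        sys_ = ElasticSystem(m, MaterialModel(), bcs)
        sh = hydrostatic(sys_.nodal_stresses(sys_.solve(loads)))
        R = np.array([[0.0, 0, 1], [1, 0, 0], [0, 1, 0]])   # x→y→z→x
        m2 = m.transformed(R, np.zeros(3))
        bcs2 = BoundaryConditionSet()
        axis_map = {0: 1, 1: 2, 2: 0}
        for nodes, axes in bcs.constraints:
            bcs2.add(nodes, tuple(axis_map[a] for a in axes))
        loads2 = [(n, R @ f) for n, f in loads]
        sys2 = ElasticSystem(m2, MaterialModel(), bcs2)
        sh2 = hydrostatic(sys2.nodal_stresses(sys2.solve(loads2)))
        assert np.allclose(sh2, sh, atol=1e-10)


class TestHydrostatic:
    def test_uniaxial_shear_and_spherical(self):
        assert hydrostatic(np.diag([-3.0, 0, 0])) == pytest.approx(-1.0)
        shear = np.array([[0, 1.0, 0], [1.0, 0, 0], [0, 0, 0]])
        assert hydrostatic(shear) == pytest.approx(0.0)
        assert hydrostatic(5.0 * np.eye(3)) == pytest.approx(5.0)

    def test_average_over_history(self):
        c = np.array([1.0, -2.0, 3.0])
        hist = StressHistory(np.tile(c, (10, 1)), 5)
        assert np.allclose(average_hydrostatic(hist), c)
        ramp = np.arange(1, 11)[:, None] * c[None]
        hist = StressHistory(ramp, 5)
        assert np.allclose(average_hydrostatic(hist), c * 5.5)
        anti = np.concatenate([np.tile(c, (5, 1)), np.tile(-c, (5, 1))])
        assert np.allclose(average_hydrostatic(StressHistory(anti, 5)), 0.0)

    def test_compressive_clamp(self):
        f = np.array([-2.0, 0.0, 3.0])
        assert np.array_equal(compressive_clamp(f), [-2.0, 0.0, 0.0])
        assert np.array_equal(compressive_clamp(-f), [0.0, 0.0, -3.0])
        assert np.array_equal(compressive_clamp(np.zeros(3)), np.zeros(3))


class TestNodalGradient:
    def test_linear_field_exact_everywhere(self):
        m = kuhn_box_mesh(10, 6, 8, 2.0)
        alpha = 0.7
        grad = nodal_gradient(alpha * m.points[:, 2], m)
        assert np.allclose(grad[:, 2], alpha, atol=1e-8)
        assert np.allclose(grad[:, :2], 0.0, atol=1e-8)

    def test_constant_field_zero_gradient(self, default_mesh):
        grad = nodal_gradient(np.full(default_mesh.n_points, 3.3),
                              default_mesh)
        assert np.allclose(grad, 0.0, atol=1e-10)

    def test_linear_field_exact_on_jaw_mesh(self, default_mesh):
        coeff = np.array([0.2, -0.5, 0.9])
        field = default_mesh.points @ coeff
        grad = nodal_gradient(field, default_mesh)
        assert np.allclose(grad, coeff[None, :], atol=1e-7)

    def test_non_finite_field_rejected(self, default_mesh):
        bad = np.zeros(default_mesh.n_points)
        bad[0] = np.nan
        with pytest.raises(ValueError):
            nodal_gradient(bad, default_mesh)


class TestJawCycle:
    def test_increment_count_and_markers(self, jaw_mechanics_setup):
        hist = jaw_mechanics_setup["history"]
        n = config.N_INCREMENTS_PER_STEP
        assert hist.increments.shape[0] == 2 * n
        assert hist.peak_closure == n - 1
        assert hist.peak_opening == 2 * n - 1

    def test_linear_ramp_within_each_step(self, jaw_mechanics_setup):
        hist = jaw_mechanics_setup["history"]
        n = config.N_INCREMENTS_PER_STEP
        for k in range(n):
            assert np.allclose(hist.increments[k],
                               (k + 1) / n * hist.increments[n - 1],
                               rtol=1e-12)
            assert np.allclose(hist.increments[n + k],
                               (k + 1) / n * hist.increments[2 * n - 1],
                               rtol=1e-12)

    def test_joint_stress_reverses_between_phases(self, default_mesh,
                                                  jaw_mechanics_setup):
        """Dorsal compression at closure, tension at opening (and the
        reverse ventrally), as in the observed jaw stress fields."""
        hist = jaw_mechanics_setup["history"]
        shc = hist.field_at("peak_closure")
        sho = hist.field_at("peak_opening")
        mc = default_mesh.region_nodes("MC")
        pts = default_mesh.points[mc]
        near = np.abs(pts[:, 0] - 3.0) < 3.0
        dorsal = mc[near & (pts[:, 2] > 8)]
        ventral = mc[near & (pts[:, 2] < -8)]
        assert shc[dorsal].mean() < 0 < shc[ventral].mean()
        assert sho[ventral].mean() < 0 < sho[dorsal].mean()

    def test_average_stress_compressive_at_joint(self, default_mesh,
                                                 jaw_mechanics_setup):
        S = average_hydrostatic(jaw_mechanics_setup["history"])
        iz = default_mesh.region_nodes("interzone")
        assert S[iz].mean() < 0


class TestMuscleCalibration:
    def test_physiological_opening_reached(self, jaw_mechanics_setup):
        assert abs(jaw_mechanics_setup["achieved"]
                   - config.PHYSIOLOGICAL_OPENING_UM) < 0.1

    def test_scale_doubles_with_target(self, default_mesh,
                                       jaw_mechanics_setup):
        mat = jaw_mechanics_setup["materials"]
        bcs = jaw_mechanics_setup["bcs"]
        loads = jaw_mechanics_setup["loads"]
        s1, _, _ = calibrate_muscle_forces(default_mesh, mat, bcs, loads,
                                           target_opening=20.0)
        s2, _, _ = calibrate_muscle_forces(default_mesh, mat, bcs, loads,
                                           target_opening=40.0)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)

    def test_round_trip_self_consistency(self, default_mesh,
                                         jaw_mechanics_setup):
        scaled = jaw_mechanics_setup["scaled_loads"]
        mat = jaw_mechanics_setup["materials"]
        bcs = jaw_mechanics_setup["bcs"]
        sys_ = ElasticSystem(default_mesh, mat, bcs)
        u = sys_.solve(scaled.phase_loads(default_mesh, "opening"))
        opening = jaw_opening_displacement(default_mesh, u)
        assert opening == pytest.approx(config.PHYSIOLOGICAL_OPENING_UM,
                                        rel=1e-8)

    def test_force_ratio_preserved(self, jaw_mechanics_setup):
        loads = jaw_mechanics_setup["loads"]
        scaled = jaw_mechanics_setup["scaled_loads"]
        base = config.MUSCLE_FORCES_NN["4"]
        for name, m in scaled.muscles.items():
            ratio = m.magnitude / loads.muscles[name].magnitude
            assert ratio == pytest.approx(jaw_mechanics_setup["scale"])
            assert loads.muscles[name].magnitude == base[name]


class TestMaterialModel:
    def test_interzone_fraction_exact(self):
        mat = MaterialModel.from_study("free", "4-4.5")
        assert mat.cartilage_E == 142.01
        assert mat.interzone_E == pytest.approx(0.00025 * 142.01, rel=1e-12)
        assert mat.poisson == 0.3

    def test_immobilised_moduli_table(self):
        assert MaterialModel.from_study("immobilised", "4-4.5").cartilage_E == 82.91
        assert MaterialModel.from_study("immobilised", "4.5-5").cartilage_E == 117.44

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MaterialModel(cartilage_E=-1.0)
        with pytest.raises(ValueError):
            MaterialModel(poisson=0.5)
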