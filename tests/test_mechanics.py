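"""Elastic energies, analytic forces, and overdamped integration."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from budmorph import mesh as M
from budmorph import mechanics as mech

from conftest import two_triangle_patch


def _params(**kw):
    defaults = dict(ks_mother=2.0, ks_bud=2.0, kb_mother=1.0, kb_bud=1.0,
                    ka=2.0, Dm=0.0, P=0.0)
    defaults.update(kw)
    return mech.MechParams(**defaults)


class TestEnergyValues:
    """Closed-form single-element checks."""

    def test_rest_state_has_zero_energy(self, icosphere2):
        p = _params()
        terms = mech.total_energy(icosphere2, None, p)
        assert terms["total"] == pytest.approx(0.0, abs=1e-20)

    def test_ordinary_spring_value(self):
        # E = (ks/2)(L - L0)^2 = (2/2)(0.5)^2 = 0.25 on a stretched edge
        m = two_triangle_patch()
        key = (0, 1)
        L0 = m.edge_L0[key]
        m.vertices[1, 0] *= (L0 + 0.5) / L0  # stretch edge (0,1) by 0.5
        m.edge_L0 = {k: (0.0 if k == key else None) or v
                     for k, v in m.edge_L0.items()}
        m.invalidate()
        geom = M.compute_geometry(m)
        _, per_edge = mech.energy_stretch(m, geom, _params(), per_edge=True)
        row = m.topology.edge_index[key]
        assert per_edge[row] == pytest.approx(
            0.5 * 2.0 * (geom.edge_length[row] - L0) ** 2, rel=1e-12)

    def test_spring_examples_direct_substitution(self):
        # ordinary: ks=2, L0=1, L=1.5 -> 0.25; septin: ks=2, L0=2, L=2.5 -> 0.0625
        assert 0.5 * 2.0 * (1.5 - 1.0) ** 2 == pytest.approx(0.25)
        m = two_triangle_patch()
        key = (0, 1)
        m.edge_L0[key] = 2.0
        m.septin_edges = {key}
        m.vertices[0] = [0, 0, 0]
        m.vertices[1] = [2.5, 0, 0]
        m.invalidate()
        geom = M.compute_geometry(m)
        _, per_edge = mech.energy_stretch(m, geom, _params(), per_edge=True)
        row = m.topology.edge_index[key]
        assert per_edge[row] == pytest.approx(2.0 / (2 * 2.0**2) * 0.5**2, rel=1e-12)
        assert per_edge[row] == pytest.approx(0.0625, rel=1e-12)

    def test_septin_scaling_law(self):
        # at L0 = 1 septin and ordinary coincide; otherwise energy ~ 1/L0^2
        for L0, expect_ratio in ((1.0, 1.0), (2.0, 0.25), (0.5, 4.0)):
            m = two_triangle_patch()
            key = (0, 1)
            m.edge_L0[key] = L0
            m.vertices[0] = [0, 0, 0]
            m.vertices[1] = [L0 + 0.3, 0, 0]
            m.invalidate()
            geom = M.compute_geometry(m)
            row = m.topology.edge_index[key]
            _, ordinary = mech.energy_stretch(m, geom, _params(), per_edge=True)
            m.septin_edges = {key}
            m.invalidate()
            _, septin = mech.energy_stretch(m, M.compute_geometry(m), _params(),
                                            per_edge=True)
            assert septin[row] / ordinary[row] == pytest.approx(1.0 / L0**2)
            assert septin[row] == pytest.approx(expect_ratio * ordinary[row])

    @pytest.mark.parametrize("delta,expect", [(np.pi / 2, 1.0), (np.pi, 2.0)])
    def test_bend_value(self, delta, expect):
        # E = kb (1 - cos(theta - theta0)) for a single hinge
        m = two_triangle_patch()
        m.vertices[3] = [0.5, -0.9, 0.0]
        m.invalidate()
        m.set_rest_state_from_geometry()  # flat strip: theta0 = 0
        # fold vertex 3 about the shared edge (the x-axis) by delta
        y = -0.9
        m.vertices[3] = [0.5, y * np.cos(delta), -y * np.sin(delta)]
        m.invalidate()
        geom = M.compute_geometry(m)
        assert abs(geom.dihedral_angle[0]) == pytest.approx(delta, abs=1e-9)
        e = mech.energy_bend(m, geom, _params(kb_mother=1.0))
        assert e == pytest.approx(expect, rel=1e-9)

    def test_area_value_and_linearity(self):
        # E = (ka/(2 A0))(A - A0)^2: ka=2, A0=1, A=1.5 -> 0.25
        m = two_triangle_patch()
        m.face_A0[:] = 1.0
        geom = M.compute_geometry(m)
        A = geom.face_area
        expected = (2.0 / 2.0 * (A - 1.0) ** 2).sum()
        assert mech.energy_area(m, geom, _params()) == pytest.approx(expected)
        assert mech.energy_area(m, geom, _params(ka=4.0)) == \
            pytest.approx(2 * expected)
        assert 2.0 / (2 * 1.0) * (1.5 - 1.0) ** 2 == pytest.approx(0.25)

    def test_morse_pointwise(self):
        p = mech.MechParams(Dm=1.0, am=1.0, Lm=0.8)
        assert mech.morse_energy(0.8, p) == pytest.approx(0.0)
        assert mech.morse_energy(1.5, p) == 0.0  # beyond range
        # L = Lm/2: D (1 - exp(-a(L - Lm)))^2 = (1 - e^{Lm/2})^2
        expect = (1 - np.exp(0.4)) ** 2
        assert mech.morse_energy(0.4, p) == pytest.approx(expect, rel=1e-12)

    def test_morse_excludes_connected_pairs(self, icosphere1):
        # range beyond every edge length: only non-adjacent pairs contribute
        p = mech.MechParams(Dm=1.0, am=1.0, Lm=1.2)
        pairs = mech._morse_pairs(icosphere1, p)
        keys = {tuple(pr) for pr in pairs.tolist()}
        assert keys and not (keys & set(icosphere1.edge_L0))

    def test_total_energy_breakdown_sums(self, perturbed_sphere):
        p = mech.MechParams(Dm=1.0, am=3.0, Lm=0.5)
        terms = mech.total_energy(perturbed_sphere, None, p)
        assert terms["total"] == pytest.approx(
            terms["stretch"] + terms["bend"] + terms["area"] + terms["excluded"])

    def test_two_triangle_brute_force_oracle(self):
        # independent per-element summation against the vectorized path
        m = two_triangle_patch()
        m.vertices[3, 2] = 0.4
        m.invalidate()
        p = _params()
        geom = M.compute_geometry(m)
        e_stretch = 0.0
        for (i, j), L0 in m.edge_L0.items():
            L = np.linalg.norm(m.vertices[i] - m.vertices[j])
            e_stretch += 0.5 * 2.0 * (L - L0) ** 2
        e_area = sum(2.0 / (2 * A0) * (A - A0) ** 2
                     for A, A0 in zip(geom.face_area, m.face_A0))
        th = geom.dihedral_angle[0]
        th0 = m.edge_theta0[(0, 1)]
        e_bend = 1.0 * (1 - np.cos(th - th0))
        total = mech.total_energy(m, geom, p)
        assert total["stretch"] == pytest.approx(e_stretch, rel=1e-12)
        assert total["area"] == pytest.approx(e_area, rel=1e-12)
        assert total["bend"] == pytest.approx(e_bend, rel=1e-12)


class TestForces:
    def test_gradient_matches_finite_differences(self, rng):
        """Analytic -grad E vs central differences on a strained mesh."""
        m = M.build_icosphere(1, 1.0)
        M.init_bud_patch(m, [0, 0, 1], 0.5)
        m.set_rest_state_from_geometry()
        m.vertices = m.vertices + 0.02 * rng.standard_normal(m.vertices.shape)
        p = mech.MechParams(Dm=1.0, am=3.0, Lm=0.5)

        def E(x):
            mm = m.copy()
            mm.vertices = x.reshape(-1, 3).copy()
            return mech.total_energy(mm, None, p)["total"]

        x0 = m.vertices.ravel().copy()
        ana = -mech.elastic_forces(m, M.compute_geometry(m), p).ravel()
        h = 1e-6
        num = np.empty_like(x0)
        for k in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[k] += h
            xm[k] -= h
            num[k] = (E(xp) - E(xm)) / (2 * h)
        scale = np.abs(num).max()
        assert np.abs(ana - num).max() / scale < 1e-6

    def test_turgor_zero_pressure(self, icosphere1):
        g = M.compute_geometry(icosphere1)
        F = mech.turgor_forces(icosphere1, g, _params(P=0.0))
        assert np.all(F == 0.0)

    def test_turgor_closed_surface_balances(self, icosphere2):
        g = M.compute_geometry(icosphere2)
        F = mech.turgor_forces(icosphere2, g, _params(P=3.0))
        assert np.linalg.norm(F.sum(axis=0)) < 1e-9 * 3.0 * g.total_area

    def test_turgor_single_triangle_lumping(self):
        # each corner of an isolated face carries P*A/3 along the normal
        m = two_triangle_patch()
        m.faces = m.faces[:1].copy()
        m.face_A0 = m.face_A0[:1].copy()
        m.face_region = m.face_region[:1].copy()
        m.edge_L0 = {k: v for k, v in m.edge_L0.items() if 3 not in k}
        m.edge_theta0 = {}
        m.invalidate()
        g = M.compute_geometry(m)
        F = mech.turgor_forces(m, g, _params(P=2.0))
        A, n = g.face_area[0], g.face_normal[0]
        for corner in m.faces[0]:
            assert np.allclose(F[corner], 2.0 * A / 3.0 * n)

    def test_rigid_motion_invariance(self, perturbed_sphere, rng):
        p = mech.MechParams(Dm=1.0, am=3.0, Lm=0.5)
        e0 = mech.total_energy(perturbed_sphere, None, p)
        # random rotation (QR of a Gaussian matrix) + translation
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        m2 = perturbed_sphere.copy()
        m2.vertices = perturbed_sphere.vertices @ Q.T + np.array([1.3, -0.7, 2.1])
        m2.invalidate()
        e1 = mech.total_energy(m2, None, p)
        for term in ("stretch", "bend", "area", "excluded", "total"):
            assert e1[term] == pytest.approx(e0[term], rel=1e-12, abs=1e-14)


class TestIntegration:
    def test_zero_force_leaves_positions(self, icosphere1):
        m = icosphere1.copy()
        x0 = m.vertices.copy()
        mech.step_overdamped(m, _params())
        assert np.array_equal(m.vertices, x0)

    def test_energy_descent_at_zero_pressure(self, perturbed_sphere):
        p = mech.MechParams(P=0.0, dt=1e-4)
        m = perturbed_sphere
        prev = mech.total_energy(m, None, p)["total"]
        for _ in range(100):
            mech.step_overdamped(m, p)
            cur = mech.total_energy(m, None, p)["total"]
            assert cur <= prev + 1e-12
            prev = cur

    def test_exponential_relaxation_of_uniform_mode(self):
        """Near equilibrium the overdamped flow is linear, so a small uniform
        dilation decays mono-exponentially with an amplitude-independent
        rate (checked at two amplitudes)."""
        rates = []
        for amp in (1e-3, 5e-4):
            m = M.build_icosphere(1, 1.0)
            p = mech.MechParams(P=0.0, dt=1e-4, kb_mother=0.0, kb_bud=0.0,
                                ka=0.0, Dm=0.0, ks_mother=10.0, ks_bud=10.0)
            m.vertices *= 1.0 + amp
            m.invalidate()
            devs = []
            for _ in range(200):
                mech.step_overdamped(m, p)
                devs.append(np.linalg.norm(m.vertices, axis=1).mean() - 1.0)
            devs = np.asarray(devs)
            logs = np.log(devs)
            t = np.arange(len(devs), dtype=float)
            slope, icpt = np.polyfit(t, logs, 1)
            resid = logs - (slope * t + icpt)
            assert np.abs(resid).max() < 1e-3  # mono-exponential
            rates.append(-slope)
        assert rates[0] == pytest.approx(rates[1], rel=1e-2)

    def test_relax_rest_sphere_immediately(self, icosphere1):
        m = icosphere1.copy()
        res = mech.relax(m, _params(), max_steps=100, force_tol=1e-8)
        assert res.converged and res.steps == 0

    def test_pressurized_equilibrium_radius(self):
        """Full relaxation against a one-parameter radial energy oracle."""
        m = M.build_icosphere(2, 1.0)
        p = mech.MechParams(P=4.0, dt=5e-4, Dm=0.0)
        ref = m.copy()

        def radial_energy(r):
            mm = ref.copy()
            mm.vertices = ref.vertices * r
            mm.invalidate()
            elastic = mech.total_energy(mm, None, p)["total"]
            # pressure potential: -P * enclosed volume
            return elastic - p.P * M._enclosed_volume(mm)

        opt = minimize_scalar(radial_energy, bounds=(1.0, 1.2), method="bounded")
        res = mech.relax(m, p, max_steps=3000, force_tol=1e-3)
        assert res.converged
        r_sim = np.linalg.norm(m.vertices, axis=1).mean()
        assert r_sim > 1.0
        assert r_sim == pytest.approx(opt.x, rel=1e-3)

    def test_nonfinite_step_raises(self, icosphere1):
        m = icosphere1.copy()
        m.vertices = m.vertices * 1.5
        m.invalidate()
        p = mech.MechParams(dt=1e308, max_step_frac=0.0)
        with pytest.raises(mech.IntegrationError, match="dt"):
            mech.step_overdamped(m, p)


class TestCompiledKernel:
    def test_kernel_matches_vectorized_forces(self, rng):
        """The compiled relax kernel and the numpy path are dual routes to
        the same analytic forces."""
        if not mech._HAVE_NUMBA:
            # fallback path is the vectorized one; nothing to cross-check
            return
        m = M.build_icosphere(2, 1.0)
        M.init_bud_patch(m, [0, 0, 1], 0.5)
        m.set_rest_state_from_geometry()
        m.vertices = m.vertices + 0.01 * rng.standard_normal(m.vertices.shape)
        p = mech.MechParams()
        geom = M.compute_geometry(m)
        ref = mech.elastic_forces(m, geom, p) + mech.turgor_forces(m, geom, p)
        buf = np.empty_like(m.vertices)
        vmin = np.empty(m.n_vertices)
        out, min_edge = mech._fast_forces(
            m, p, mech._compiled_force_arrays(m, p), buf, vmin)
        assert np.abs(out - ref).max() <= 1e-9 * np.abs(ref).max()
        assert min_edge == pytest.approx(geom.edge_length.min())
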