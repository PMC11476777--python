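"""Spatial cue, Laplace-Beltrami discretization, and the activator /
global-inhibitor reaction-diffusion system."""

import numpy as np
import pytest

from budmorph import mesh as M
from budmorph import remodeling as R
from budmorph import mechanics as mech
from budmorph import signaling as S
from budmorph.schedules import Schedule


def _cue_params(n, umin=0.05, umax=1.0):
    return S.CueParams(umin=umin, umax=umax, n_schedule=Schedule.constant(n))


class TestCueField:
    def test_endpoints(self, budded_sphere):
        cue = S.cue_field(budded_sphere, _cue_params(3.0), 0)
        cz = budded_sphere.vertices[budded_sphere.faces, 2].mean(axis=1)
        tip, bottom = int(np.argmax(cz)), int(np.argmin(cz))
        assert cue.u[tip] == pytest.approx(1.0, abs=0.02)
        assert cue.u[bottom] == pytest.approx(0.05, abs=0.01)
        assert cue.u.min() >= 0.05 and cue.u.max() <= 1.0

    def test_mid_height_direct_substitution(self, budded_sphere):
        # s = 0.5, n = 2 -> u = umin + 0.25 (umax - umin)
        cue = S.cue_field(budded_sphere, _cue_params(2.0), 0)
        cz = budded_sphere.vertices[budded_sphere.faces, 2].mean(axis=1)
        s = (cz - cue.H_min) / cue.H_total
        k = int(np.argmin(np.abs(s - 0.5)))
        expect = 0.05 + (1.0 - 0.05) * s[k] ** 2
        assert cue.u[k] == pytest.approx(expect, rel=1e-12)

    def test_large_exponent_limit(self, budded_sphere):
        # n -> inf: u collapses to umin everywhere away from the tip
        cue = S.cue_field(budded_sphere, _cue_params(400.0), 0)
        cz = budded_sphere.vertices[budded_sphere.faces, 2].mean(axis=1)
        s = (cz - cue.H_min) / cue.H_total
        assert np.all(cue.u[s < 0.95] < 0.05 + 1e-3)
        assert cue.u.max() == pytest.approx(1.0)

    def test_schedule_drives_exponent(self, budded_sphere):
        cp = S.CueParams(n_schedule=Schedule((0, 10), (2.0, 8.0), "linear"))
        assert S.cue_field(budded_sphere, cp, 0).n == 2.0
        assert S.cue_field(budded_sphere, cp, 5).n == 5.0
        assert S.cue_field(budded_sphere, cp, 99).n == 8.0

    def test_flat_mesh_rejected(self):
        m = M.build_icosphere(1, 1.0)
        m.vertices[:, 2] = 0.0
        m.invalidate()
        with pytest.raises(M.MeshError, match="H_total"):
            S.cue_field(m, _cue_params(2.0), 0)


class TestLaplacian:
    def test_constants_in_kernel_and_symmetry(self, budded_sphere):
        W, mass = S.assemble_laplacian(budded_sphere)
        assert abs(W - W.T).max() == 0.0
        c = np.full(budded_sphere.n_vertices, 3.7)
        assert np.abs(W @ c).max() < 1e-12
        assert mass.sum() == pytest.approx(
            M.compute_geometry(budded_sphere).total_area, rel=1e-12)

    def test_l1_harmonic_eigenvalue_converges(self):
        """z is an l=1 spherical harmonic: Lap z = -2 z on the unit sphere;
        the discrete error must fall below 2% and shrink with refinement."""
        errs = []
        for sub in (3, 4, 5):
            m = M.build_icosphere(sub, 1.0)
            W, mass = S.assemble_laplacian(m)
            z = m.vertices[:, 2]
            lap = (W @ z) / mass
            errs.append(np.sqrt(mass @ (lap + 2 * z) ** 2 / (mass @ (2 * z) ** 2)))
        assert errs[2] < 0.02
        assert errs[0] > errs[1] > errs[2]

    def test_degenerate_triangle_warns_and_clamps(self):
        m = M.build_icosphere(1, 1.0)
        # squash one vertex onto a neighbor's position (nearly)
        top = m.topology
        i, j = top.edges[0]
        m.vertices[j] = m.vertices[i] + 1e-9
        m.invalidate()
        with pytest.warns(UserWarning, match="clamped"):
            W, _ = S.assemble_laplacian(m)
        assert np.isfinite(W.data).all()


class TestSurfaceAverage:
    def test_constant_field(self, budded_sphere):
        assert S.surface_average(budded_sphere, np.full(
            budded_sphere.n_vertices, 2.5)) == pytest.approx(2.5)

    def test_odd_field_on_symmetric_sphere(self, icosphere2):
        assert abs(S.surface_average(icosphere2, icosphere2.vertices[:, 2])) < 1e-12

    def test_against_per_face_quadrature_oracle(self, budded_sphere, rng):
        a = rng.random(budded_sphere.n_vertices)
        geom = M.compute_geometry(budded_sphere)
        # integral of the linear interpolant over each face = A * mean(corners)
        total = sum(Af * a[f].mean() for Af, f in
                    zip(geom.face_area, budded_sphere.faces))
        assert S.surface_average(budded_sphere, a) == pytest.approx(
            total / geom.total_area, rel=1e-10)


class TestRdStep:
    def test_pure_diffusion_of_constant(self, budded_sphere):
        p = S.SignalingParams(k0=0, k1=0, k2=0, k3=0, k4=0)
        cue = S.cue_field(budded_sphere, _cue_params(2.0), 0)
        st = S.ChemicalState(np.full(budded_sphere.n_vertices, 0.7), 1.0)
        out = S.rd_step(budded_sphere, st, cue, p, 0.1)
        assert np.allclose(out.a, 0.7, rtol=1e-10)

    def test_pure_decay_matches_closed_form(self, budded_sphere):
        k2 = 3.0
        p = S.SignalingParams(Dc=0.0, k0=0, k1=0, k2=k2, k3=0, k4=0)
        cue = S.cue_field(budded_sphere, _cue_params(2.0), 0)
        dt = 1e-3 / k2
        st = S.ChemicalState(np.full(budded_sphere.n_vertices, 1.0), 1.0)
        op = S.DiffusionOperator(budded_sphere, 0.0, dt)
        n_steps = 200
        for _ in range(n_steps):
            st = S.rd_step(budded_sphere, st, cue, p, dt, op)
        expect = np.exp(-k2 * n_steps * dt)
        assert st.a[0] == pytest.approx(expect, rel=1e-4)

    def test_inhibitor_grows_when_average_exceeds_setpoint(self, budded_sphere):
        p = S.SignalingParams()
        cue = S.cue_field(budded_sphere, _cue_params(2.0), 0)
        st = S.ChemicalState(np.full(budded_sphere.n_vertices, 10 * p.kss), 1.0)
        out = S.rd_step(budded_sphere, st, cue, p, 0.05)
        assert out.b > st.b


class TestQuasiSteady:
    def test_homeostasis_forced_by_inhibitor(self, budded_sphere):
        p = S.SignalingParams()
        cue = S.cue_field(budded_sphere, _cue_params(8.0), 0)
        st = S.solve_quasi_steady(budded_sphere, S.ChemicalState.uniform(
            budded_sphere, p), cue, p, tol=1e-6)
        assert st.converged and st.b > 0
        abar = S.surface_average(budded_sphere, st.a)
        assert abs(abar - p.kss) < 1e-6

    def test_uniform_cue_gives_uniform_field(self, budded_sphere):
        p = S.SignalingParams()
        cue = S.cue_field(budded_sphere, _cue_params(2.0, umin=0.4, umax=0.4), 0)
        st = S.solve_quasi_steady(budded_sphere, S.ChemicalState.uniform(
            budded_sphere, p), cue, p, tol=1e-8)
        spread = st.a.max() - st.a.min()
        assert spread < 1e-6 * st.a.mean()

    def test_steep_cue_localizes_at_tip(self, budded_sphere):
        p = S.SignalingParams()
        cue = S.cue_field(budded_sphere, _cue_params(8.0), 0)
        st = S.solve_quasi_steady(budded_sphere, S.ChemicalState.uniform(
            budded_sphere, p), cue, p, tol=1e-6)
        peak = int(np.argmax(st.a))
        tip = int(np.argmax(budded_sphere.vertices[:, 2]))
        max_edge = M.compute_geometry(budded_sphere).edge_length.max()
        assert np.linalg.norm(budded_sphere.vertices[peak]
                              - budded_sphere.vertices[tip]) <= max_edge

    def test_polarization_height_monotone_in_exponent(self, budded_sphere):
        from budmorph.metrics import polarization_height
        p = S.SignalingParams()
        phs = []
        for n in (2.0, 4.0, 8.0):
            cue = S.cue_field(budded_sphere, _cue_params(n), 0)
            st = S.solve_quasi_steady(budded_sphere, S.ChemicalState.uniform(
                budded_sphere, p), cue, p, tol=1e-6)
            phs.append(polarization_height(budded_sphere, st.a, 0.8)[0])
        assert phs[0] >= phs[1] >= phs[2]
        assert phs[0] > phs[2]

    def test_nonconvergence_flagged(self, budded_sphere):
        p = S.SignalingParams()
        cue = S.cue_field(budded_sphere, _cue_params(8.0), 0)
        with pytest.warns(UserWarning, match="did not converge"):
            st = S.solve_quasi_steady(budded_sphere, S.ChemicalState.uniform(
                budded_sphere, p), cue, p, tol=1e-6, max_iters=3)
        assert not st.converged

    def test_b_zero_initial_state_rejected(self, budded_sphere):
        with pytest.raises(ValueError, match="positive"):
            S.ChemicalState(np.ones(budded_sphere.n_vertices), 0.0)


class TestRemodelTransfer:
    def test_swap_only_leaves_field(self, budded_sphere, rng):
        old = budded_sphere.copy()
        a = rng.random(budded_sphere.n_vertices)
        st = S.ChemicalState(a.copy(), 1.0)
        R.run_swaps(budded_sphere, 200, mech.MechParams(), 5.0, rng)
        out = S.transfer_state_after_remodel(old, st, budded_sphere)
        assert np.array_equal(out.a, a)
        assert out.b == st.b

    def test_split_vertex_gets_endpoint_mean(self, budded_sphere, rng):
        m = budded_sphere
        old = m.copy()
        a = np.zeros(m.n_vertices)
        cands = R._region_interior_edges(m, set(int(f) for f in m.bud_faces()))
        i, j = cands[0]
        a[i], a[j] = 2.0, 4.0
        st = S.ChemicalState(a.copy(), 1.0)
        R.split_pair(m, (i, j), 1.1)
        out = S.transfer_state_after_remodel(old, st, m)
        assert out.a[-1] == pytest.approx(3.0)
        assert len(out.a) == m.n_vertices

    def test_mass_drift_bounded_per_split(self, budded_sphere, rng):
        m = budded_sphere
        old = m.copy()
        a = rng.random(m.n_vertices)
        st = S.ChemicalState(a.copy(), 1.0)
        geom0 = M.compute_geometry(m)
        total0 = geom0.vertex_dual_area @ a
        cands = R._region_interior_edges(m, set(int(f) for f in m.bud_faces()))
        R.split_pair(m, cands[0], 1.1)
        out = S.transfer_state_after_remodel(old, st, m)
        geom1 = M.compute_geometry(m)
        total1 = geom1.vertex_dual_area @ out.a
        new_mass = geom1.vertex_dual_area[-1]
        assert abs(total1 - total0) <= new_mass * out.a[-1] + 1e-12

    def test_missing_provenance_raises(self, budded_sphere, rng):
        m = budded_sphere
        old = m.copy()
        st = S.ChemicalState(np.ones(m.n_vertices), 1.0)
        cands = R._region_interior_edges(m, set(int(f) for f in m.bud_faces()))
        R.split_pair(m, cands[0], 1.1)
        m.journal.clear()  # simulate lost provenance
        with pytest.raises(M.MeshError):
            S.transfer_state_after_remodel(old, st, m)


class TestRemeshStability:
    def test_field_stable_under_random_swaps(self, rng):
        """Solving, swapping 100 times, and re-solving moves the field by
        less than 1% in relative L2 norm (on a mesh fine enough to resolve
        the polarization length scale)."""
        m = M.build_icosphere(4, 1.0)
        M.init_bud_patch(m, [0, 0, 1], 0.5)
        m.set_rest_state_from_geometry()
        p = S.SignalingParams()
        cue = S.cue_field(m, _cue_params(8.0), 0)
        st = S.solve_quasi_steady(m, S.ChemicalState.uniform(m, p), cue, p,
                                  tol=1e-8)
        a_before = st.a.copy()
        stats = R.run_swaps(m, 100, mech.MechParams(), 2.0, rng)
        assert stats.accepted > 10
        st2 = S.solve_quasi_steady(m, st, S.cue_field(m, _cue_params(8.0), 0),
                                   p, tol=1e-8)
        drift = np.linalg.norm(st2.a - a_before) / np.linalg.norm(a_before)
        assert st2.converged
        assert drift < 0.01
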