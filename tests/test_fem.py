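from dataclasses import replace

import numpy as np
import pytest

from cartatlas import fem
from cartatlas.material import TIBIAL

LINEAR = replace(TIBIAL, e_0=0.0, e_eps=0.0, linear_matrix=True)


def _box(nx, ny, nz, lx, ly, h):
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, h, nz + 1)
    nodes = np.array([[x, y, z] for z in zs for y in ys for x in xs])

    def nid(i, j, k):
        return k * (nx + 1) * (ny + 1) + j * (nx + 1) + i

    elems = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elems.append([nid(i, j, k), nid(i + 1, j, k),
                              nid(i + 1, j + 1, k), nid(i, j + 1, k),
                              nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    top = np.nonzero(nodes[:, 2] == h)[0]
    bottom = np.nonzero(nodes[:, 2] == 0)[0]
    return nodes, np.array(elems), top, bottom


def _terzaghi_error(nz, nsteps, Tv=0.3):
    """Relative L2 error of the consolidation pressure profile vs the
    closed-form series solution, evaluated at time factor Tv."""
    cv = fem.consolidation_coefficient(LINEAR)
    t_end = Tv / cv
    times = np.concatenate([[0.0], np.linspace(t_end / nsteps, t_end, nsteps)])
    sigma0 = 0.001
    pb = fem.terzaghi_problem(nz, LINEAR, sigma0, times)
    hist = fem.solve(pb)
    z = pb.nodes[:, 2]
    zs = np.unique(z)
    p_num = np.array([hist.p[-1][z == zz].mean() for zz in zs])
    p_ref = sigma0 * fem.terzaghi_series(1.0 - zs, Tv)
    return np.linalg.norm(p_num - p_ref) / np.linalg.norm(p_ref)


class TestSolve:
    def test_zero_load_stays_at_rest(self):
        pb = fem.terzaghi_problem(5, LINEAR, 0.0, [0.0, 1.0, 2.0])
        pb.f_ext = None
        hist = fem.solve(pb)
        assert np.abs(hist.u).max() == 0.0
        assert np.abs(hist.p).max() == 0.0

    def test_terzaghi_pore_pressure_profile(self):
        assert _terzaghi_error(20, 100) < 0.02

    def test_undrained_column_is_incompressible(self):
        """Sealed column under a step load: the pore fluid carries the
        full load (p = sigma0) and the skeleton barely deforms."""
        sigma0 = 0.001
        pb = fem.terzaghi_problem(10, LINEAR, sigma0, [0.0, 1e-3],
                                  drained=False)
        hist = fem.solve(pb)
        assert np.allclose(hist.p[-1], sigma0, rtol=1e-6)
        eps = hist.strain[-1]
        vol = eps[..., :3].sum(axis=-1)
        lam, mu = LINEAR.lame
        eps_drained = sigma0 / (lam + 2 * mu)  # drained axial strain scale
        assert np.abs(vol).max() < 0.01 * eps_drained

    def test_discrete_fluid_mass_conservation_when_sealed(self):
        sigma0 = 0.001
        pb = fem.terzaghi_problem(10, LINEAR, sigma0, [0.0, 0.5, 1.0],
                                  drained=False)
        hist = fem.solve(pb)
        sys_ = fem._System(pb)
        for i in (1, 2):
            u1 = hist.u[i].ravel()
            u0 = hist.u[i - 1].ravel()
            dt = hist.times[i] - hist.times[i - 1]
            resid = (sys_.Q.T @ (u1 - u0) + dt * (sys_.H @ hist.p[i])
                     + sys_.S @ (hist.p[i] - hist.p[i - 1]))
            # sealed + incompressible: skeleton barely moves, so compare
            # against the volume scale the load would cause if drained
            lam, mu = LINEAR.lame
            vol_scale = sigma0 / (lam + 2 * mu) * 10.0  # strain x volume
            assert np.linalg.norm(resid) < 1e-8 * vol_scale

    def test_energy_balance_dissipation_nonnegative(self):
        """External work is never less than stored elastic energy."""
        cv = fem.consolidation_coefficient(LINEAR)
        t_end = 0.3 / cv
        times = np.concatenate([[0.0], np.linspace(t_end / 40, t_end, 40)])
        sigma0 = 0.001
        pb = fem.terzaghi_problem(10, LINEAR, sigma0, times)
        hist = fem.solve(pb)
        f = pb.f_ext(0, 0.0)
        work = 0.0
        lam, mu = LINEAR.lame
        D = fem._linear_D(lam, mu)
        sys_ = fem._System(pb)
        for i in range(1, len(times)):
            du = (hist.u[i] - hist.u[i - 1]).ravel()
            work += f @ hist.u[i].ravel() - f @ hist.u[i - 1].ravel()
            eps = hist.strain[i]
            energy = 0.5 * np.einsum("egi,ij,egj,eg->", eps, D, eps,
                                     sys_.wdet)
            assert work >= energy - 1e-12

    def test_unconstrained_mesh_raises_informative_error(self):
        nodes, elems, top, bottom = _box(2, 2, 2, 1, 1, 1)
        f = np.zeros(nodes.size)
        f[3 * top + 2] = -0.01
        pb = fem.FEProblem(nodes=nodes, elements=elems, params=LINEAR,
                           times=np.array([0.0, 1.0]), drained=top,
                           f_ext=lambda s, t: f)
        with pytest.raises(fem.SingularSystemError):
            fem.solve(pb)

    def test_refinement_converges_monotonically(self):
        errs = [_terzaghi_error(nz, ns)
                for nz, ns in [(5, 25), (10, 50), (20, 100)]]
        assert errs[0] > errs[1] > errs[2]


class TestContact:
    def test_distant_surface_gives_no_force(self):
        pos = np.zeros((4, 3))
        areas = np.ones(4)
        plane = fem.RigidPlane([0, 0, 5.0], [0, 0, 1.0])
        forces, flags, stiff = fem.contact_step(pos, areas, plane, 10.0)
        assert np.all(forces == 0) and not flags.any()
        assert np.all(stiff == 0)

    def test_uniform_overlap_gives_penalty_traction(self):
        nodes, elems, top, bottom = _box(4, 4, 1, 8.0, 8.0, 2.0)
        areas = fem.tributary_areas(nodes, elems, top)
        assert areas.sum() == pytest.approx(64.0)
        overlap = 0.05
        plane = fem.RigidPlane([0, 0, 2.0 - overlap], [0, 0, 1.0])
        forces, flags, _ = fem.contact_step(nodes[top], areas, plane, 100.0)
        assert flags.all()
        traction = -forces[:, 2].sum() / 64.0
        assert traction == pytest.approx(100.0 * overlap)

    def test_compression_only(self, rng):
        pos = rng.normal(size=(50, 3))
        areas = np.abs(rng.normal(size=50)) + 0.1
        sphere = fem.RigidSphere([0.0, 0.0, 0.0], 1.0)
        forces, flags, _ = fem.contact_step(pos, areas, sphere, 5.0)
        inside = np.linalg.norm(pos, axis=1) < 1.0
        assert np.array_equal(flags, inside)
        # force pushes strictly outward from the center
        radial = np.einsum("ni,ni->n", forces, pos)
        assert np.all(radial[flags] > 0)

    def test_patch_equilibrium_contact_balances_reaction(self):
        """Total contact force equals the bottom reaction within 1%."""
        nodes, elems, top, bottom = _box(4, 4, 2, 8.0, 8.0, 2.0)
        areas = fem.tributary_areas(nodes, elems, top)
        plane = fem.RigidPlane([0, 0, 2.0 - 0.02], [0, 0, 1.0])
        pb = fem.FEProblem(
            nodes=nodes, elements=elems, params=LINEAR,
            times=np.array([0.0, 0.01]),
            fix={"x": bottom, "y": bottom, "z": bottom},
            drained=np.array([], dtype=int),
            contact_nodes=top, contact_areas=areas,
            surface_fn=lambda s, t: plane, penalty=50.0)
        hist = fem.solve(pb)
        pos = nodes[top] + hist.u[-1][top]
        forces, _, _ = fem.contact_step(pos, areas, plane, 50.0)
        f_contact = -forces[:, 2].sum()
        # reaction: internal nodal forces on the fixed bottom nodes
        sys_ = fem._System(pb)
        eps = sys_.gp_strain(hist.u[-1].ravel())
        hist0 = (np.zeros((sys_.ne, 8, sys_.nf)),) * 2
        sig, _, _, _ = sys_.material(eps, hist0, 0.01)
        f_int = sys_.internal_force(sig) - sys_.Q @ hist.p[-1]
        f_bottom = f_int[3 * bottom + 2].sum()
        assert f_contact == pytest.approx(f_bottom, rel=0.01)

    def test_nonpositive_penalty_rejected(self):
        with pytest.raises(ValueError):
            fem.contact_step(np.zeros((1, 3)), np.ones(1),
                             fem.RigidPlane([0, 0, 0], [0, 0, 1]), 0.0)


class TestRunGait:
    @pytest.fixture(scope="class")
    def gait_setup(self):
        from cartatlas.fixtures import FixtureSpec, gen_atlas_library
        from cartatlas.gait import build_loading, default_gait_waveform, \
            resample_waveform
        from cartatlas.pipeline import build_fe_problem
        lib = gen_atlas_library(FixtureSpec(seed=7, n_atlases=1))
        atlas = lib.atlases[0]
        wf = resample_waveform(default_gait_waveform(), 13)
        loading = build_loading(wf, 75.0, 0.4)
        problem, surface = build_fe_problem(atlas, loading)
        return problem, surface, loading

    def test_stance_grid_produces_matching_frames(self, gait_setup):
        problem, surface, loading = gait_setup
        hist = fem.run_gait(problem, loading, base_surface=surface)
        assert hist.u.shape[0] == 13
        assert hist.stance_pct[-1] == 100.0
        assert hist.contact_flags.any(axis=1).all(), \
            "every frame should have a loaded contact patch"

    def test_pore_pressure_tracks_applied_force(self, gait_setup):
        problem, surface, loading = gait_setup
        hist = fem.run_gait(problem, loading, base_surface=surface)
        peak_p = hist.p.max(axis=1)
        assert peak_p.max() > 0.2  # pressurized at peak load (MPa)
        # at gait rates the fluid carries the load, so the pore-pressure
        # trajectory must track the force-control target closely
        r = np.corrcoef(peak_p, loading.medial_force_n)[0, 1]
        assert r > 0.9

    def test_degenerate_constant_loading_matches_static(self, gait_setup):
        problem, surface, loading = gait_setup
        from cartatlas.gait import LoadingProfile
        const = LoadingProfile(
            stance_pct=np.linspace(0, 100, 5),
            medial_force_n=np.full(5, 150.0),
            flexion_deg=np.zeros(5),
            body_mass_kg=loading.body_mass_kg,
            meniscus_fraction=loading.meniscus_fraction)
        hist = fem.run_gait(problem, const, base_surface=surface)
        # at constant force the displacement field settles monotonically
        peak_u = np.abs(hist.u[:, :, 2]).max(axis=1)
        assert peak_u[1] > 0
        assert np.all(np.diff(peak_u[1:]) > -0.05 * peak_u[1])
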