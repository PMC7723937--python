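import numpy as np
import pytest

from cartatlas.material import (FEMORAL, TIBIAL, FRPVEParams,
                                MaterialPointState, fibril_stress_update,
                                fluid_fraction, nonfibrillar_stress,
                                primary_fibril_directions,
                                secondary_fibril_directions, total_stress)


class TestFluidFraction:
    def test_surface_and_deep_values(self):
        assert fluid_fraction(0.0) == pytest.approx(0.8)
        assert fluid_fraction(1.0) == pytest.approx(0.65)

    def test_strictly_decreasing_with_depth(self):
        h = np.linspace(0, 1, 50)
        assert np.all(np.diff(fluid_fraction(h)) < 0)

    @pytest.mark.parametrize("h", [-0.01, 1.01])
    def test_depth_outside_unit_interval_rejected(self, h):
        with pytest.raises(ValueError):
            fluid_fraction(h)


class TestFibrilDirections:
    def test_arcade_boundary_conditions(self):
        s, n = np.array([1.0, 0, 0]), np.array([0, 0, 1.0])
        surface = primary_fibril_directions(0.0, s, n)
        assert abs(surface[0] @ s) == pytest.approx(1.0)
        deep = primary_fibril_directions(1.0, s, n)
        assert abs(deep[0] @ n) == pytest.approx(1.0)
        assert abs(deep[1] @ n) == pytest.approx(1.0)

    def test_unit_norm_over_random_depths_and_frames(self, rng):
        for _ in range(100):
            v = rng.normal(size=3)
            s = v / np.linalg.norm(v)
            w = rng.normal(size=3)
            n = w - (w @ s) * s
            n /= np.linalg.norm(n)
            dirs = primary_fibril_directions(rng.uniform(0, 1), s, n)
            assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0,
                               atol=1e-12)

    def test_non_orthogonal_frame_rejected(self):
        with pytest.raises(ValueError):
            primary_fibril_directions(0.5, np.array([1.0, 0, 0]),
                                      np.array([0.5, 0, 1.0]))

    def test_secondary_set_is_13_unit_nonparallel(self):
        d = secondary_fibril_directions()
        assert d.shape == (13, 3)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        dots = np.abs(d @ d.T) - np.eye(13)
        assert dots.max() < 1 - 1e-6


def _zero_state(n):
    return (np.zeros(n), np.zeros(n)) if n > 1 else (0.0, 0.0)


class TestFibrilLaw:
    def test_compression_carries_no_stress(self):
        s, _ = fibril_stress_update(-0.05, (0.0, 0.0), 0.1, TIBIAL)
        assert s == 0.0

    @pytest.mark.parametrize("params", [FEMORAL, TIBIAL])
    def test_zero_eta_is_purely_elastic(self, params):
        from dataclasses import replace
        p = replace(params, eta=0.0)
        eps = 0.05
        s, _ = fibril_stress_update(eps, (0.0, 0.0), 0.1, p)
        assert s == pytest.approx(p.e_0 * eps + 0.5 * p.e_eps * eps ** 2,
                                  rel=1e-12)

    @pytest.mark.parametrize("params", [FEMORAL, TIBIAL])
    def test_transient_and_equilibrium_match_ode_oracle(self, params):
        """Ramp to 5% strain, hold 1e4 s: backward-Euler fibril stress
        tracks an explicit fine-step integration of the adopted ODE
        within 0.1% and lands on the closed-form equilibrium."""
        eps_hold, t_ramp, t_end = 0.05, 1.0, 1.0e4

        def strain(t):
            return eps_hold * min(t / t_ramp, 1.0)

        # oracle: explicit Euler at dt=1e-3 on
        #   sigma_v' = E_br(eps) eps' - (E_br(eps)/eta) sigma_v
        dt_o = 1e-3
        n_ramp = int(t_ramp / dt_o)
        sv = 0.0
        e_prev = 0.0
        for i in range(1, n_ramp + 1):
            e = strain(i * dt_o)
            ebr = params.e_0 + params.e_eps * e
            sv += ebr * (e - e_prev) - ebr / params.eta * sv * dt_o
            e_prev = e
        ebr_h = params.e_0 + params.e_eps * eps_hold
        sigma_eq = params.e_0 * eps_hold + 0.5 * params.e_eps * eps_hold ** 2

        def oracle(t):
            return sigma_eq + sv * np.exp(-(t - t_ramp) * ebr_h / params.eta)

        # implementation: backward Euler, fine steps on the ramp where
        # the modulus lag matters, coarser ones during the hold
        state = (0.0, 0.0)
        t, s_impl = 0.0, 0.0
        probes = {}
        probe_times = [50.0, 200.0, 1000.0, t_end]
        for dt in [0.001] * 1000 + [0.25] * int((t_end - t_ramp) / 0.25):
            t += dt
            s_impl, state = fibril_stress_update(strain(t), state, dt, params)
            for tp in probe_times:
                if abs(t - tp) < 1e-9:
                    probes[tp] = s_impl
        for tp, s in probes.items():
            assert s == pytest.approx(oracle(tp), rel=1e-3), tp
        assert probes[t_end] == pytest.approx(sigma_eq, rel=1e-3)

    def test_relaxation_is_monotone_and_bounded_below(self):
        state = (0.0, 0.0)
        eps = 0.05
        vals = []
        for _ in range(500):
            s, state = fibril_stress_update(eps, state, 5.0, TIBIAL)
            vals.append(s)
        sigma_eq = TIBIAL.e_0 * eps + 0.5 * TIBIAL.e_eps * eps ** 2
        assert np.all(np.diff(vals) <= 1e-15)
        assert vals[-1] >= sigma_eq - 1e-12

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            fibril_stress_update(0.01, (0.0, 0.0), 0.0, TIBIAL)


def _voigt_matrix(e, nu):
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = mu * np.eye(3)
    return D


class TestNonfibrillarMatrix:
    def test_zero_strain_zero_stress(self):
        assert np.allclose(nonfibrillar_stress(np.zeros((3, 3)), TIBIAL), 0)

    def test_small_strain_limit_is_hookean(self):
        eps = np.zeros((3, 3))
        eps[0, 0] = 1e-6
        sig = nonfibrillar_stress(eps, FEMORAL)
        lam, mu = FEMORAL.lame
        assert sig[0, 0] == pytest.approx((lam + 2 * mu) * 1e-6, rel=1e-5)
        assert sig[1, 1] == pytest.approx(lam * 1e-6, rel=1e-5)

    def test_random_small_strain_matches_voigt_oracle(self, rng):
        D = _voigt_matrix(TIBIAL.e_m, TIBIAL.nu_m)
        for _ in range(20):
            v = rng.normal(scale=1e-7, size=6)
            eps = np.array([[v[0], v[3] / 2, v[5] / 2],
                            [v[3] / 2, v[1], v[4] / 2],
                            [v[5] / 2, v[4] / 2, v[2]]])
            sig = nonfibrillar_stress(eps, TIBIAL)
            sv = np.array([sig[0, 0], sig[1, 1], sig[2, 2],
                           sig[0, 1], sig[1, 2], sig[0, 2]])
            assert np.allclose(sv, D @ v, rtol=1e-4, atol=1e-16)

    def test_asymmetric_strain_rejected(self):
        bad = np.array([[0.0, 1e-3, 0], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            nonfibrillar_stress(bad, TIBIAL)


def _state(strain, p=0.0, primary=None, secondary=None, depth=0.0):
    if primary is None:
        primary = primary_fibril_directions(depth, np.array([1.0, 0, 0]),
                                            np.array([0.0, 0, 1]))
    if secondary is None:
        secondary = secondary_fibril_directions()
    return MaterialPointState(strain=np.asarray(strain, float),
                              pore_pressure=p, depth=depth,
                              primary_dirs=primary, secondary_dirs=secondary)


class TestTotalStress:
    def test_zero_strain_zero_pressure_gives_zero(self):
        sig, _ = total_stress(_state(np.zeros((3, 3))), TIBIAL, 0.1)
        assert np.allclose(sig, 0.0)

    def test_pure_pressure_gives_minus_p_identity(self):
        sig, _ = total_stress(_state(np.zeros((3, 3)), p=0.5), TIBIAL, 0.1)
        assert np.allclose(sig, -0.5 * np.eye(3))

    def test_mixture_additivity_is_exact(self, rng):
        """total - (-pI) - sigma_nf equals the summed fibril term."""
        eps = rng.normal(scale=0.01, size=(3, 3))
        eps = 0.5 * (eps + eps.T)
        p = 0.3
        st = _state(eps, p=p, depth=0.4)
        sig, _ = total_stress(st, TIBIAL, 0.1)
        fib_term = sig + p * np.eye(3) - nonfibrillar_stress(eps, TIBIAL)
        # recompute the fibril sum independently
        from cartatlas.material import fibril_weights
        dirs = np.vstack([st.primary_dirs, st.secondary_dirs])
        w = fibril_weights(2, 13, TIBIAL.primary_density_ratio)
        expect = np.zeros((3, 3))
        for wi, d in zip(w, dirs):
            ef = d @ eps @ d
            s, _ = fibril_stress_update(float(ef), (0.0, 0.0), 0.1, TIBIAL)
            expect += wi * s * np.outer(d, d)
        assert np.allclose(fib_term, expect, atol=1e-14)

    def test_single_fibril_uniaxial_hand_assembly(self):
        from dataclasses import replace
        par = replace(TIBIAL, eta=0.0)
        d = np.array([1.0, 0.0, 0.0])
        eps = np.diag([0.05, 0.0, 0.0])
        st = _state(eps, primary=d[None, :], secondary=np.zeros((0, 3)))
        sig, _ = total_stress(st, par, 0.1)
        s_f, _ = fibril_stress_update(0.05, (0.0, 0.0), 0.1, par)
        expect = nonfibrillar_stress(eps, par) + s_f * np.outer(d, d)
        assert np.allclose(sig, expect, atol=1e-14)

    def test_tension_stiffer_than_compression(self):
        e = 0.02
        up, _ = total_stress(_state(np.diag([e, 0, 0])), TIBIAL, 0.1)
        dn, _ = total_stress(_state(np.diag([-e, 0, 0])), TIBIAL, 0.1)
        assert up[0, 0] > -dn[0, 0]

    def test_rotation_equivariance(self, rng):
        from scipy.spatial.transform import Rotation
        eps = rng.normal(scale=0.01, size=(3, 3))
        eps = 0.5 * (eps + eps.T)
        st = _state(eps, p=0.2, depth=0.3)
        sig, _ = total_stress(st, TIBIAL, 0.1)
        for R in Rotation.random(20, rng=rng).as_matrix():
            st_r = MaterialPointState(
                strain=R @ eps @ R.T, pore_pressure=0.2, depth=0.3,
                primary_dirs=st.primary_dirs @ R.T,
                secondary_dirs=st.secondary_dirs @ R.T)
            sig_r, _ = total_stress(st_r, TIBIAL, 0.1)
            assert np.allclose(sig_r, R @ sig @ R.T, atol=1e-12)


def test_table_defaults_and_unit_conversion():
    assert FEMORAL.e_m == 0.215 and FEMORAL.e_0 == 0.92
    assert TIBIAL.e_eps == 23.06 and TIBIAL.k_perm == 18.0
    # 1e-15 m^4/(N s) = 1e-3 mm^4/(N s)
    assert TIBIAL.k_mm == pytest.approx(0.018)


def test_material_config_yaml_round_trip(tmp_path):
    cfg = tmp_path / "mat.yaml"
    cfg.write_text("tibial:\n  e_m: 0.2\nfemoral: {}\n")
    from cartatlas.material import load_material_config
    mats = load_material_config(cfg)
    assert mats["tibial"].e_m == 0.2
    assert mats["tibial"].e_0 == TIBIAL.e_0
    assert mats["femoral"] == FEMORAL


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        FRPVEParams(e_m=0.1, e_0=0.2, e_eps=1.0, nu_m=0.6, eta=1.0, k_perm=1.0)
    with pytest.raises(ValueError):
        FRPVEParams(e_m=-1.0, e_0=0.2, e_eps=1.0, nu_m=0.1, eta=1.0, k_perm=1.0)
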