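"""Material model, air-puff load, explicit solver and static inflation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orasim import _kernel
from orasim.geometry import CorneaGeometry, build_mesh, solve_unloaded_config
from orasim.mechanics import (AirPuff, MaterialModel, airpuff_spatial,
                              airpuff_temporal, relaxation_modulus,
                              simulate_airpuff, stable_timestep,
                              static_inflate)
from orasim.units import MMHG_TO_PA

GEOM = CorneaGeometry(R_mm=7.0, CCT_um=550.0)
VISCO = MaterialModel(E_MPa=0.4, a1=0.4, a2=0.1, a3=0.1,
                      tau1_s=10.0 ** -2.5, tau2_s=1e-4, tau3_s=1e-4)


class TestMaterialModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            MaterialModel(E_MPa=-1.0)
        with pytest.raises(ValueError):
            MaterialModel(E_MPa=0.4, nu=0.5)
        with pytest.raises(ValueError):
            MaterialModel(E_MPa=0.4, a1=0.7, a2=0.2, a3=0.2)

    @pytest.mark.parametrize("mat,t,expected", [
        (VISCO, 0.0, 1.0),
        (MaterialModel(E_MPa=0.4, a1=0.54, a2=0.1, a3=0.1,
                       tau1_s=0.003, tau2_s=1e-4, tau3_s=1e-4), 1e6, 0.26),
        (MaterialModel(E_MPa=0.4, a1=0.4, a2=0.1, a3=0.1,
                       tau1_s=0.001, tau2_s=1e-4, tau3_s=1e-4),
         0.001, 0.5471608564545294),
    ])
    def test_relaxation_modulus_values(self, mat, t, expected):
        assert relaxation_modulus(mat, t) == pytest.approx(expected, abs=1e-9)

    def test_relaxation_modulus_rejects_negative_time(self):
        with pytest.raises(ValueError):
            relaxation_modulus(VISCO, -1e-6)

    @given(a1=st.floats(0.0, 0.6), a2=st.floats(0.0, 0.15),
           tau1=st.floats(1e-4, 0.1), t=st.floats(0.0, 1.0),
           dt=st.floats(1e-6, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_relaxation_modulus_monotone_with_exact_limit(self, a1, a2, tau1,
                                                          t, dt):
        mat = MaterialModel(E_MPa=0.4, a1=a1, a2=a2, a3=0.1,
                            tau1_s=tau1, tau2_s=1e-4, tau3_s=1e-4)
        assert relaxation_modulus(mat, t) >= relaxation_modulus(mat, t + dt)
        assert relaxation_modulus(mat, 1e9) == pytest.approx(mat.g_inf,
                                                             abs=1e-15)


class TestAirPuff:
    def test_temporal_peak_and_width(self):
        puff = AirPuff()
        assert airpuff_temporal(puff, 0.0121) == 1.0
        assert airpuff_temporal(puff, 0.0121 + 0.0057) == pytest.approx(
            math.exp(-1.0), abs=1e-12)

    @given(dt=st.floats(0.0, 0.0121))
    @settings(max_examples=50, deadline=None)
    def test_temporal_symmetry(self, dt):
        puff = AirPuff()
        a = airpuff_temporal(puff, 0.0121 - dt)
        b = airpuff_temporal(puff, 0.0121 + dt)
        assert a == pytest.approx(b, rel=1e-12)

    def test_spatial_shape(self):
        puff = AirPuff()
        assert airpuff_spatial(puff, 0.0) == pytest.approx(1.020, abs=1e-12)
        assert airpuff_spatial(puff, 0.741) == pytest.approx(
            math.exp(-1.0) + 0.020, abs=1e-12)
        assert airpuff_spatial(puff, 1e6) == pytest.approx(0.020, abs=1e-12)
        # strictly decreasing until the Gaussian underflows to the offset
        x = np.linspace(0, 3.0, 50)
        assert (np.diff(airpuff_spatial(puff, x)) < 0).all()
        x_far = np.linspace(0, 5.5, 50)
        assert (np.diff(airpuff_spatial(puff, x_far)) <= 0).all()


class TestStableTimestep:
    def test_sanity_band_for_default_mesh(self):
        # hand estimate: c_d = sqrt((K + 4G/3)/rho) ~ 80 m/s,
        # L_char ~ 0.05-0.15 mm  ->  dt ~ 0.5-1.5 us
        m = build_mesh(GEOM, 40, 4)
        dt = stable_timestep(m, VISCO)
        assert 2e-7 < dt < 2e-6

    def test_finer_mesh_shrinks_dt(self):
        dt_coarse = stable_timestep(build_mesh(GEOM, 40, 4), VISCO)
        dt_fine = stable_timestep(build_mesh(GEOM, 80, 8), VISCO)
        assert dt_fine < dt_coarse

    def test_quadrupled_modulus_halves_dt(self):
        m = build_mesh(GEOM, 24, 3)
        m1 = MaterialModel(E_MPa=0.2)
        m4 = MaterialModel(E_MPa=0.8)
        assert stable_timestep(m, m4) == pytest.approx(
            stable_timestep(m, m1) / 2.0, rel=1e-12)

    def test_degenerate_element_named(self):
        m = build_mesh(GEOM, 8, 2)
        bad = m.nodes_mm.copy()
        q = m.elems[5]
        bad[q[2]] = bad[q[0]]  # collapse a quad
        bad[q[3]] = bad[q[1]]
        with pytest.raises(ValueError, match="5"):
            stable_timestep(m.with_nodes(bad), VISCO)


class TestStaticInflate:
    def test_zero_pressure_identity(self):
        m = build_mesh(GEOM, 16, 3)
        out = static_inflate(m, VISCO, 0.0)
        assert np.array_equal(out.nodes_mm, m.nodes_mm)

    def test_near_linearity_at_low_pressure(self):
        m = build_mesh(GEOM, 24, 3)
        mat = MaterialModel(E_MPa=0.4)
        apex = m.apex_index
        d1 = static_inflate(m, mat, 1.0).nodes_mm[apex, 1] - m.nodes_mm[apex, 1]
        d2 = static_inflate(m, mat, 2.0).nodes_mm[apex, 1] - m.nodes_mm[apex, 1]
        assert d2 == pytest.approx(2.0 * d1, rel=0.15)

    def test_thin_shell_membrane_stress_matches_laplace(self):
        """Apex membrane stress of a thin spherical cap ~ p R / (2 t)."""
        geom = CorneaGeometry(R_mm=7.0, CCT_um=100.0, pct_offset_um=0.0)
        m = build_mesh(geom, 40, 2)
        _, st_ = static_inflate(m, MaterialModel(E_MPa=0.4), 2.0,
                                return_state=True, modulus="instantaneous")
        sigma_ref = 2.0 * MMHG_TO_PA * 7e-3 / (2.0 * 100e-6)
        apex_inplane = st_.stress_Pa[:4, [0, 3]].mean()
        assert apex_inplane == pytest.approx(sigma_ref, rel=0.10)


class TestDynamics:
    def test_no_puff_means_no_motion(self):
        m = build_mesh(GEOM, 24, 3)
        unl = solve_unloaded_config(m, VISCO, 15.0)
        h = simulate_airpuff(unl, VISCO, 15.0, AirPuff(P_max_mmHg=0.0),
                             output_frames=51)
        assert np.abs(h.apex_displacement_mm).max() < 1e-6
        assert h.times_s[0] == 0.0
        assert h.times_s[-1] == pytest.approx(0.025)
        assert (np.diff(h.times_s) > 0).all()

    def test_stiffer_cornea_indents_less(self):
        m = build_mesh(GEOM, 24, 3)
        peaks = {}
        for E in (0.3, 0.6):
            mat = MaterialModel(E_MPa=E, a1=0.4, a2=0.1, a3=0.1,
                                tau1_s=10.0 ** -2.5, tau2_s=1e-4, tau3_s=1e-4)
            unl = solve_unloaded_config(m, mat, 15.0)
            h = simulate_airpuff(unl, mat, 15.0, AirPuff(), output_frames=51)
            peaks[E] = h.apex_displacement_mm.max()
        assert peaks[0.6] < peaks[0.3]

    def test_axis_nodes_never_move_radially(self, baseline_run):
        _, history, _ = baseline_run
        # the first profile point sits on the symmetry axis in every frame
        assert np.abs(history.anterior_profiles_mm[:, 0, 0]).max() == 0.0

    def test_frame_zero_is_inflated_reference(self, baseline_run):
        _, history, _ = baseline_run
        assert history.apex_displacement_mm[0] == 0.0


def test_zero_prony_update_equals_pure_elasticity():
    """With all a_i = 0 the viscoelastic force evaluation on a fixed state
    equals the plain elastic formula."""
    rng = np.random.default_rng(5)
    m = build_mesh(GEOM, 8, 2)
    X = m.nodes_mm * 1e-3
    ne = m.n_elements
    e_dev = rng.normal(0.0, 0.01, (ne, 4))
    eps_v = rng.normal(0.0, 0.01, ne)
    q_hg = rng.normal(0.0, 1e-6, (ne, 2))
    zero4 = np.zeros((ne, 4))
    V = np.zeros_like(X)
    G0, K = VISCO.shear_modulus_Pa, VISCO.bulk_modulus_Pa
    F_visc = np.zeros_like(X)
    _kernel.element_pass(X, V, m.elems, 1e-7, G0, K, 1.0, 0.0, 0.0, 0.0,
                         1.0, 1.0, 1.0, 0.05, e_dev.copy(), zero4.copy(),
                         zero4.copy(), zero4.copy(), eps_v.copy(),
                         q_hg.copy(), F_visc)

    # independent elastic reference (same mean-gradient element formulas)
    F_ref = np.zeros_like(X)
    for e in range(ne):
        n = m.elems[e]
        x, y = X[n, 0], X[n, 1]
        A = 0.5 * ((x[2] - x[0]) * (y[3] - y[1]) - (x[3] - x[1]) * (y[2] - y[0]))
        rc = 0.25 * x.sum()
        bx = np.array([y[1] - y[3], y[2] - y[0], y[3] - y[1], y[0] - y[2]]) / (2 * A)
        by = np.array([x[3] - x[1], x[0] - x[2], x[1] - x[3], x[2] - x[0]]) / (2 * A)
        s = 2.0 * G0 * e_dev[e]
        pr = K * eps_v[e]
        sig = s + pr * np.array([1.0, 1.0, 0.0, 1.0])
        Ve = 2.0 * np.pi * rc * A
        hoop = 2.0 * np.pi * A * 0.25 * sig[3]
        hvec = np.array([1.0, -1.0, 1.0, -1.0])
        gam = hvec - (hvec @ x) * bx - (hvec @ y) * by
        khg = 0.05 * G0 * Ve * (bx @ bx + by @ by)
        for i in range(4):
            F_ref[n[i], 0] -= Ve * (bx[i] * sig[0] + by[i] * sig[2]) + hoop
            F_ref[n[i], 1] -= Ve * (by[i] * sig[1] + bx[i] * sig[2])
            F_ref[n[i], 0] -= khg * q_hg[e, 0] * gam[i]
            F_ref[n[i], 1] -= khg * q_hg[e, 1] * gam[i]
    np.testing.assert_allclose(F_visc, F_ref, rtol=1e-12, atol=1e-18)
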