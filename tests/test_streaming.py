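"""Second-order streaming: drift closed forms, scaling, superposition."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cochstream.flow import OscillatoryField, solve_oscillatory
from cochstream.geometry import build_geometry
from cochstream.membrane import Tone
from cochstream.staggered import MembraneBC, StokesSystem
from cochstream.streaming import (
    advective_product,
    boundary_slip,
    reynolds_forcing,
    solve_streaming_single,
    stokes_drift,
    superpose,
)


def _synthetic_field(geom, fluid, omega, u_fn, v_fn):
    """OscillatoryField from closed-form complex amplitudes."""
    Xu, Yu = np.meshgrid(geom.x_edges, geom.yc, indexing="ij")
    Xv, Yv = np.meshgrid(geom.xc, geom.y_edges, indexing="ij")
    bc = MembraneBC.zeros(geom)
    bc.v_above = v_fn(geom.xc, 0.0 * geom.xc)
    bc.v_below = bc.v_above.copy()
    bc.u_above = u_fn(geom.x_edges, 0.0 * geom.x_edges)
    bc.u_below = bc.u_above.copy()
    return OscillatoryField(geom=geom, fluid=fluid, omega=omega,
                            u=u_fn(Xu, Yu), v=v_fn(Xv, Yv),
                            p=np.zeros((geom.nx, geom.ny), complex), bc=bc)


@pytest.fixture(scope="module")
def flat_geom():
    return build_geometry(L=4e-3, h=0.5e-3, helicotrema_len=0.5e-3,
                          dx_coarse=20e-6, dy_min=10e-6, dy_growth=1.15)


def _brute_force_drift(u_of_xt, omega, x0, cycles=200):
    """Mean drift of a particle in a 1-D oscillatory velocity field."""
    T = 2 * np.pi / omega
    sol = solve_ivp(lambda t, x: [u_of_xt(x[0], t)], (0.0, cycles * T), [x0],
                    rtol=1e-10, atol=1e-14, max_step=T / 40)
    return (sol.y[0, -1] - x0) / (cycles * T)


class TestStokesDriftClosedForms:
    def test_progressive_wave(self, flat_geom, fluid):
        # u = U cos(omega t - k x): classical drift U^2 k / (2 omega),
        # verified independently by brute-force trajectory averaging
        om, U, k = 2 * np.pi * 150.0, 1e-3, 2 * np.pi / 1.0e-3
        fld = _synthetic_field(
            flat_geom, fluid, om,
            lambda X, Y: U * np.exp(-1j * k * X) + 0j,
            lambda X, Y: np.zeros_like(X, complex))
        u_sd, v_sd = stokes_drift(fld)
        expected = U**2 * k / (2 * om)
        interior = slice(5, -5)
        # central differences of e^{-ikx} carry a sin(k dx)/(k dx) factor
        np.testing.assert_allclose(u_sd[interior, :], expected, rtol=5e-3)
        np.testing.assert_allclose(v_sd, 0.0, atol=1e-12 * expected)

        bf = _brute_force_drift(
            lambda x, t: U * np.cos(om * t - k * x), om, 1.7e-3)
        # the drifting particle sees a Doppler-shifted period, leaving an
        # O(U k/omega) sampling remainder in the finite-window average
        assert bf == pytest.approx(expected, rel=5e-3)

    def test_standing_wave_has_zero_drift(self, flat_geom, fluid):
        om, U, k = 2 * np.pi * 150.0, 1e-3, 2 * np.pi / 1.0e-3
        fld = _synthetic_field(
            flat_geom, fluid, om,
            lambda X, Y: U * np.cos(k * X) + 0j,
            lambda X, Y: np.zeros_like(X, complex))
        u_sd, _ = stokes_drift(fld)
        scale = U**2 * k / (2 * om)
        assert np.abs(u_sd).max() < 1e-10 * scale

        bf = _brute_force_drift(
            lambda x, t: U * np.cos(k * x) * np.cos(om * t), om, 1.3e-3)
        assert abs(bf) < 1e-4 * scale

    def test_uniform_oscillation_has_zero_drift(self, flat_geom, fluid):
        om = 2 * np.pi * 150.0
        fld = _synthetic_field(
            flat_geom, fluid, om,
            lambda X, Y: 1e-3 * np.ones_like(X, complex),
            lambda X, Y: np.zeros_like(X, complex))
        u_sd, v_sd = stokes_drift(fld)
        assert np.abs(u_sd).max() == 0.0
        assert np.abs(v_sd).max() == 0.0

    def test_two_dimensional_decaying_wave(self, flat_geom, fluid):
        # divergence-free wave u = U e^{-ikx-ky}, v = -i u has analytic
        # drift (k U^2 / omega) e^{-2ky} in x and zero in y
        om, U, k = 2 * np.pi * 150.0, 1e-3, 2 * np.pi / 2.0e-3

        def uf(X, Y):
            return U * np.exp(-1j * k * X) * np.exp(-k * np.abs(Y))

        def vf(X, Y):
            return -1j * np.sign(Y + 1e-300) * uf(X, Y)

        fld = _synthetic_field(flat_geom, fluid, om, uf, vf)
        u_sd, _ = stokes_drift(fld)
        ys = flat_geom.yc
        expected = (k * U**2 / om) * np.exp(-2 * k * np.abs(ys))
        jm = flat_geom.j_mem
        # interior rows away from stencil-patched boundaries, below the
        # coarse stretched rows where (k dy)^2 truncation grows
        rows = (np.arange(len(ys)) > jm) & (ys < 0.2e-3)
        got = u_sd[10:-10][:, rows]
        np.testing.assert_allclose(
            got, np.broadcast_to(expected[rows], got.shape), rtol=0.04)


class TestReynoldsForcing:
    def test_uniform_field_gives_zero_forcing(self, flat_geom, fluid):
        fld = _synthetic_field(
            flat_geom, fluid, 2 * np.pi * 150.0,
            lambda X, Y: (1e-3 + 0.5e-3j) * np.ones_like(X, complex),
            lambda X, Y: np.zeros_like(X, complex))
        f_u, f_v = reynolds_forcing(fld)
        assert np.abs(f_u).max() < 1e-12
        assert np.abs(f_v).max() < 1e-12

    def test_decaying_wave_forcing_is_purely_drift(self, flat_geom, fluid):
        # for u = U e^{-ikx - ky}, v = -i u the quadratic advective product
        # (u* . grad) u is purely imaginary: it generates Stokes drift but
        # no mean Reynolds force (Re Q = 0 analytically)
        om, U, k = 2 * np.pi * 150.0, 1e-3, 2 * np.pi / 2.0e-3

        def uf(X, Y):
            return U * np.exp(-1j * k * X) * np.exp(-k * np.abs(Y))

        def vf(X, Y):
            return -1j * np.sign(Y + 1e-300) * uf(X, Y)

        fld = _synthetic_field(flat_geom, fluid, om, uf, vf)
        Qu, Qv = advective_product(fld)
        jm = flat_geom.j_mem
        box = (slice(10, -10), slice(jm + 1, -2))
        scale = np.abs(Qu[box].imag).max()
        assert scale > 0
        assert np.abs(Qu[box].real).max() < 0.01 * scale


class TestStreamingSolve:
    def test_zero_input_zero_streaming(self, flat_geom, fluid):
        system = StokesSystem(flat_geom, fluid)
        fld = solve_oscillatory(system, bc=MembraneBC.zeros(flat_geom),
                                omega=2 * np.pi * 150.0,
                                check_resolution=False)
        st = solve_streaming_single(system, fld)
        assert st.max_speed() == 0.0

    def test_quadratic_scaling_is_exact(self, packet_setup, fluid):
        system, bc, om = (packet_setup["system"], packet_setup["bc"],
                          packet_setup["omega"])
        geom = packet_setup["geom"]
        f1 = solve_oscillatory(system, bc=bc, omega=om, check_resolution=False)
        bc300 = MembraneBC(300 * bc.v_above, 300 * bc.v_below,
                           300 * bc.u_above, 300 * bc.u_below)
        f300 = solve_oscillatory(system, bc=bc300, omega=om,
                                 check_resolution=False)
        s1 = solve_streaming_single(system, f1)
        s300 = solve_streaming_single(system, f300)
        # the amplitude-scaling trick: compute at 300x the drive, divide by
        # 300^2, recover the original streaming to round-off
        np.testing.assert_allclose(s300.u_ss / 300**2, s1.u_ss,
                                   rtol=1e-9, atol=1e-9 * np.abs(s1.u_ss).max())
        np.testing.assert_allclose(s300.v_euler / 300**2, s1.v_euler,
                                   rtol=1e-9, atol=1e-9 * np.abs(s1.v_euler).max())

    def test_multi_frequency_additivity(self, packet_setup, fluid):
        # distinct frequencies do not beat into the mean: the comb field is
        # exactly the sum of the single-tone fields
        system, bc = packet_setup["system"], packet_setup["bc"]
        geom = packet_setup["geom"]
        toneA = Tone(150.0, 80.0)
        toneB = Tone(240.0, 80.0)
        sts = []
        for tone in (toneA, toneB):
            fld = solve_oscillatory(system, bc=bc, omega=tone.omega,
                                    check_resolution=False)
            fld.tone = tone
            sts.append(solve_streaming_single(system, fld))
        total = superpose(sts)
        np.testing.assert_allclose(total.u_ss, sts[0].u_ss + sts[1].u_ss,
                                   rtol=1e-12)
        assert [t.f for t in total.tones] == [150.0, 240.0]

    def test_superpose_refuses_duplicate_frequencies(self, packet_setup):
        system, bc = packet_setup["system"], packet_setup["bc"]
        fld = solve_oscillatory(system, bc=bc, omega=2 * np.pi * 150.0,
                                check_resolution=False)
        fld.tone = Tone(150.0, 80.0)
        st = solve_streaming_single(system, fld)
        with pytest.raises(ValueError, match="duplicate"):
            superpose([st, st])

    def test_superpose_permutation_invariance(self, packet_setup):
        system, bc = packet_setup["system"], packet_setup["bc"]
        sts = []
        for f in (150.0, 240.0, 330.0):
            fld = solve_oscillatory(system, bc=bc, omega=2 * np.pi * f,
                                    check_resolution=False)
            fld.tone = Tone(f, 80.0)
            sts.append(solve_streaming_single(system, fld))
        a = superpose(sts)
        b = superpose(sts[::-1])
        np.testing.assert_allclose(a.u_ss, b.u_ss, rtol=1e-12,
                                   atol=1e-15 * np.abs(a.u_ss).max())


class TestBoundarySlip:
    def test_zero_membrane_velocity_zero_slip(self, flat_geom, fluid):
        system = StokesSystem(flat_geom, fluid)
        fld = solve_oscillatory(system, bc=MembraneBC.zeros(flat_geom),
                                omega=2 * np.pi * 150.0,
                                check_resolution=False)
        slip = boundary_slip(fld)
        assert np.abs(slip.u_above).max() == 0.0
        assert np.abs(slip.v_above).max() == 0.0

    def test_rigid_vertical_oscillation_gives_no_tangential_slip(
            self, flat_geom, fluid):
        # u independent of y near the wall: <(xi d_y) u> = 0
        om = 2 * np.pi * 150.0
        fld = _synthetic_field(
            flat_geom, fluid, om,
            lambda X, Y: np.zeros_like(X, complex),
            lambda X, Y: 1e-4 * np.ones_like(X, complex))
        slip = boundary_slip(fld)
        assert np.abs(slip.u_above).max() < 1e-20

    def test_slip_scales_quadratically(self, packet_setup):
        system, bc, om = (packet_setup["system"], packet_setup["bc"],
                          packet_setup["omega"])
        f1 = solve_oscillatory(system, bc=bc, omega=om, check_resolution=False)
        bc2 = MembraneBC(2 * bc.v_above, 2 * bc.v_below,
                         2 * bc.u_above, 2 * bc.u_below)
        f2 = solve_oscillatory(system, bc=bc2, omega=om,
                               check_resolution=False)
        s1, s2 = boundary_slip(f1), boundary_slip(f2)
        np.testing.assert_allclose(s2.u_above, 4 * s1.u_above, rtol=1e-12)
        np.testing.assert_allclose(s2.v_below, 4 * s1.v_below, rtol=1e-12)

    def test_lagrangian_mean_vanishes_on_the_membrane(self, packet_setup):
        # material particles on the oscillating membrane have no mean
        # tangential motion: slip and Stokes drift must cancel at y -> 0
        system, bc, om = (packet_setup["system"], packet_setup["bc"],
                          packet_setup["omega"])
        geom = packet_setup["geom"]
        fld = solve_oscillatory(system, bc=bc, omega=om, check_resolution=False)
        st = solve_streaming_single(system, fld, include_slip=True)
        u_sd, _ = stokes_drift(fld)
        me = geom.mem_edge
        scale = np.abs(st.slip.u_above[me]).max()
        resid = st.slip.u_above[me] + u_sd[me, geom.j_mem]
        # the drift one row off the wall is not exactly the wall limit;
        # cancellation holds to the stencil's truncation level
        assert np.abs(resid).max() < 0.35 * scale
        assert scale > 0


class TestPureToneVortexStructure:
    def test_counter_rotating_vortex_pair(self, tone_run):
        # one vortex per chamber at the wave peak: near-membrane flow is
        # apex-ward, far-field flow base-ward, mirrored across the membrane
        st = tone_run.streaming
        geom = tone_run.geom
        xpk = tone_run.wkbs[0].peak_place()
        span = (geom.x_edges > xpk - 0.7e-3) & (geom.x_edges < xpk + 0.1e-3)
        yc = geom.yc
        near_hi = (yc > 5e-6) & (yc < 40e-6)
        far_hi = (yc > 0.3 * geom.h) & (yc < 0.9 * geom.h)
        near_lo = (yc < -5e-6) & (yc > -40e-6)
        far_lo = (yc < -0.3 * geom.h) & (yc > -0.9 * geom.h)
        assert st.u_ss[np.ix_(span, near_hi)].mean() > 0   # apex-ward jet
        assert st.u_ss[np.ix_(span, far_hi)].mean() < 0    # base-ward return
        assert st.u_ss[np.ix_(span, near_lo)].mean() > 0
        assert st.u_ss[np.ix_(span, far_lo)].mean() < 0

        # vertical mean flow converges towards the membrane basal of the
        # peak (fluid is drawn in) in both chambers
        basal = (geom.xc > xpk - 1.2e-3) & (geom.xc < xpk - 0.4e-3)
        ye = geom.y_edges
        mid_hi = (ye > 0.1 * geom.h) & (ye < 0.5 * geom.h)
        mid_lo = (ye < -0.1 * geom.h) & (ye > -0.5 * geom.h)
        assert st.v_ss[np.ix_(basal, mid_hi)].mean() < 0
        assert st.v_ss[np.ix_(basal, mid_lo)].mean() > 0

    def test_oscillatory_amplitude_peaks_at_place(self, tone_run):
        fld = tone_run.oscillatory[0]
        geom = tone_run.geom
        speed = fld.speed_at_centers()
        xmax = geom.xc[int(np.argmax(speed.max(axis=1)))]
        assert abs(xmax - tone_run.wkbs[0].peak_place()) < 0.5e-3

    def test_streaming_profile_extent_grows_with_level(self, level_runs):
        # the vertical reach of the streaming at the characteristic place
        # follows the wave's penetration depth 1/|k_peak| ~ sqrt(xi): a
        # louder stimulus (larger calibrated drag) drives a broader,
        # deeper-reaching near-membrane jet.  Compared between 60 and
        # 80 dB, where the vortex orientation is the same; at 100 dB the
        # mean-flux recirculation around the membrane tip reverses the
        # local profile (see the methods note).
        extent, lane = {}, {}
        for spl in (60.0, 80.0):
            run = level_runs[spl]
            xpk = run.wkbs[0].peak_place()
            yc, up, _, _ = run.streaming.profile_at(xpk)
            sel = yc > 0
            w = np.abs(up[sel])
            extent[spl] = float(yc[sel][w > 0.2 * w.max()].max())
            lane[spl] = float(yc[sel][np.argmax(up[sel])])
        assert extent[60.0] < extent[80.0]
        assert lane[60.0] < lane[80.0]
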