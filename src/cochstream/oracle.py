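"""Time-domain oracle: a small, slow, independent Navier-Stokes solver.

This mirrors the reference methodology (incompressible solver, implicit
Euler time integration, ten or more timesteps per cycle, Courant number
kept well below one) at desk scale: semi-implicit time stepping (implicit
viscosity, explicit advection) with an incremental pressure projection on
the same staggered grid family as the main solvers, a *fixed* flat membrane
with transpiration forcing, and passive tracers whose per-cycle mean drift
estimates the Lagrangian mean flow.

It exists only to validate the frequency-domain perturbative pipeline
(Eulerian streaming from Reynolds stresses + Stokes drift); because its
membrane does not move, the moving-boundary slip term of the main pipeline
is deliberately absent here, and comparisons are made against streaming
fields computed with ``include_slip=False``.  It is never used for
headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import differential as dfl
from .geometry import CochleaGeometry, FluidProperties
from .staggered import MembraneBC, StaggeredOperators

__all__ = ["SolverSettings", "OracleResult", "TimeDomainSolver", "run_oracle"]


@dataclass(frozen=True)
class SolverSettings:
    """Time-stepping settings for the oracle."""

    steps_per_cycle: int = 32     # of the highest frequency; >= 10
    n_cycles: int = 120           # total cycles of the fundamental
    transient_cycles: int = 60    # cycles discarded before drift averaging
    courant_cap: float = 0.9      # refuse if u_max dt / dx_min exceeds this

    def __post_init__(self) -> None:
        if self.steps_per_cycle < 10:
            raise ValueError("need >= 10 timesteps per cycle of the highest frequency")
        if not (0 < self.courant_cap < 1):
            raise ValueError("Courant cap must lie in (0, 1)")
        if self.transient_cycles >= self.n_cycles:
            raise ValueError("transient must be shorter than the run")


class _Bilinear:
    """Fast vectorised bilinear interpolation on a rectilinear grid."""

    def __init__(self, xg, yg):
        self.xg, self.yg = xg, yg

    def __call__(self, F, pts):
        xg, yg = self.xg, self.yg
        i = np.clip(np.searchsorted(xg, pts[:, 0]) - 1, 0, len(xg) - 2)
        j = np.clip(np.searchsorted(yg, pts[:, 1]) - 1, 0, len(yg) - 2)
        tx = np.clip((pts[:, 0] - xg[i]) / (xg[i + 1] - xg[i]), 0.0, 1.0)
        ty = np.clip((pts[:, 1] - yg[j]) / (yg[j + 1] - yg[j]), 0.0, 1.0)
        return ((1 - tx) * (1 - ty) * F[i, j] + tx * (1 - ty) * F[i + 1, j]
                + (1 - tx) * ty * F[i, j + 1] + tx * ty * F[i + 1, j + 1])


class TimeDomainSolver:
    """Semi-implicit incompressible solver on the two-chamber MAC grid."""

    def __init__(self, geom: CochleaGeometry, fluid: FluidProperties,
                 dt: float, courant_cap: float = 0.9):
        self.geom, self.fluid, self.dt = geom, fluid, dt
        self.courant_cap = courant_cap
        self.ops = op = StaggeredOperators(geom)
        mu, rho = fluid.mu, fluid.rho0
        nu = fluid.nu
        Iu = sp.identity(op.nu, format="csr")
        Iv = sp.identity(op.nv, format="csr")
        self._lu_u = splu((Iu - dt * nu * op.Lu).tocsc())
        self._lu_v = splu((Iv - dt * nu * op.Lv).tocsc())
        # pressure Poisson operator of the projection: D (dt/rho) G
        Lp = (op.Du @ op.Gx + op.Dv @ op.Gy) * (dt / rho)
        Lp = Lp.tolil()
        Lp.rows[op.pin_cell] = [op.pin_cell]
        Lp.data[op.pin_cell] = [1.0]
        self._lu_p = splu(Lp.tocsc())
        self._dx_min = float(min(np.diff(geom.x_edges).min(),
                                 np.diff(geom.y_edges).min()))
        # interpolators for tracer advection
        jm = geom.j_mem
        self._iu_up = _Bilinear(geom.x_edges, np.concatenate([[0.0], geom.yc[jm:]]))
        self._iu_lo = _Bilinear(geom.x_edges, np.concatenate([geom.yc[:jm], [0.0]]))
        self._iv_up = _Bilinear(geom.xc, geom.y_edges[jm:])
        self._iv_lo = _Bilinear(geom.xc, geom.y_edges[: jm + 1])

    def step(self, u, v, bc_new: MembraneBC, bc_old: MembraneBC):
        """Advance one timestep; returns full-grid (u, v, p)."""
        geom, op, dt = self.geom, self.ops, self.dt
        nu_visc, rho = self.fluid.nu, self.fluid.rho0
        umax = max(np.abs(u).max(), np.abs(v).max(), 1e-300)
        if umax * dt / self._dx_min > self.courant_cap:
            raise RuntimeError(
                f"Courant number {umax * dt / self._dx_min:.2f} exceeds cap "
                f"{self.courant_cap}"
            )
        # explicit advection at time n
        conv_u = (u * dfl.du_dx(geom, u)
                  + dfl.v_at_u(geom, v) * dfl.du_dy(geom, u, bc_old))
        conv_v = (dfl.u_at_v(geom, u) * dfl.dv_dx(geom, v)
                  + v * dfl.dv_dy(geom, v, bc_old))
        rhs_u = (op.u_vec(u) - dt * op.u_vec(conv_u)
                 + dt * nu_visc * (op.BuA @ bc_new.u_above + op.BuB @ bc_new.u_below))
        rhs_v = (op.v_vec(v) - dt * op.v_vec(conv_v)
                 + dt * nu_visc * (op.BvA @ bc_new.v_above + op.BvB @ bc_new.v_below))
        us = self._lu_u.solve(rhs_u)
        vs = self._lu_v.solve(rhs_v)
        # projection onto the divergence-free space
        div = (op.Du @ us + op.Dv @ vs
               + op.TvA @ bc_new.v_above + op.TvB @ bc_new.v_below)
        div[op.pin_cell] = 0.0
        phi = self._lu_p.solve(div)
        us = us - (self.dt / rho) * (op.Gx @ phi)
        vs = vs - (self.dt / rho) * (op.Gy @ phi)
        return (op.u_grid(us), op.v_grid(vs, bc_new),
                phi.reshape(geom.nx, geom.ny) / dt)

    def velocity_at(self, u, v, bc: MembraneBC, pts: np.ndarray) -> np.ndarray:
        """Instantaneous velocity at points, chamber-aware bilinear interp."""
        geom, jm = self.geom, self.geom.j_mem
        out = np.empty_like(pts)
        up = pts[:, 1] >= 0.0
        row_a = np.where(geom.mem_edge, bc.u_above.real, u[:, jm])
        row_b = np.where(geom.mem_edge, bc.u_below.real, u[:, jm - 1])
        U_up = np.hstack([row_a[:, None], u[:, jm:]])
        U_lo = np.hstack([u[:, :jm], row_b[:, None]])
        V_up = np.hstack(
            [np.where(geom.mem_cell, bc.v_above.real, v[:, jm])[:, None],
             v[:, jm + 1:]])
        V_lo = np.hstack(
            [v[:, :jm],
             np.where(geom.mem_cell, bc.v_below.real, v[:, jm])[:, None]])
        if np.any(up):
            out[up, 0] = self._iu_up(U_up, pts[up])
            out[up, 1] = self._iv_up(V_up, pts[up])
        if np.any(~up):
            out[~up, 0] = self._iu_lo(U_lo, pts[~up])
            out[~up, 1] = self._iv_lo(V_lo, pts[~up])
        return out


@dataclass
class OracleResult:
    """Per-cycle tracer positions and derived Lagrangian drift."""

    probes: np.ndarray            # (n, 2) initial positions
    cycle_positions: np.ndarray   # (n_cycles+1, n, 2) at cycle boundaries
    period: float                 # fundamental period (s)
    transient_cycles: int
    realized_courant: float

    @property
    def drift_velocity(self) -> np.ndarray:
        """Mean Lagrangian drift velocity (n, 2) after the transient (m/s)."""
        pos = self.cycle_positions[self.transient_cycles:]
        n_cyc = pos.shape[0] - 1
        return (pos[-1] - pos[0]) / (n_cyc * self.period)

    def drift_series(self) -> np.ndarray:
        """Per-cycle drift velocities (n_cycles, n, 2) (m/s)."""
        return np.diff(self.cycle_positions, axis=0) / self.period


def run_oracle(
    geom: CochleaGeometry,
    fluid: FluidProperties,
    tones: list[tuple[float, np.ndarray]],
    settings: SolverSettings,
    probes: np.ndarray,
) -> OracleResult:
    """Integrate the time-dependent flow and track passive tracers.

    ``tones`` is a list of ``(omega, V_hat_at_cell_centres)``; the membrane
    velocity is ``V(x, t) = sum_j Re[V_hat_j exp(i omega_j t)]``.  Tracers
    are advanced with RK4 inside each flow step (field interpolated
    linearly in time), and sampled at cycle boundaries of the fundamental
    (lowest) frequency; the drift after the transient estimates the
    Lagrangian mean velocity at the probes.
    """
    omegas = np.array([w for w, _ in tones])
    om_max, om_min = float(omegas.max()), float(omegas.min())
    dt = 2 * np.pi / om_max / settings.steps_per_cycle
    period = 2 * np.pi / om_min
    steps_per_period = int(round(period / dt))
    dt = period / steps_per_period          # commensurate with the period

    solver = TimeDomainSolver(geom, fluid, dt, settings.courant_cap)

    def bc_at(t: float) -> MembraneBC:
        V = np.zeros(geom.nx)
        for (om, Vh) in tones:
            V += np.real(Vh * np.exp(1j * om * t))
        bc = MembraneBC.zeros(geom, dtype=float)
        bc.v_above = np.where(geom.mem_cell, V, 0.0)
        bc.v_below = bc.v_above.copy()
        return bc

    u = np.zeros((geom.nx + 1, geom.ny))
    v = np.zeros((geom.nx, geom.ny + 1))
    pts = np.array(probes, float).copy()
    cyc_pos = [pts.copy()]
    bc_old = bc_at(0.0)
    cmax = 0.0
    t = 0.0
    for n in range(settings.n_cycles * steps_per_period):
        bc_new = bc_at(t + dt)
        u_new, v_new, _ = solver.step(u, v, bc_new, bc_old)
        umax = max(np.abs(u_new).max(), np.abs(v_new).max())
        cmax = max(cmax, umax * dt / solver._dx_min)

        # RK4 tracer step with the field linear in time over [t, t+dt]
        def vel(tau, q):
            w = tau / dt
            uu = (1 - w) * u + w * u_new
            vv = (1 - w) * v + w * v_new
            bb = bc_old if w < 0.5 else bc_new
            return solver.velocity_at(uu, vv, bb, q)

        k1 = vel(0.0, pts)
        k2 = vel(dt / 2, pts + dt / 2 * k1)
        k3 = vel(dt / 2, pts + dt / 2 * k2)
        k4 = vel(dt, pts + dt * k3)
        pts = pts + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        u, v, bc_old = u_new, v_new, bc_new
        t += dt
        if (n + 1) % steps_per_period == 0:
            cyc_pos.append(pts.copy())

    return OracleResult(
        probes=np.array(probes, float),
        cycle_positions=np.array(cyc_pos),
        period=period,
        transient_cycles=settings.transient_cycles,
        realized_courant=cmax,
    )
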