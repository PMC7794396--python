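"""Second-order time-averaged (steady streaming) flow.

The oscillatory field ``u1 = Re[u_hat e^{i omega t}]`` forces a steady
secondary flow through three second-order ingredients:

* the Reynolds-stress body force ``F = -rho0 <(u1 . grad) u1>``,
* a steady boundary slip on the membrane faces from Taylor-expanding the
  no-slip condition on the *moving* membrane about its mean line, and
* the Stokes drift ``u_sd = <(xi . grad) u1>`` (``xi`` the fluid-particle
  excursion), which converts the Eulerian mean into the Lagrangian mean
  actually transporting particles.

With the peak-amplitude convention ``<a b> = Re[a_hat conj(b_hat)]/2``, all
three reduce to the single quadratic form ``Q = (conj(u_hat) . grad) u_hat``:
``F = -(rho0/2) Re Q`` and ``u_sd = -Im Q / (2 omega)``.  The steady problem
itself is linear Stokes flow (streaming Reynolds number << 1 at nm/s-um/s
streaming speeds), so streaming fields of distinct frequencies superpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import differential as dfl
from .flow import OscillatoryField
from .geometry import CochleaGeometry, FluidProperties
from .membrane import Tone
from .staggered import MembraneBC, StokesSystem

__all__ = [
    "StreamingField", "advective_product", "reynolds_forcing", "stokes_drift",
    "boundary_slip", "solve_streaming_single", "superpose",
]


def advective_product(field: OscillatoryField):
    """``Q = (conj(u_hat) . grad) u_hat`` on the staggered nodes.

    Returns ``(Q_u, Q_v)`` at u- and v-nodes respectively.
    """
    geom, bc = field.geom, field.bc
    u, v = field.u, field.v
    Qu = (np.conj(u) * dfl.du_dx(geom, u)
          + np.conj(dfl.v_at_u(geom, v)) * dfl.du_dy(geom, u, bc))
    Qv = (np.conj(dfl.u_at_v(geom, u)) * dfl.dv_dx(geom, v)
          + np.conj(v) * dfl.dv_dy(geom, v, bc))
    return Qu, Qv


def reynolds_forcing(field: OscillatoryField):
    """Mean Reynolds-stress body force ``-rho0 <(u1.grad)u1>`` (N/m^3)."""
    Qu, Qv = advective_product(field)
    rho0 = field.fluid.rho0
    return -0.5 * rho0 * np.real(Qu), -0.5 * rho0 * np.real(Qv)


def stokes_drift(field: OscillatoryField, omega: float | None = None):
    """Stokes drift ``<(xi.grad)u1>`` with ``xi_hat = u_hat/(i omega)`` (m/s).

    The sign convention is fixed by the progressive-wave limit: a wave
    ``u = U cos(omega t - k x)`` must drift forward at ``U^2 k / (2 omega)``.
    """
    if omega is None:
        omega = field.omega
    Qu, Qv = advective_product(field)
    return -np.imag(Qu) / (2 * omega), -np.imag(Qv) / (2 * omega)


def boundary_slip(field: OscillatoryField) -> MembraneBC:
    """Steady slip velocity on the membrane faces (m/s).

    No slip holds on the *moving* membrane; expanding about the mean line
    gives the steady boundary value ``u_mean = -<(xi_bm . grad) u1>`` with
    ``xi_bm = V_hat/(i omega)`` the vertical membrane excursion.  Evaluated
    one-sided on each chamber's face with second-order stencils.
    """
    geom, bc, om = field.geom, field.bc, field.omega
    slip = MembraneBC.zeros(geom, dtype=float)

    xi_c_a = bc.v_above / (1j * om)          # membrane excursion at centres
    xi_c_b = bc.v_below / (1j * om)
    # excursion at x-edges for the u-slip
    xi_e_a = np.interp(geom.x_edges, geom.xc, xi_c_a.real) + 1j * np.interp(
        geom.x_edges, geom.xc, xi_c_a.imag)
    xi_e_b = np.interp(geom.x_edges, geom.xc, xi_c_b.real) + 1j * np.interp(
        geom.x_edges, geom.xc, xi_c_b.imag)

    dudy_a = dfl.normal_gradient_at_membrane(geom, field.u, bc.u_above, "above", "u")
    dudy_b = dfl.normal_gradient_at_membrane(geom, field.u, bc.u_below, "below", "u")
    dvdy_a = dfl.normal_gradient_at_membrane(geom, field.v, bc.v_above, "above", "v")
    dvdy_b = dfl.normal_gradient_at_membrane(geom, field.v, bc.v_below, "below", "v")

    me, mc = geom.mem_edge, geom.mem_cell
    slip.u_above[me] = -0.5 * np.real(np.conj(xi_e_a[me]) * dudy_a[me])
    slip.u_below[me] = -0.5 * np.real(np.conj(xi_e_b[me]) * dudy_b[me])
    slip.v_above[mc] = -0.5 * np.real(np.conj(xi_c_a[mc]) * dvdy_a[mc])
    slip.v_below[mc] = -0.5 * np.real(np.conj(xi_c_b[mc]) * dvdy_b[mc])
    return slip


@dataclass
class StreamingField:
    """Eulerian mean, Stokes drift and Lagrangian mean on the 2-D grid.

    ``u``-components at x-edge nodes, ``v``-components at y-edge nodes.
    The Lagrangian mean ``u_ss = u_euler + u_sd`` is the transport velocity
    felt by tracers and is the primary observable.
    """

    geom: CochleaGeometry
    fluid: FluidProperties
    u_euler: np.ndarray
    v_euler: np.ndarray
    u_sd: np.ndarray
    v_sd: np.ndarray
    p_mean: np.ndarray
    slip: MembraneBC
    tones: list = dc_field(default_factory=list)

    @property
    def u_ss(self) -> np.ndarray:
        return self.u_euler + self.u_sd

    @property
    def v_ss(self) -> np.ndarray:
        return self.v_euler + self.v_sd

    def speed_at_centers(self, component: str = "lagrangian") -> np.ndarray:
        """Streaming speed magnitude at cell centres (m/s)."""
        u, v = {
            "lagrangian": (self.u_ss, self.v_ss),
            "euler": (self.u_euler, self.v_euler),
            "drift": (self.u_sd, self.v_sd),
        }[component]
        geom = self.geom
        u_cc = 0.5 * (u[:-1] + u[1:])
        ye, yc = geom.y_edges, geom.yc
        wy = (ye[1:] - yc) / (ye[1:] - ye[:-1])
        v_cc = v[:, :-1] * wy + v[:, 1:] * (1.0 - wy)
        return np.sqrt(u_cc**2 + v_cc**2)

    def max_speed(self, component: str = "lagrangian") -> float:
        return float(self.speed_at_centers(component).max())

    def profile_at(self, x: float):
        """Vertical profiles of (u_ss, v_ss) on the x-slice nearest ``x``.

        Returns ``(yc, u_ss(yc), ye, v_ss(ye))`` mirroring the published
        profile extraction at the characteristic place.
        """
        geom = self.geom
        ie = int(np.argmin(np.abs(geom.x_edges - x)))
        ic = int(np.argmin(np.abs(geom.xc - x)))
        return geom.yc, self.u_ss[ie, :], geom.y_edges, self.v_ss[ic, :]

    def interpolators(self, chamber: str):
        """(u, v) linear interpolators for one chamber, membrane-aware.

        The membrane line is a boundary row of each chamber so that no
        interpolation ever mixes the two chambers where they are separate.
        """
        geom = self.geom
        jm = geom.j_mem
        if chamber == "upper":
            yu = np.concatenate([[0.0], geom.yc[jm:]])
            row0 = np.where(geom.mem_edge, self.slip.u_above, self.u_ss[:, jm])
            U = np.vstack([row0, self.u_ss[:, jm:].T]).T
            yv = geom.y_edges[jm:]
            V = self.v_ss[:, jm:]
        elif chamber == "lower":
            yu = np.concatenate([geom.yc[:jm], [0.0]])
            row0 = np.where(geom.mem_edge, self.slip.u_below, self.u_ss[:, jm - 1])
            U = np.hstack([self.u_ss[:, :jm], row0[:, None]])
            yv = geom.y_edges[: jm + 1]
            V = self.v_ss[:, : jm + 1]
        else:
            raise ValueError("chamber must be 'upper' or 'lower'")
        ui = RegularGridInterpolator((geom.x_edges, yu), U,
                                     bounds_error=False, fill_value=None)
        vi = RegularGridInterpolator((geom.xc, yv), V,
                                     bounds_error=False, fill_value=None)
        return ui, vi

    def velocity(self, pts: np.ndarray) -> np.ndarray:
        """Lagrangian mean velocity at arbitrary points (n, 2) -> (n, 2)."""
        pts = np.atleast_2d(pts)
        out = np.zeros_like(pts, dtype=float)
        upper = pts[:, 1] >= 0.0
        for chamber, mask in (("upper", upper), ("lower", ~upper)):
            if not np.any(mask):
                continue
            ui, vi = self.interpolators(chamber)
            out[mask, 0] = ui(pts[mask])
            out[mask, 1] = vi(pts[mask])
        return out


def solve_streaming_single(
    system: StokesSystem,
    field: OscillatoryField,
    *,
    include_slip: bool = True,
) -> StreamingField:
    """Steady-streaming response to a single tone's oscillatory field.

    Solves ``0 = -grad p + mu lap u + F`` with the streaming slip as the
    membrane boundary value (``include_slip=False`` reproduces a rigid,
    non-moving transpiration boundary, as used when validating against the
    time-domain oracle which shares that approximation), then adds the
    Stokes drift to form the Lagrangian mean.
    """
    geom = system.geom
    Qu, Qv = advective_product(field)
    rho0 = system.fluid.rho0
    f_u = -0.5 * rho0 * np.real(Qu)
    f_v = -0.5 * rho0 * np.real(Qv)
    slip = boundary_slip(field) if include_slip else MembraneBC.zeros(geom, float)
    u_e, v_e, p_m = system.solve(0.0, slip, f_u=f_u, f_v=f_v)
    u_sd = -np.imag(Qu) / (2 * field.omega)
    v_sd = -np.imag(Qv) / (2 * field.omega)
    return StreamingField(
        geom=geom, fluid=system.fluid,
        u_euler=u_e, v_euler=v_e, u_sd=u_sd, v_sd=v_sd, p_mean=p_m,
        slip=slip, tones=[field.tone] if field.tone is not None else [],
    )


def superpose(fields: list[StreamingField]) -> StreamingField:
    """Sum of single-tone streaming fields (distinct frequencies only).

    Cross-frequency products time-average to zero, so the mean flow of a
    multi-tone stimulus is exactly the sum of its single-tone mean flows.
    Duplicate frequencies are refused (their cross terms would not vanish).
    """
    if not fields:
        raise ValueError("no fields to superpose")
    base = fields[0]
    freqs = []
    for f in fields:
        if not np.allclose(f.geom.x_edges, base.geom.x_edges) or not np.allclose(
            f.geom.y_edges, base.geom.y_edges
        ):
            raise ValueError("streaming fields live on different grids")
        freqs.extend(t.f for t in f.tones)
    if len(set(freqs)) != len(freqs):
        raise ValueError("duplicate tone frequencies in superposition")
    slip = MembraneBC.zeros(base.geom, float)
    for f in fields:
        slip.v_above = slip.v_above + f.slip.v_above
        slip.v_below = slip.v_below + f.slip.v_below
        slip.u_above = slip.u_above + f.slip.u_above
        slip.u_below = slip.u_below + f.slip.u_below
    return StreamingField(
        geom=base.geom, fluid=base.fluid,
        u_euler=sum(f.u_euler for f in fields),
        v_euler=sum(f.v_euler for f in fields),
        u_sd=sum(f.u_sd for f in fields),
        v_sd=sum(f.v_sd for f in fields),
        p_mean=sum(f.p_mean for f in fields),
        slip=slip,
        tones=[t for f in fields for t in f.tones],
    )
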