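"""First-order oscillatory Stokes flow in the two-chamber domain.

At the low Reynolds numbers of sound-evoked cochlear flow the first-order
field is a single harmonic: ``u(x, y, t) = Re[u_hat(x, y) exp(i omega t)]``.
The membrane enters as a transpiration boundary condition on the flattened
membrane line (displacements are nm-um against a 0.5 mm chamber height):
both chamber faces move vertically with the WKB membrane velocity, with no
slip tangentially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import differential as dfl
from .geometry import CochleaGeometry, FluidProperties
from .membrane import Tone, WKBSolution
from .staggered import MembraneBC, StokesSystem

__all__ = ["OscillatoryField", "solve_oscillatory", "flux_audit", "energy_balance"]


@dataclass
class OscillatoryField:
    """Complex velocity/pressure amplitudes of one tone on the 2-D grid."""

    geom: CochleaGeometry
    fluid: FluidProperties
    omega: float
    u: np.ndarray          # (nx+1, ny) complex, at x-edges
    v: np.ndarray          # (nx, ny+1) complex, at y-edges
    p: np.ndarray          # (nx, ny) complex, at centres
    bc: MembraneBC
    tone: Tone | None = None

    def speed_at_centers(self) -> np.ndarray:
        """|u_hat| magnitude sqrt(|u|^2 + |v|^2) at cell centres."""
        u_cc = 0.5 * (self.u[:-1] + self.u[1:])
        ye, yc = self.geom.y_edges, self.geom.yc
        wy = (ye[1:] - yc) / (ye[1:] - ye[:-1])
        v_cc = self.v[:, :-1] * wy + self.v[:, 1:] * (1.0 - wy)
        return np.sqrt(np.abs(u_cc) ** 2 + np.abs(v_cc) ** 2)


def solve_oscillatory(
    system: StokesSystem,
    wkb: WKBSolution | None = None,
    *,
    bc: MembraneBC | None = None,
    omega: float | None = None,
    check_resolution: bool = True,
) -> OscillatoryField:
    """Solve the unsteady Stokes problem for one tone.

    The driving boundary data either come from a WKB membrane solution
    (the usual case) or are supplied directly through ``bc`` (benchmarks).
    """
    geom, fluid = system.geom, system.fluid
    if wkb is not None:
        omega = wkb.tone.omega
        V_hat = wkb.interp_V(geom.xc)
        bc = MembraneBC.from_membrane_velocity(geom, V_hat)
    elif bc is None or omega is None:
        raise ValueError("provide either a WKBSolution or (bc, omega)")
    if check_resolution:
        geom.check_resolves(fluid, omega)
    u, v, p = system.solve(omega, bc)
    return OscillatoryField(geom=geom, fluid=fluid, omega=omega,
                            u=u, v=v, p=p, bc=bc,
                            tone=wkb.tone if wkb is not None else None)


def flux_audit(field: OscillatoryField) -> dict:
    """Volume-conservation audit per chamber.

    The complex flux pumped into each chamber through its membrane face
    must leave through the helicotrema plane at the membrane's apical end.
    Returns the two fluxes and their relative mismatch per chamber.
    """
    geom = field.geom
    dy = np.diff(geom.y_edges)
    dx = np.diff(geom.x_edges)
    jm = geom.j_mem
    ie = int(np.argmin(np.abs(geom.x_edges - geom.x_mem_end)))
    mc = geom.mem_cell

    mem_upper = np.sum(field.bc.v_above[mc] * dx[mc])
    mem_lower = np.sum(field.bc.v_below[mc] * dx[mc])
    plane_upper = np.sum(field.u[ie, jm:] * dy[jm:])
    plane_lower = np.sum(field.u[ie, :jm] * dy[:jm])

    def rel(a, b):
        scale = max(abs(a), abs(b), 1e-300)
        return abs(a - b) / scale

    return {
        "membrane_flux_upper": complex(mem_upper),
        "helicotrema_flux_upper": complex(plane_upper),
        "mismatch_upper": rel(mem_upper, plane_upper),
        "membrane_flux_lower": complex(-mem_lower),
        "helicotrema_flux_lower": complex(plane_lower),
        "mismatch_lower": rel(-mem_lower, plane_lower),
    }


def energy_balance(field: OscillatoryField) -> dict:
    """Time-averaged power input vs viscous dissipation (W per unit depth).

    Power enters through the normal traction on the moving membrane faces;
    in steady oscillation it must equal the volume-integrated mean viscous
    dissipation ``mu <2 e_ij e_ij>``.
    """
    geom, fluid = field.geom, field.fluid
    mu = fluid.mu
    dx, dy = np.diff(geom.x_edges), np.diff(geom.y_edges)
    jm, mc = geom.j_mem, geom.mem_cell
    yc = geom.yc

    # pressure extrapolated to the membrane faces (linear, one-sided)
    def p_face(side):
        if side == "above":
            p1, p2, y1, y2 = field.p[:, jm], field.p[:, jm + 1], yc[jm], yc[jm + 1]
        else:
            p1, p2, y1, y2 = field.p[:, jm - 1], field.p[:, jm - 2], yc[jm - 1], yc[jm - 2]
        return p1 + (p2 - p1) * (0.0 - y1) / (y2 - y1)

    dvdy_a = dfl.normal_gradient_at_membrane(geom, field.v, field.bc.v_above,
                                             "above", "v")
    dvdy_b = dfl.normal_gradient_at_membrane(geom, field.v, field.bc.v_below,
                                             "below", "v")
    # <power> = 1/2 Re[conj(V) * sigma_n], outward normal of each chamber
    sig_a = -p_face("above") + 2 * mu * dvdy_a
    sig_b = -p_face("below") + 2 * mu * dvdy_b
    power = 0.5 * np.sum(
        np.real(np.conj(field.bc.v_above[mc]) * (-sig_a[mc])) * dx[mc]
    ) + 0.5 * np.sum(
        np.real(np.conj(field.bc.v_below[mc]) * (sig_b[mc])) * dx[mc]
    )

    # dissipation mu * sum |ehat_ij|^2 at cell centres
    dudx = (field.u[1:] - field.u[:-1]) / dx[:, None]
    dvdy = (field.v[:, 1:] - field.v[:, :-1]) / dy[None, :]
    dudy = dfl.du_dy(geom, field.u, field.bc)
    dudy_cc = 0.5 * (dudy[:-1] + dudy[1:])
    dvdx = dfl.dv_dx(geom, field.v)
    ye = geom.y_edges
    wy = (ye[1:] - yc) / (ye[1:] - ye[:-1])
    dvdx_cc = dvdx[:, :-1] * wy + dvdx[:, 1:] * (1.0 - wy)
    e_xy = 0.5 * (dudy_cc + dvdx_cc)
    dens = mu * (np.abs(dudx) ** 2 + np.abs(dvdy) ** 2 + 2 * np.abs(e_xy) ** 2)
    dissipation = float(np.sum(dens * dx[:, None] * dy[None, :]))

    return {
        "power_in": float(power),
        "dissipation": dissipation,
        "rel_mismatch": abs(power - dissipation) / max(abs(power), abs(dissipation), 1e-300),
    }
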