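"""Gradients and staggered interpolation on the two-chamber MAC grid.

These helpers operate on full-grid arrays (boundary nodes included) and
patch the rows adjacent to walls and to the interior membrane line with
one-sided three-point stencils, so that no stencil ever differences across
the membrane where the two chambers are hydrodynamically separate.
"""

from __future__ import annotations

import numpy as np

from .geometry import CochleaGeometry
from .staggered import MembraneBC

__all__ = [
    "du_dx", "du_dy", "dv_dx", "dv_dy",
    "v_at_u", "u_at_v", "normal_gradient_at_membrane",
]


def _onesided(f0, f1, f2, y0, y1, y2):
    """d/dy at y0 from values at (y0, y1, y2) (Lagrange, 2nd order)."""
    c0 = (2 * y0 - y1 - y2) / ((y0 - y1) * (y0 - y2))
    c1 = (y0 - y2) / ((y1 - y0) * (y1 - y2))
    c2 = (y0 - y1) / ((y2 - y0) * (y2 - y1))
    return c0 * f0 + c1 * f1 + c2 * f2


def du_dx(geom: CochleaGeometry, u: np.ndarray) -> np.ndarray:
    """d u / d x at u-nodes (x-edges carry no interior boundary)."""
    return np.gradient(u, geom.x_edges, axis=0)


def du_dy(geom: CochleaGeometry, u: np.ndarray, bc: MembraneBC) -> np.ndarray:
    """d u / d y at u-nodes, one-sided at walls and membrane faces."""
    yc, h, jm = geom.yc, geom.h, geom.j_mem
    g = np.gradient(u, yc, axis=1)
    # walls (tangential value 0 at +-h)
    g[:, 0] = _onesided(0.0, u[:, 0], u[:, 1], -h, yc[0], yc[1])
    g[:, -1] = _onesided(0.0, u[:, -1], u[:, -2], h, yc[-1], yc[-2])
    # membrane rows, membrane-span edges only
    me = geom.mem_edge
    g[me, jm] = _onesided(bc.u_above[me], u[me, jm], u[me, jm + 1],
                          0.0, yc[jm], yc[jm + 1])
    g[me, jm - 1] = _onesided(bc.u_below[me], u[me, jm - 1], u[me, jm - 2],
                              0.0, yc[jm - 1], yc[jm - 2])
    return g


def dv_dx(geom: CochleaGeometry, v: np.ndarray) -> np.ndarray:
    """d v / d x at v-nodes, one-sided at the end walls (v = 0 there)."""
    xc, L = geom.xc, geom.L
    g = np.gradient(v, xc, axis=0)
    g[0] = _onesided(0.0, v[0], v[1], 0.0, xc[0], xc[1])
    g[-1] = _onesided(0.0, v[-1], v[-2], L, xc[-1], xc[-2])
    return g


def dv_dy(geom: CochleaGeometry, v: np.ndarray, bc: MembraneBC) -> np.ndarray:
    """d v / d y at v-nodes, split per chamber across the membrane."""
    ye, jm = geom.y_edges, geom.j_mem
    g = np.gradient(v, ye, axis=1)
    mc = geom.mem_cell
    # first faces above/below the membrane: difference towards the
    # chamber's own membrane value, never across
    g[mc, jm + 1] = _onesided(v[mc, jm + 1], bc.v_above[mc], v[mc, jm + 2],
                              ye[jm + 1], 0.0, ye[jm + 2])
    g[mc, jm - 1] = _onesided(v[mc, jm - 1], bc.v_below[mc], v[mc, jm - 2],
                              ye[jm - 1], 0.0, ye[jm - 2])
    # membrane face itself: one-sided from above (upper-chamber value)
    g[mc, jm] = _onesided(bc.v_above[mc], v[mc, jm + 1], v[mc, jm + 2],
                          0.0, ye[jm + 1], ye[jm + 2])
    return g


def v_at_u(geom: CochleaGeometry, v: np.ndarray) -> np.ndarray:
    """Interpolate v (on y-edges) to u-nodes (x-edges, cell centres in y)."""
    xc, xe, ye, yc = geom.xc, geom.x_edges, geom.y_edges, geom.yc
    # average to cell centres in y first
    wy = (ye[1:] - yc) / (ye[1:] - ye[:-1])
    v_cc = v[:, :-1] * wy + v[:, 1:] * (1.0 - wy)      # (nx, ny)
    out = np.empty((geom.nx + 1, geom.ny), dtype=v.dtype)
    out[1:-1] = 0.5 * (v_cc[:-1] + v_cc[1:])
    out[0] = v_cc[0]
    out[-1] = v_cc[-1]
    # linear-in-x weights for the (mildly) nonuniform grid
    w = (xc[1:] - xe[1:-1]) / (xc[1:] - xc[:-1])
    out[1:-1] = v_cc[:-1] * w[:, None] + v_cc[1:] * (1.0 - w[:, None])
    return out


def u_at_v(geom: CochleaGeometry, u: np.ndarray) -> np.ndarray:
    """Interpolate u (on x-edges) to v-nodes (cell centres in x, y-edges)."""
    yc, ye = geom.yc, geom.y_edges
    u_cc = 0.5 * (u[:-1] + u[1:])                      # (nx, ny) at centres
    out = np.empty((geom.nx, geom.ny + 1), dtype=u.dtype)
    w = (yc[1:] - ye[1:-1]) / (yc[1:] - yc[:-1])
    out[:, 1:-1] = u_cc[:, :-1] * w + u_cc[:, 1:] * (1.0 - w)
    out[:, 0] = 0.0       # wall
    out[:, -1] = 0.0      # wall
    jm = geom.j_mem
    # membrane faces: tangential fluid velocity vanishes there at first
    # order; helicotrema columns keep the interpolated value
    out[geom.mem_cell, jm] = 0.0
    return out


def normal_gradient_at_membrane(geom: CochleaGeometry, q: np.ndarray,
                                q_face, side: str, staggering: str):
    """One-sided d q / d y evaluated on the membrane line ``y = 0``.

    ``staggering`` is ``"u"`` (values at y cell-centres) or ``"v"``
    (values at y-edges); ``q_face`` is the boundary value on the face.
    Returns an array over the full x extent of the given staggering.
    """
    jm = geom.j_mem
    if staggering == "u":
        yc = geom.yc
        if side == "above":
            return _onesided(q_face, q[:, jm], q[:, jm + 1], 0.0, yc[jm], yc[jm + 1])
        return _onesided(q_face, q[:, jm - 1], q[:, jm - 2], 0.0, yc[jm - 1], yc[jm - 2])
    ye = geom.y_edges
    if side == "above":
        return _onesided(q_face, q[:, jm + 1], q[:, jm + 2], 0.0, ye[jm + 1], ye[jm + 2])
    return _onesided(q_face, q[:, jm - 1], q[:, jm - 2], 0.0, ye[jm - 1], ye[jm - 2])
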