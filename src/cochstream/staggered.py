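"""Staggered-grid (MAC) operators and direct Stokes solvers.

Velocity unknowns live on cell faces (``u`` on vertical faces, ``v`` on
horizontal faces), pressure at cell centres.  The basilar membrane is an
interior boundary on the ``y = 0`` face line: its normal velocity is
prescribed per side (the two chambers may see different values in the
second-order steady problem) and the tangential velocity on each face is a
prescribed boundary value (zero for the first-order flow, the steady
streaming slip for the mean flow).  All outer walls are no-slip.

One assembly serves three solvers: the frequency-domain oscillatory Stokes
problem ``i omega rho u = -grad p + rho nu lap u``, the forced steady
Stokes problem for the mean flow, and the time-stepping operators of the
time-domain oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import CochleaGeometry, FluidProperties

__all__ = ["MembraneBC", "StaggeredOperators", "StokesSystem"]


def _d2coeffs(hm: float, hp: float) -> tuple[float, float, float]:
    """3-point second-derivative coefficients (lower, centre, upper)."""
    s = hm + hp
    return 2.0 / (hm * s), -2.0 / (hm * hp), 2.0 / (hp * s)


@dataclass
class MembraneBC:
    """Velocity boundary data on the two membrane faces.

    ``v_above``/``v_below`` are the normal (vertical) velocities seen by the
    upper and lower chamber at cell centres; ``u_above``/``u_below`` the
    tangential values at x-edges.  Entries outside the membrane span are
    ignored.  For the first-order flow both normal values equal the membrane
    velocity and the tangential values vanish (no slip); for the steady
    problem they carry the streaming slip.
    """

    v_above: np.ndarray
    v_below: np.ndarray
    u_above: np.ndarray
    u_below: np.ndarray

    @classmethod
    def zeros(cls, geom: CochleaGeometry, dtype=complex) -> "MembraneBC":
        return cls(
            v_above=np.zeros(geom.nx, dtype),
            v_below=np.zeros(geom.nx, dtype),
            u_above=np.zeros(geom.nx + 1, dtype),
            u_below=np.zeros(geom.nx + 1, dtype),
        )

    @classmethod
    def from_membrane_velocity(cls, geom: CochleaGeometry, V_hat: np.ndarray
                               ) -> "MembraneBC":
        """No-slip transpiration: both faces move with the membrane."""
        bc = cls.zeros(geom, dtype=np.asarray(V_hat).dtype)
        bc.v_above = np.where(geom.mem_cell, V_hat, 0.0)
        bc.v_below = bc.v_above.copy()
        return bc


class StaggeredOperators:
    """Sparse MAC operators for one geometry (assembled once)."""

    def __init__(self, geom: CochleaGeometry):
        self.geom = geom
        nx, ny = geom.nx, geom.ny
        xe, ye = geom.x_edges, geom.y_edges
        xc, yc = geom.xc, geom.yc
        jm = geom.j_mem
        mem_cell, mem_edge = geom.mem_cell, geom.mem_edge
        dx = np.diff(xe)
        dy = np.diff(ye)

        # --- unknown numbering -------------------------------------------
        # u: interior x-edges (i = 1..nx-1), all rows; row-major (i, j)
        self.nu = (nx - 1) * ny

        def uix(i, j):
            return (i - 1) * ny + j

        # v: interior y-edges excluding membrane Dirichlet nodes
        v_unknown = np.zeros((nx, ny + 1), bool)
        v_unknown[:, 1:ny] = True
        v_unknown[mem_cell, jm] = False
        self.v_unknown = v_unknown
        vmap = -np.ones((nx, ny + 1), np.int64)
        vmap[v_unknown] = np.arange(np.count_nonzero(v_unknown))
        self.vmap = vmap
        self.nv = int(np.count_nonzero(v_unknown))
        self.np_ = nx * ny

        def pix(i, j):
            return i * ny + j

        self._uix, self._pix = uix, pix

        Lu = sp.lil_matrix((self.nu, self.nu))
        BuA = sp.lil_matrix((self.nu, nx + 1))
        BuB = sp.lil_matrix((self.nu, nx + 1))
        Gx = sp.lil_matrix((self.nu, self.np_))

        # --- u-momentum stencils -----------------------------------------
        for i in range(1, nx):
            for j in range(ny):
                r = uix(i, j)
                # x-part
                am, a0, ap = _d2coeffs(xe[i] - xe[i - 1], xe[i + 1] - xe[i])
                Lu[r, r] = Lu[r, r] + a0
                if i - 1 >= 1:
                    Lu[r, uix(i - 1, j)] += am
                if i + 1 <= nx - 1:
                    Lu[r, uix(i + 1, j)] += ap
                # y-part
                if j == 0:
                    hm = yc[0] + geom.h
                    lower = None          # wall, value 0
                elif j == jm and mem_edge[i]:
                    hm = yc[j]
                    lower = ("memA", i)
                else:
                    hm = yc[j] - yc[j - 1]
                    lower = ("u", uix(i, j - 1))
                if j == ny - 1:
                    hp = geom.h - yc[j]
                    upper = None
                elif j == jm - 1 and mem_edge[i]:
                    hp = -yc[j]
                    upper = ("memB", i)
                else:
                    hp = yc[j + 1] - yc[j]
                    upper = ("u", uix(i, j + 1))
                am, a0, ap = _d2coeffs(hm, hp)
                Lu[r, r] = Lu[r, r] + a0
                for coeff, nb in ((am, lower), (ap, upper)):
                    if nb is None:
                        continue
                    kind, idx = nb
                    if kind == "u":
                        Lu[r, idx] += coeff
                    elif kind == "memA":
                        BuA[r, idx] += coeff
                    else:
                        BuB[r, idx] += coeff
                # pressure gradient
                hx = xc[i] - xc[i - 1]
                Gx[r, pix(i, j)] += 1.0 / hx
                Gx[r, pix(i - 1, j)] -= 1.0 / hx

        Lv = sp.lil_matrix((self.nv, self.nv))
        BvA = sp.lil_matrix((self.nv, nx))
        BvB = sp.lil_matrix((self.nv, nx))
        Gy = sp.lil_matrix((self.nv, self.np_))

        # --- v-momentum stencils -----------------------------------------
        for i in range(nx):
            for j in range(1, ny):
                if not v_unknown[i, j]:
                    continue
                r = vmap[i, j]
                # y-part
                am, a0, ap = _d2coeffs(ye[j] - ye[j - 1], ye[j + 1] - ye[j])
                Lv[r, r] = Lv[r, r] + a0
                for coeff, jj in ((am, j - 1), (ap, j + 1)):
                    if jj in (0, ny):
                        continue  # wall, value 0
                    if vmap[i, jj] >= 0:
                        Lv[r, vmap[i, jj]] += coeff
                    else:  # membrane Dirichlet node
                        if jj > j:
                            BvB[r, i] += coeff   # approached from below
                        else:
                            BvA[r, i] += coeff   # approached from above
                # x-part
                if i == 0:
                    hm = xc[0]
                    left = None
                else:
                    hm = xc[i] - xc[i - 1]
                    left = i - 1
                if i == nx - 1:
                    hp = geom.L - xc[i]
                    right = None
                else:
                    hp = xc[i + 1] - xc[i]
                    right = i + 1
                am, a0, ap = _d2coeffs(hm, hp)
                Lv[r, r] = Lv[r, r] + a0
                for coeff, ii in ((am, left), (ap, right)):
                    if ii is None:
                        continue  # wall, value 0
                    if vmap[ii, j] >= 0:
                        Lv[r, vmap[ii, j]] += coeff
                    else:  # membrane node hit sideways (membrane tip)
                        BvA[r, ii] += 0.5 * coeff
                        BvB[r, ii] += 0.5 * coeff
                hy = yc[j] - yc[j - 1]
                Gy[r, pix(i, j)] += 1.0 / hy
                Gy[r, pix(i, j - 1)] -= 1.0 / hy

        # --- divergence ---------------------------------------------------
        Du = sp.lil_matrix((self.np_, self.nu))
        Dv = sp.lil_matrix((self.np_, self.nv))
        TvA = sp.lil_matrix((self.np_, nx))
        TvB = sp.lil_matrix((self.np_, nx))
        for i in range(nx):
            for j in range(ny):
                r = pix(i, j)
                if i + 1 <= nx - 1:
                    Du[r, uix(i + 1, j)] += 1.0 / dx[i]
                if i >= 1:
                    Du[r, uix(i, j)] -= 1.0 / dx[i]
                for sign, jj in ((1.0, j + 1), (-1.0, j)):
                    if jj in (0, ny):
                        continue
                    if vmap[i, jj] >= 0:
                        Dv[r, vmap[i, jj]] += sign / dy[j]
                    else:  # membrane face value
                        if jj == jm and j == jm:        # bottom face of upper cell
                            TvA[r, i] += sign / dy[j]
                        else:                            # top face of lower cell
                            TvB[r, i] += sign / dy[j]

        self.Lu, self.BuA, self.BuB, self.Gx = (m.tocsr() for m in (Lu, BuA, BuB, Gx))
        self.Lv, self.BvA, self.BvB, self.Gy = (m.tocsr() for m in (Lv, BvA, BvB, Gy))
        self.Du, self.Dv, self.TvA, self.TvB = (m.tocsr() for m in (Du, Dv, TvA, TvB))
        # pressure pinned in the most apical helicotrema cell
        self.pin_cell = pix(nx - 1, jm)

    # --- full-array <-> unknown-vector maps ------------------------------
    def u_vec(self, u_full: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(u_full[1:-1, :]).ravel()

    def v_vec(self, v_full: np.ndarray) -> np.ndarray:
        return v_full[self.v_unknown]

    def u_grid(self, vec: np.ndarray, bc: MembraneBC | None = None) -> np.ndarray:
        g = self.geom
        out = np.zeros((g.nx + 1, g.ny), dtype=vec.dtype)
        out[1:-1, :] = vec.reshape(g.nx - 1, g.ny)
        return out

    def v_grid(self, vec: np.ndarray, bc: MembraneBC | None = None) -> np.ndarray:
        g = self.geom
        out = np.zeros((g.nx, g.ny + 1), dtype=vec.dtype)
        out[self.v_unknown] = vec
        if bc is not None:
            mask = g.mem_cell
            out[mask, g.j_mem] = 0.5 * (bc.v_above[mask] + bc.v_below[mask])
        return out


class StokesSystem:
    """Direct (sparse LU) solver for oscillatory and steady Stokes flow."""

    def __init__(self, geom: CochleaGeometry, fluid: FluidProperties):
        self.geom = geom
        self.fluid = fluid
        self.ops = StaggeredOperators(geom)
        self._lu_cache: dict[float, object] = {}

    def _matrix(self, omega: float):
        op = self.ops
        rho, mu = self.fluid.rho0, self.fluid.mu
        dtype = complex if omega != 0.0 else float
        Iu = sp.identity(op.nu, dtype=dtype, format="csr")
        Iv = sp.identity(op.nv, dtype=dtype, format="csr")
        Au = (1j * omega * rho) * Iu - mu * op.Lu if omega else (-mu * op.Lu)
        Av = (1j * omega * rho) * Iv - mu * op.Lv if omega else (-mu * op.Lv)
        A = sp.bmat(
            [[Au, None, op.Gx], [None, Av, op.Gy], [op.Du, op.Dv, None]],
            format="csr", dtype=dtype,
        )
        # pin the pressure nullspace: replace one continuity row
        pin = op.nu + op.nv + op.pin_cell
        A = A.tolil()
        A.rows[pin] = [pin]
        A.data[pin] = [1.0]
        return A.tocsc()

    def _lu(self, omega: float):
        key = float(omega)
        if key not in self._lu_cache:
            self._lu_cache[key] = splu(self._matrix(omega))
        return self._lu_cache[key]

    def _rhs(self, bc: MembraneBC, f_u=None, f_v=None, dtype=complex):
        op, mu = self.ops, self.fluid.mu
        rhs = np.zeros(op.nu + op.nv + op.np_, dtype=dtype)
        rhs[: op.nu] = mu * (op.BuA @ bc.u_above + op.BuB @ bc.u_below)
        rhs[op.nu : op.nu + op.nv] = mu * (op.BvA @ bc.v_above + op.BvB @ bc.v_below)
        rhs[op.nu + op.nv :] = -(op.TvA @ bc.v_above + op.TvB @ bc.v_below)
        if f_u is not None:
            rhs[: op.nu] += op.u_vec(f_u)
        if f_v is not None:
            rhs[op.nu : op.nu + op.nv] += op.v_vec(f_v)
        rhs[op.nu + op.nv + op.pin_cell] = 0.0
        return rhs

    def solve(self, omega: float, bc: MembraneBC, f_u=None, f_v=None):
        """Solve one (oscillatory or steady) Stokes problem.

        Returns full-grid arrays ``(u, v, p)``; ``u`` is (nx+1, ny) on
        x-edges, ``v`` is (nx, ny+1) on y-edges (membrane faces filled with
        the mean of the two prescribed sides), ``p`` is (nx, ny).
        """
        op = self.ops
        dtype = complex if (omega != 0.0 or np.iscomplexobj(bc.v_above)) else float
        sol = self._lu(omega).solve(self._rhs(bc, f_u, f_v, dtype=dtype))
        u = op.u_grid(sol[: op.nu])
        v = op.v_grid(sol[op.nu : op.nu + op.nv], bc)
        p = sol[op.nu + op.nv :].reshape(self.geom.nx, self.geom.ny)
        return u, v, p

    def divergence_residual(self, u, v, bc: MembraneBC) -> float:
        """Max |div u| over cells, with membrane faces from ``bc`` (1/s)."""
        op = self.ops
        div = (op.Du @ op.u_vec(u) + op.Dv @ op.v_vec(v)
               + op.TvA @ bc.v_above + op.TvB @ bc.v_below)
        div[op.pin_cell] = 0.0
        return float(np.abs(div).max())
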