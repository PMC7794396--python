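"""Two-chamber cochlea geometry and structured staggered grid.

The domain is the rectangle ``[0, L] x [-h, h]``: two chambers of height
``h`` separated by the basilar membrane along ``y = 0`` for
``x < L - helicotrema_len``, and connected through the open helicotrema gap
at the apical end.  All outer boundaries are rigid walls.  The grid is a
rectilinear tensor mesh: the vertical spacing is geometrically stretched
away from the membrane so the oscillatory Stokes layer
``delta_nu = sqrt(2 nu / omega)`` is resolved, and the longitudinal spacing
follows the local wavelength of the membrane wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluidProperties", "CochleaGeometry", "build_geometry"]


@dataclass(frozen=True)
class FluidProperties:
    """Perilymph/endolymph, close to water."""

    rho0: float = 1000.0   # density (kg/m^3)
    nu: float = 1e-6       # kinematic viscosity (m^2/s)

    def __post_init__(self) -> None:
        if self.rho0 <= 0 or self.nu <= 0:
            raise ValueError("fluid density and viscosity must be positive")

    @property
    def mu(self) -> float:
        """Dynamic viscosity (Pa s)."""
        return self.rho0 * self.nu

    def stokes_layer(self, omega: float) -> float:
        """Oscillatory boundary-layer thickness sqrt(2 nu / omega) (m)."""
        return float(np.sqrt(2.0 * self.nu / omega))


def _graded_edges(length: float, target: np.ndarray, x_sample: np.ndarray,
                  growth: float = 1.2) -> np.ndarray:
    """Edges on [0, length] following a target spacing, with bounded grading.

    The sampled target spacing is smoothed so neighbouring cells never grow
    faster than ``growth`` per cell, then integrated into edges and rescaled
    to land exactly on ``length``.
    """
    t = target.copy()
    g = growth - 1.0
    # two-sweep grading limiter: |d(dx)/dx| <= g
    for i in range(1, len(t)):
        t[i] = min(t[i], t[i - 1] + g * (x_sample[i] - x_sample[i - 1]))
    for i in range(len(t) - 2, -1, -1):
        t[i] = min(t[i], t[i + 1] + g * (x_sample[i + 1] - x_sample[i]))
    edges = [0.0]
    while edges[-1] < length:
        dx = float(np.interp(edges[-1], x_sample, t))
        edges.append(edges[-1] + dx)
    e = np.array(edges)
    if len(e) < 3:
        e = np.linspace(0.0, length, 3)
    return e * (length / e[-1])


def _stretched_half(h: float, dy_min: float, growth: float,
                    dy_max: float, dy_wall: float | None = None) -> np.ndarray:
    """Edges from the membrane (0) to the outer wall (h).

    Spacing grows geometrically from ``dy_min`` at the membrane to
    ``dy_max`` in the bulk and, when ``dy_wall`` is given, shrinks back to
    ``dy_wall`` at the wall so the wall Stokes layer is resolved too.
    """
    if dy_wall is None:
        edges = [0.0]
        dy = dy_min
        while edges[-1] < h:
            edges.append(edges[-1] + dy)
            dy = min(dy * growth, dy_max)
        e = np.array(edges)
        return e * (h / e[-1])
    ys = np.linspace(0.0, h, 801)
    g = growth - 1.0
    target = np.minimum(dy_max,
                        np.minimum(dy_min + g * ys, dy_wall + g * (h - ys)))
    return _graded_edges(h, target, ys, growth)


@dataclass(frozen=True)
class CochleaGeometry:
    """Rectilinear staggered-grid geometry of the uncoiled cochlea."""

    L: float                 # domain length (m)
    h: float                 # height of each chamber (m)
    helicotrema_len: float   # apical gap with no membrane (m)
    x_edges: np.ndarray      # (Nx+1,) ascending, 0..L, contains x_mem_end
    y_edges: np.ndarray      # (Ny+1,) ascending, -h..h, contains 0

    def __post_init__(self) -> None:
        if not (self.L > self.helicotrema_len > 0):
            raise ValueError("need L > helicotrema_len > 0 (chambers must connect)")
        if self.h <= 0:
            raise ValueError("chamber height must be positive")
        xe, ye = self.x_edges, self.y_edges
        if xe[0] != 0.0 or abs(xe[-1] - self.L) > 1e-12 * self.L:
            raise ValueError("x_edges must span [0, L]")
        if abs(ye[0] + self.h) > 1e-12 * self.h or abs(ye[-1] - self.h) > 1e-12 * self.h:
            raise ValueError("y_edges must span [-h, h]")
        if not np.any(np.abs(ye) < 1e-15):
            raise ValueError("y_edges must contain the membrane line y = 0")
        if not np.any(np.abs(xe - self.x_mem_end) < 1e-12 * self.L):
            raise ValueError("x_edges must contain the membrane end x = L - helicotrema_len")

    @property
    def x_mem_end(self) -> float:
        """Apical end of the membrane (m)."""
        return self.L - self.helicotrema_len

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.x_edges[1:] + self.x_edges[:-1])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.y_edges[1:] + self.y_edges[:-1])

    @property
    def nx(self) -> int:
        return len(self.x_edges) - 1

    @property
    def ny(self) -> int:
        return len(self.y_edges) - 1

    @property
    def j_mem(self) -> int:
        """Index of the y-edge on the membrane line y = 0."""
        return int(np.argmin(np.abs(self.y_edges)))

    @property
    def mem_cell(self) -> np.ndarray:
        """Boolean per x-cell: membrane present above/below this cell column."""
        return self.xc < self.x_mem_end

    @property
    def mem_edge(self) -> np.ndarray:
        """Boolean per x-edge: edge lies strictly inside the membrane span."""
        return self.x_edges < self.x_mem_end - 1e-12 * self.L

    def min_dy_at_membrane(self) -> float:
        j = self.j_mem
        return float(min(self.y_edges[j + 1] - self.y_edges[j],
                         self.y_edges[j] - self.y_edges[j - 1]))

    def check_resolves(self, fluid: FluidProperties, omega_max: float,
                       cells_per_layer: int = 3) -> None:
        """Raise unless the Stokes layer at ``omega_max`` spans >= n cells."""
        delta = fluid.stokes_layer(omega_max)
        if self.min_dy_at_membrane() * cells_per_layer > delta:
            raise ValueError(
                f"near-membrane spacing {self.min_dy_at_membrane() * 1e6:.2f} um "
                f"does not resolve the Stokes layer {delta * 1e6:.2f} um with "
                f">= {cells_per_layer} cells"
            )


def build_geometry(
    *,
    L: float = 7e-3,
    h: float = 0.5e-3,
    helicotrema_len: float = 0.5e-3,
    dx_coarse: float = 40e-6,
    dx_fine: float | None = None,
    refine_span: tuple[float, float] | None = None,
    dx_target: np.ndarray | None = None,
    x_sample: np.ndarray | None = None,
    dy_min: float = 1.2e-6,
    dy_growth: float = 1.25,
    dy_max: float | None = None,
    dy_wall: float | None = None,
) -> CochleaGeometry:
    """Build the two-chamber geometry with near-membrane refinement.

    Longitudinal spacing is ``dx_coarse`` everywhere except inside
    ``refine_span`` (where it is ``dx_fine``), or follows the sampled
    ``dx_target(x_sample)`` when given; the transition is graded.  Vertical
    spacing grows geometrically from ``dy_min`` at the membrane by factor
    ``dy_growth`` up to ``dy_max`` (default ``h/8``) at the outer walls.
    """
    if not (L > helicotrema_len > 0):
        raise ValueError("need L > helicotrema_len > 0 (chambers must connect)")
    x_mem_end = L - helicotrema_len
    if dx_target is None:
        xs = np.linspace(0.0, L, 2001)
        tgt = np.full_like(xs, dx_coarse)
        if dx_fine is not None and refine_span is not None:
            a, b = refine_span
            tgt[(xs >= a) & (xs <= b)] = dx_fine
    else:
        xs = np.asarray(x_sample, float)
        tgt = np.asarray(dx_target, float)

    # build each membrane/helicotrema segment separately so an edge lands
    # exactly on the membrane end (flux audits rely on it)
    seg1 = _graded_edges(x_mem_end, np.interp(
        np.linspace(0, x_mem_end, 1201), xs, tgt),
        np.linspace(0, x_mem_end, 1201))
    seg2 = _graded_edges(helicotrema_len, np.interp(
        x_mem_end + np.linspace(0, helicotrema_len, 201), xs, tgt),
        np.linspace(0, helicotrema_len, 201))
    x_edges = np.concatenate([seg1, x_mem_end + seg2[1:]])

    if dy_max is None:
        dy_max = h / 8.0
    half = _stretched_half(h, dy_min, dy_growth, dy_max, dy_wall)
    y_edges = np.concatenate([-half[::-1], half[1:]])

    return CochleaGeometry(L=L, h=h, helicotrema_len=helicotrema_len,
                           x_edges=x_edges, y_edges=y_edges)
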