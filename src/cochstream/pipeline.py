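"""High-level drivers: from membrane model and stimulus to streaming fields.

These functions encapsulate the standard workflow: solve the WKB membrane
wave for each tone, build a grid refined to the shortest local wavelength
and to the Stokes layer of the highest frequency, then run the oscillatory
and steady-streaming solves and superpose over tones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import OscillatoryField, solve_oscillatory
from .geometry import CochleaGeometry, FluidProperties, build_geometry
from .membrane import MembraneProperties, Tone, WKBSolution, solve_wkb
from .staggered import StokesSystem
from .streaming import StreamingField, solve_streaming_single, superpose

__all__ = ["Resolution", "RESOLUTIONS", "grid_for_tones", "run_tones",
           "single_tone_streaming"]


@dataclass(frozen=True)
class Resolution:
    """Grid resolution preset."""

    points_per_wavelength: float = 12.0   # longitudinal cells per wavelength
    cells_per_stokes_layer: float = 3.5   # vertical cells across delta_nu
    dx_max: float = 50e-6                 # coarse longitudinal cap (m)
    dy_growth: float = 1.25


RESOLUTIONS = {
    "coarse": Resolution(points_per_wavelength=8.0, cells_per_stokes_layer=3.0,
                         dx_max=80e-6, dy_growth=1.35),
    "default": Resolution(),
    "fine": Resolution(points_per_wavelength=18.0, cells_per_stokes_layer=5.0,
                       dx_max=35e-6, dy_growth=1.18),
}


def grid_for_tones(
    wkbs: list[WKBSolution],
    fluid: FluidProperties,
    *,
    L: float = 7e-3,
    h: float = 0.5e-3,
    helicotrema_len: float = 0.5e-3,
    resolution: Resolution | str = "default",
    envelope_cut: float = 1e-3,
) -> CochleaGeometry:
    """Grid refined to the tones' local wavelengths and Stokes layers.

    The longitudinal target spacing follows ``2 pi / (n Re k)`` of the
    shortest locally relevant wavelength; each tone's wavenumber counts
    only where its envelope exceeds ``envelope_cut`` of its maximum (the
    evanescent tail carries no energy and needs no resolution).
    """
    if isinstance(resolution, str):
        resolution = RESOLUTIONS[resolution]
    xs = np.linspace(0.0, L, 2001)
    k_eff = np.full_like(xs, 2 * np.pi / (resolution.points_per_wavelength
                                          * resolution.dx_max))
    for w in wkbs:
        env = np.interp(xs, w.x, w.envelope)
        rek = np.interp(xs, w.x, np.abs(w.k.real))
        rek[env < envelope_cut * env.max()] = 0.0
        k_eff = np.maximum(k_eff, rek)
    dx_target = 2 * np.pi / (resolution.points_per_wavelength * k_eff)
    dx_target = np.clip(dx_target, 0.5e-6, resolution.dx_max)

    omega_max = max(w.tone.omega for w in wkbs)
    dy_min = fluid.stokes_layer(omega_max) / resolution.cells_per_stokes_layer
    return build_geometry(
        L=L, h=h, helicotrema_len=helicotrema_len,
        dx_target=dx_target, x_sample=xs,
        dy_min=dy_min, dy_growth=resolution.dy_growth,
        dy_wall=2.0 * dy_min,
    )


@dataclass
class ToneRun:
    """All products of one multi-tone run."""

    wkbs: list[WKBSolution]
    geom: CochleaGeometry
    system: StokesSystem
    oscillatory: list[OscillatoryField]
    per_tone_streaming: list[StreamingField]
    streaming: StreamingField


def run_tones(
    props: MembraneProperties,
    fluid: FluidProperties,
    tones: list[Tone],
    *,
    L: float = 7e-3,
    h: float = 0.5e-3,
    helicotrema_len: float = 0.5e-3,
    resolution: Resolution | str = "default",
    attenuation: str = "compensated",
    include_slip: bool = True,
    xi_override: float | None = None,
    geom: CochleaGeometry | None = None,
) -> ToneRun:
    """Full pipeline for a list of tones (a comb or a single tone).

    Each tone carries its own level-dependent damping (no cross-tone
    interaction); the steady fields superpose linearly.
    """
    wkbs = [
        solve_wkb(props, t, rho0=fluid.rho0, h=h, L=L,
                  xi=xi_override, attenuation=attenuation)
        for t in tones
    ]
    if geom is None:
        geom = grid_for_tones(wkbs, fluid, L=L, h=h,
                              helicotrema_len=helicotrema_len,
                              resolution=resolution)
    system = StokesSystem(geom, fluid)
    osc = [solve_oscillatory(system, w) for w in wkbs]
    per_tone = [solve_streaming_single(system, f, include_slip=include_slip)
                for f in osc]
    total = per_tone[0] if len(per_tone) == 1 else superpose(per_tone)
    return ToneRun(wkbs=wkbs, geom=geom, system=system, oscillatory=osc,
                   per_tone_streaming=per_tone, streaming=total)


def single_tone_streaming(
    props: MembraneProperties,
    fluid: FluidProperties,
    tone: Tone,
    **kwargs,
) -> ToneRun:
    """Convenience wrapper for a pure-tone run."""
    return run_tones(props, fluid, [tone], **kwargs)
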