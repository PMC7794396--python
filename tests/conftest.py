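"""Shared fixtures: calibrated membrane model and small solver setups.

Expensive solver products (single-tone runs at the three calibrated
levels, a coarse two-chamber benchmark) are session-scoped so that the
acceptance checks, scaling laws and profile-shape tests share one solve.
"""

from __future__ import annotations

import numpy as np
import pytest

from cochstream.geometry import FluidProperties, build_geometry
from cochstream.membrane import MembraneProperties, Tone
from cochstream.pipeline import single_tone_streaming
from cochstream.staggered import MembraneBC, StokesSystem


@pytest.fixture(scope="session")
def props() -> MembraneProperties:
    return MembraneProperties()


@pytest.fixture(scope="session")
def fluid() -> FluidProperties:
    return FluidProperties()


@pytest.fixture(scope="session")
def level_runs(props, fluid):
    """20 kHz single-tone runs at the three calibrated levels."""
    return {
        spl: single_tone_streaming(props, fluid, Tone(20000.0, spl))
        for spl in (60.0, 80.0, 100.0)
    }


@pytest.fixture(scope="session")
def tone_run(props, fluid):
    """Pure 5 kHz tone at 80 dB on a coarse grid (vortex-structure checks)."""
    return single_tone_streaming(props, fluid, Tone(5000.0, 80.0),
                                 resolution="coarse")


@pytest.fixture(scope="session")
def packet_setup(fluid):
    """Coarse two-chamber setup driven by a synthetic membrane wave packet.

    A Gaussian-envelope travelling wave at 150 Hz on a 3 mm domain: cheap
    to solve, well resolved, and low streaming Reynolds number, used for
    oracle comparisons and scaling checks.
    """
    om = 2 * np.pi * 150.0
    geom = build_geometry(L=3e-3, h=0.5e-3, helicotrema_len=0.5e-3,
                          dx_coarse=35e-6, dy_min=7e-6, dy_growth=1.3)
    xc = geom.xc
    V0, kx = 4e-4, 2 * np.pi / 1.5e-3
    Vh = V0 * np.exp(-((xc - 1.2e-3) ** 2) / (2 * 0.4e-3**2)) \
        * np.exp(-1j * kx * xc)
    Vh = np.where(geom.mem_cell, Vh, 0.0)
    system = StokesSystem(geom, fluid)
    bc = MembraneBC.from_membrane_velocity(geom, Vh)
    return {"geom": geom, "system": system, "bc": bc, "omega": om, "V": Vh}
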