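"""Basilar-membrane impedance, WKB travelling wave, and tonotopic map.

The basilar membrane is modelled as an array of independent transverse
strips of area ``A`` (one hair-cell width times the membrane breadth), each
a damped harmonic oscillator with stiffness ``K(x)``, moving mass ``m(x)``
and drag ``xi``.  Both stiffness and mass vary exponentially along the
cochlea, which produces the logarithmic tonotopic map between stimulus
frequency and the place where the evoked travelling wave peaks.

The pressure difference across the membrane obeys a 1-D wave equation with
a slowly varying complex wavenumber; it is solved here in the WKB
(Liouville-Green) approximation.  All complex amplitudes follow the
convention ``q(t) = Re[q_hat exp(i omega t)]``, i.e. ``q_hat`` is the full
(peak) amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "P_REF_RMS",
    "MembraneProperties",
    "Tone",
    "WKBSolution",
    "TonotopicMap",
    "spl_to_pressure_amplitude",
    "fit_length_scales",
    "impedance",
    "solve_wkb",
    "default_wkb_grid",
    "characteristic_place",
    "tonotopic_slope",
]

#: RMS reference pressure of the dB SPL scale (Pa).
P_REF_RMS = 20e-6

#: Level-dependent drag of the membrane strip, calibrated so the WKB peak
#: width matches measured gerbil tuning curves at 17 kHz (N s/m per strip).
XI_TABLE = {60.0: 10e-9, 80.0: 500e-9, 100.0: 2000e-9}


def spl_to_pressure_amplitude(spl: float) -> float:
    """Peak pressure amplitude (Pa) of a pure tone at ``spl`` dB SPL.

    The SPL scale references 20 uPa RMS; the returned value is the peak
    amplitude ``sqrt(2) * p_rms``.
    """
    if not np.isfinite(spl):
        raise ValueError("sound pressure level must be finite")
    return float(np.sqrt(2.0) * P_REF_RMS * 10.0 ** (spl / 20.0))


def fit_length_scales(
    K0: float, K_ref: float, m0: float, m_ref: float, x_ref: float
) -> tuple[float, float]:
    """Exponential length scales ``(l_K, l_m)`` from basal and apical samples.

    ``K(x) = K0 exp(-x/l_K)`` and ``m(x) = m0 exp(x/l_m)`` are anchored at
    ``x=0`` and ``x=x_ref``.
    """
    if min(K0, K_ref, m0, m_ref, x_ref) <= 0:
        raise ValueError("all stiffness/mass/position values must be positive")
    if K_ref >= K0:
        raise ValueError("stiffness must decrease from base to apex (K_ref < K0)")
    if m_ref <= m0:
        raise ValueError("mass must increase from base to apex (m_ref > m0)")
    l_K = x_ref / np.log(K0 / K_ref)
    l_m = x_ref / np.log(m_ref / m0)
    return float(l_K), float(l_m)


@dataclass(frozen=True)
class MembraneProperties:
    """Stiffness/mass/damping profile of the basilar membrane.

    Default values are gerbil measurements: organ-of-Corti moving mass
    32 ng growing to 65 ng over 7 mm, strip stiffness 1 N/m decaying to
    0.03 N/m over the same span, strip area 8 um x 186 um.  The exponential
    length scales are derived from those endpoint values unless given
    explicitly.
    """

    m0: float = 32e-12          # basal strip mass (kg)
    K0: float = 1.0             # basal strip stiffness (N/m)
    x_ref: float = 7e-3         # apical reference position (m)
    m_ref: float = 65e-12       # strip mass at x_ref (kg)
    K_ref: float = 0.03         # strip stiffness at x_ref (N/m)
    A: float = 8e-6 * 186e-6    # strip area (m^2)
    l_m: float | None = None    # mass length scale (m); derived if None
    l_K: float | None = None    # stiffness length scale (m); derived if None
    xi_by_spl: Mapping[float, float] = field(
        default_factory=lambda: dict(XI_TABLE)
    )

    def __post_init__(self) -> None:
        if self.l_K is None or self.l_m is None:
            l_K, l_m = fit_length_scales(
                self.K0, self.K_ref, self.m0, self.m_ref, self.x_ref
            )
            if self.l_K is None:
                object.__setattr__(self, "l_K", l_K)
            if self.l_m is None:
                object.__setattr__(self, "l_m", l_m)
        if min(self.m0, self.K0, self.A) <= 0:
            raise ValueError("m0, K0 and A must be positive")
        if self.l_K <= 0 or self.l_m <= 0:
            raise ValueError("length scales must be positive")
        if any(v <= 0 for v in self.xi_by_spl.values()):
            raise ValueError("damping values must be positive")

    def stiffness(self, x):
        """Strip stiffness K(x) (N/m), strictly decreasing."""
        return self.K0 * np.exp(-np.asarray(x, float) / self.l_K)

    def mass(self, x):
        """Strip moving mass m(x) (kg), strictly increasing."""
        return self.m0 * np.exp(np.asarray(x, float) / self.l_m)

    def resonance_frequency(self, x):
        """Undamped strip resonance f0(x) = sqrt(K/m)/(2 pi) (Hz)."""
        return np.sqrt(self.stiffness(x) / self.mass(x)) / (2 * np.pi)

    def xi_for_spl(self, spl: float) -> float:
        """Level-dependent drag (N s/m) by log-log interpolation.

        The three calibrated levels are interpolated log-log; levels outside
        the calibrated range clamp to the nearest endpoint with a warning.
        """
        levels = np.array(sorted(self.xi_by_spl))
        xis = np.array([self.xi_by_spl[v] for v in levels])
        if spl < levels[0] or spl > levels[-1]:
            warnings.warn(
                f"SPL {spl} dB outside calibrated damping range "
                f"[{levels[0]}, {levels[-1]}] dB; clamping",
                stacklevel=2,
            )
            return float(xis[0] if spl < levels[0] else xis[-1])
        # log-log in (pressure, xi): SPL is already log-pressure (dB)
        return float(np.exp(np.interp(spl, levels, np.log(xis))))


def impedance(props: MembraneProperties, x, omega: float, xi: float):
    """Complex specific acoustic impedance Z(x) (Pa s/m) of the membrane.

    ``Z = [i omega m(x) + xi - i K(x)/omega] / A``: mass reactance, drag and
    stiffness reactance of the strip, divided by the strip area.
    """
    if omega <= 0:
        raise ValueError("angular frequency must be positive")
    x = np.asarray(x, float)
    return (1j * omega * props.mass(x) + xi - 1j * props.stiffness(x) / omega) / props.A


@dataclass(frozen=True)
class Tone:
    """A pure tone: frequency, level and phase of the basal pressure."""

    f: float                  # frequency (Hz)
    spl: float                # sound pressure level (dB SPL)
    phase: float = 0.0        # basal phase (rad)

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("frequency must be positive")

    @property
    def omega(self) -> float:
        """Angular frequency 2 pi f (rad/s)."""
        return 2 * np.pi * self.f

    @property
    def p0(self) -> float:
        """Complex basal pressure amplitude (Pa), peak convention."""
        return spl_to_pressure_amplitude(self.spl)

    @property
    def p0_complex(self) -> complex:
        return self.p0 * np.exp(1j * self.phase)


def tonotopic_slope(props: MembraneProperties) -> float:
    """Distance per log-frequency of the tonotopic map (m).

    The undamped resonance condition ``omega^2 = K(x)/m(x)`` with exponential
    profiles gives ``x(f) = -slope ln f + const`` with
    ``slope = 2 / (1/l_K + 1/l_m)``.
    """
    return 2.0 / (1.0 / props.l_K + 1.0 / props.l_m)


@dataclass(frozen=True)
class TonotopicMap:
    """Logarithmic frequency-place map ``x(f) = slope * ln(f_base / f)``."""

    slope: float    # distance per log-frequency (m)
    f_base: float   # frequency whose place is x = 0 (Hz)

    @classmethod
    def from_membrane(cls, props: MembraneProperties) -> "TonotopicMap":
        return cls(
            slope=tonotopic_slope(props),
            f_base=float(props.resonance_frequency(0.0)),
        )

    def place(self, f):
        """Characteristic place (m) of frequency ``f`` (Hz)."""
        return self.slope * np.log(self.f_base / np.asarray(f, float))

    def frequency(self, x):
        """Inverse map: frequency (Hz) whose place is ``x`` (m)."""
        return self.f_base * np.exp(-np.asarray(x, float) / self.slope)


@dataclass(frozen=True)
class WKBSolution:
    """WKB travelling-wave solution for one tone on a 1-D grid.

    ``p_hat`` and ``V_hat`` are the complex pressure-difference and membrane
    velocity amplitudes including the accumulated phase, so the physical
    signals are ``Re[p_hat exp(i omega t)]`` and ``Re[V_hat exp(i omega t)]``.
    """

    x: np.ndarray         # positions (m), ascending from 0
    k: np.ndarray         # complex wavenumber (1/m), Im k <= 0
    Z: np.ndarray         # complex impedance (Pa s/m)
    p_hat: np.ndarray     # complex pressure amplitude (Pa)
    V_hat: np.ndarray     # complex membrane velocity amplitude (m/s)
    tone: Tone
    xi: float             # drag used (N s/m)
    attenuation: str      # "compensated" or "full"

    @property
    def envelope(self) -> np.ndarray:
        """Membrane velocity amplitude |V_hat| (m/s)."""
        return np.abs(self.V_hat)

    @property
    def displacement(self) -> np.ndarray:
        """Membrane displacement amplitude |V_hat|/omega (m)."""
        return self.envelope / self.tone.omega

    @property
    def sensitivity(self) -> np.ndarray:
        """Displacement per unit stimulus pressure (m/Pa)."""
        return self.displacement / self.tone.p0

    def peak_place(self) -> float:
        """Place of the envelope maximum (m), parabolically refined."""
        a = self.envelope
        i = int(np.argmax(a))
        if 0 < i < len(a) - 1:
            # parabolic interpolation on a nonuniform 3-point stencil
            x0, x1, x2 = self.x[i - 1 : i + 2]
            y0, y1, y2 = a[i - 1 : i + 2]
            d1 = (y1 - y0) / (x1 - x0)
            d2 = (y2 - y1) / (x2 - x1)
            curv = (d2 - d1) / (x2 - x0) * 2.0
            if curv < 0:
                return float((x0 + x1) / 2 - d1 / curv)
        return float(self.x[i])

    def consistency_ratio(self) -> np.ndarray:
        """WKB validity metric ``|p_env'/p_env| / |k|`` (dimensionless).

        The WKB ansatz assumes the envelope varies slowly compared with the
        local wavelength; values approaching 1 flag a locally invalid
        approximation.
        """
        env = np.abs((self.Z / self.Z[0]) ** 0.25)
        denv = np.gradient(env, self.x)
        return np.abs(denv) / (env * np.abs(self.k))

    def interp_V(self, x):
        """Complex membrane velocity amplitude interpolated at ``x``."""
        x = np.asarray(x, float)
        return np.interp(x, self.x, self.V_hat.real) + 1j * np.interp(
            x, self.x, self.V_hat.imag
        )


def _wavenumber(Z, omega, rho0, h):
    """Eq.-(3)-style wavenumber with the negative-imaginary branch."""
    k = np.sqrt(2.0 * omega * rho0 / (1j * Z * h))
    return np.where(k.imag > 0, -k, k)


def default_wkb_grid(
    props: MembraneProperties,
    tone: Tone,
    *,
    rho0: float = 1000.0,
    h: float = 0.5e-3,
    L: float = 7e-3,
    xi: float | None = None,
    points_per_wavelength: int = 20,
    min_points: int = 2000,
    max_points: int = 400_000,
) -> np.ndarray:
    """Uniform 1-D grid fine enough for the phase integral of ``tone``.

    Spacing is at most ``2 pi / (points_per_wavelength * max Re k)``.
    """
    if xi is None:
        xi = props.xi_for_spl(tone.spl)
    probe = np.linspace(0.0, L, 4096)
    k = _wavenumber(impedance(props, probe, tone.omega, xi), tone.omega, rho0, h)
    kmax = float(np.max(np.abs(k.real))) or 1.0 / L
    n = int(np.ceil(L * kmax * points_per_wavelength / (2 * np.pi)))
    n = int(np.clip(n, min_points, max_points))
    return np.linspace(0.0, L, n + 1)


def solve_wkb(
    props: MembraneProperties,
    tone: Tone,
    x_grid: np.ndarray | None = None,
    *,
    rho0: float = 1000.0,
    h: float = 0.5e-3,
    L: float = 7e-3,
    xi: float | None = None,
    attenuation: Literal["compensated", "full"] = "compensated",
    consistency_threshold: float = 0.3,
) -> WKBSolution:
    """Solve the WKB travelling wave for one tone.

    The wave equation for the trans-membrane pressure has local wavenumber
    ``k(x) = sqrt(2 omega rho0 / (i Z(x) h))`` (negative-imaginary branch);
    the WKB amplitude law gives ``p_hat = p0 (Z/Z0)^(1/4)`` and membrane
    velocity ``V_hat = (p0/Z0) (Z0/Z)^(3/4) exp(-i Phi)``.

    Two envelope modes are provided.  ``"full"`` evaluates the phase
    integral ``Phi = int k dx`` with the fully damped ``k``, so the drag
    attenuates the wave all along its path.  The default ``"compensated"``
    mode instead models a cochlea whose active process cancels the viscous
    propagation loss basal to the peak (the same assumption under which the
    level-dependent drag table was calibrated): the phase comes from
    ``Re k`` and the only amplitude decay in the exponent is the evanescent
    decay of the *lossless* wavenumber apical to the resonance place.  In
    this mode the drag still limits and broadens the peak through the local
    impedance.
    """
    if xi is None:
        xi = props.xi_for_spl(tone.spl)
    if x_grid is None:
        x_grid = default_wkb_grid(
            props, tone, rho0=rho0, h=h, L=L, xi=xi
        )
    x = np.asarray(x_grid, float)
    if x.ndim != 1 or len(x) < 2 or x[0] != 0.0 or np.any(np.diff(x) <= 0):
        raise ValueError("x_grid must be 1-D, ascending, and start at 0")

    omega = tone.omega
    Z = impedance(props, x, omega, xi)
    if np.any(Z == 0):
        raise ValueError("membrane impedance vanishes on the grid")
    k = _wavenumber(Z, omega, rho0, h)

    if attenuation == "full":
        phase = cumulative_trapezoid(k, x, initial=0.0)
        log_amp = np.zeros_like(x)
    elif attenuation == "compensated":
        phase = cumulative_trapezoid(k.real, x, initial=0.0)
        Z_lossless = impedance(props, x, omega, 0.0) + 0j
        k_ll = _wavenumber(Z_lossless, omega, rho0, h)
        # lossless k is real (propagating) basal to resonance and purely
        # negative-imaginary (evanescent) apical to it; its integrable
        # singularity at the resonance place is handled by the trapezoid
        decay = np.minimum(k_ll.imag, 0.0)
        log_amp = cumulative_trapezoid(decay, x, initial=0.0)
    else:
        raise ValueError(f"unknown attenuation mode {attenuation!r}")

    p0 = tone.p0_complex
    env = (Z / Z[0]) ** 0.25
    p_hat = p0 * env * np.exp(log_amp - 1j * phase)
    V_hat = p_hat / Z

    sol = WKBSolution(
        x=x, k=k, Z=Z, p_hat=p_hat, V_hat=V_hat, tone=tone, xi=float(xi),
        attenuation=attenuation,
    )
    ratio = sol.consistency_ratio()
    if np.any(ratio > consistency_threshold):
        frac = float(np.mean(ratio > consistency_threshold))
        warnings.warn(
            f"WKB self-consistency |p'/p|/|k| exceeds {consistency_threshold} "
            f"on {100 * frac:.1f}% of grid nodes (max {ratio.max():.2f})",
            stacklevel=2,
        )
    return sol


def characteristic_place(
    props: MembraneProperties,
    f: float,
    *,
    mode: Literal["peak", "resonance"] = "peak",
    xi: float | None = None,
    spl: float = 80.0,
    rho0: float = 1000.0,
    h: float = 0.5e-3,
    L: float = 7e-3,
) -> float:
    """Characteristic place (m) of frequency ``f``.

    ``"resonance"`` solves the undamped condition ``omega^2 = K(x)/m(x)``
    in closed form; ``"peak"`` (default) returns the argmax of the damped
    WKB envelope.
    """
    omega = 2 * np.pi * f
    x_res = 0.5 * tonotopic_slope(props) * np.log(
        props.K0 / (props.m0 * omega**2)
    )
    if not (0.0 <= x_res <= L):
        raise ValueError(
            f"frequency {f} Hz maps to {x_res * 1e3:.2f} mm, outside [0, {L * 1e3:.1f}] mm"
        )
    if mode == "resonance":
        return float(x_res)
    if mode != "peak":
        raise ValueError(f"unknown mode {mode!r}")
    sol = solve_wkb(props, Tone(f=f, spl=spl), rho0=rho0, h=h, L=L, xi=xi)
    return sol.peak_place()


def place_to_frequency(props: MembraneProperties, x: float) -> float:
    """Frequency (Hz) whose undamped resonance place is ``x`` (m)."""
    return TonotopicMap.from_membrane(props).frequency(x)
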