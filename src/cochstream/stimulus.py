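"""Multi-frequency tone combs with prescribed peak spacing.

A comb is a set of tones whose frequencies differ by a constant ratio
``R > 1``; by the logarithmic tonotopic map their travelling-wave peaks are
then equally spaced, ``delta = slope * ln R``.  Overlapping the individual
streaming vortices of such a comb creates the extended "streaming channel"
used for drug transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .membrane import MembraneProperties, Tone, TonotopicMap

__all__ = ["ToneComb", "comb_from_delta", "comb_from_ratio", "comb_places",
           "MIN_SPACING"]

#: Peak spacings at or below this value are refused by default: overlapping
#: nonlinear response regions would require modelling two-tone suppression.
MIN_SPACING = 100e-6


@dataclass(frozen=True)
class ToneComb:
    """An ordered set of tones with constant frequency ratio."""

    tones: tuple[Tone, ...]
    R: float              # successive frequency ratio (> 1 for n > 1)
    delta: float          # peak-place spacing (m)

    def __post_init__(self) -> None:
        fs = [t.f for t in self.tones]
        if len(fs) > 1:
            ratios = np.array(fs[1:]) / np.array(fs[:-1])
            if not np.allclose(ratios, self.R, rtol=1e-12):
                raise ValueError("tone frequencies must follow f_{i+1} = R f_i")
            if self.R <= 1:
                raise ValueError("frequency ratio must exceed 1")

    @property
    def n(self) -> int:
        return len(self.tones)

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([t.f for t in self.tones])

    def with_random_phases(self, seed: int) -> "ToneComb":
        """Same comb with per-tone phases drawn uniformly from [0, 2 pi)."""
        rng = np.random.default_rng(seed)
        tones = tuple(
            Tone(f=t.f, spl=t.spl, phase=float(rng.uniform(0, 2 * np.pi)))
            for t in self.tones
        )
        return ToneComb(tones=tones, R=self.R, delta=self.delta)


def comb_from_delta(
    tmap: TonotopicMap,
    f1: float,
    n: int,
    delta: float,
    *,
    spl: float = 80.0,
    spl_per_tone: list[float] | None = None,
    domain: tuple[float, float] = (0.0, 7e-3),
    allow_close_spacing: bool = False,
) -> ToneComb:
    """Comb of ``n`` tones starting at ``f1`` with peak spacing ``delta``.

    ``R = exp(delta / slope)``; places run basally (toward x = 0) with
    increasing frequency.  Spacings of 100 um or less are refused unless
    ``allow_close_spacing`` (two-tone suppression is not modelled).
    """
    if n < 1:
        raise ValueError("need at least one tone")
    if delta <= 0:
        raise ValueError("peak spacing must be positive")
    if n > 1 and delta <= MIN_SPACING and not allow_close_spacing:
        raise ValueError(
            f"peak spacing {delta * 1e6:.0f} um <= {MIN_SPACING * 1e6:.0f} um: "
            "two-tone suppression between overlapping nonlinear regions is "
            "not modelled; pass allow_close_spacing=True to override"
        )
    R = float(np.exp(delta / tmap.slope))
    return _build(tmap, f1, n, R, delta, spl, spl_per_tone, domain)


def comb_from_ratio(
    tmap: TonotopicMap, f1: float, n: int, R: float, **kwargs
) -> ToneComb:
    """Comb specified by the frequency ratio instead of the spacing."""
    if n > 1 and R <= 1:
        raise ValueError("frequency ratio must exceed 1")
    delta = tmap.slope * np.log(R)
    spl = kwargs.pop("spl", 80.0)
    spl_per_tone = kwargs.pop("spl_per_tone", None)
    domain = kwargs.pop("domain", (0.0, 7e-3))
    return _build(tmap, f1, n, float(R), float(delta), spl, spl_per_tone, domain)


def _build(tmap, f1, n, R, delta, spl, spl_per_tone, domain) -> ToneComb:
    freqs = f1 * R ** np.arange(n)
    if spl_per_tone is None:
        spl_per_tone = [spl] * n
    if len(spl_per_tone) != n:
        raise ValueError("spl_per_tone length must match the number of tones")
    places = tmap.place(freqs)
    lo, hi = domain
    if places.min() < lo - 1e-12 or places.max() > hi + 1e-12:
        raise ValueError(
            f"comb places span [{places.min() * 1e3:.2f}, "
            f"{places.max() * 1e3:.2f}] mm, outside the domain "
            f"[{lo * 1e3:.1f}, {hi * 1e3:.1f}] mm"
        )
    tones = tuple(Tone(f=float(f), spl=float(s))
                  for f, s in zip(freqs, spl_per_tone))
    return ToneComb(tones=tones, R=R, delta=delta)


def comb_places(comb: ToneComb, tmap: TonotopicMap) -> np.ndarray:
    """Characteristic places of the comb (m), strictly decreasing."""
    return tmap.place(comb.frequencies)


def default_f1(tmap: TonotopicMap, n: int, delta: float,
               x_top: float = 0.25e-3) -> float:
    """Lowest comb frequency such that the highest tone peaks at ``x_top``.

    The basal-most (highest-frequency) place anchors the streaming channel
    at the injection region near the base.
    """
    f_top = float(tmap.frequency(x_top))
    R = float(np.exp(delta / tmap.slope))
    return f_top / R ** (n - 1)
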