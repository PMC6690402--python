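"""Geometry of the LM cone-contrast stimulus space.

A drifting Gabor that modulates the L- and M-cones is summarised by three
numbers: a color direction (angle in the LM plane of cone-contrast space),
a modulation amplitude (vector length in that plane), and a temporal
frequency.  S-cones are never modulated, so the stimulus space is the LM
plane crossed with frequency.  A modulation and its counterphase partner
are physically the same stimulus, so directions live on a half-turn,
canonically [0, pi).

The display can only produce a bounded range of cone contrasts.  That
boundary is modelled here as an ellipse in the LM plane with semi-axes
along the L+M and L-M diagonals; thresholds predicted to fall outside it
are censored at the edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConeContrastPair",
    "StimulusCondition",
    "GamutModel",
    "cone_contrast",
    "direction_amplitude",
    "canonical_direction",
    "unit_vector",
    "gamut_limit",
    "LUM_AXIS",
    "RG_AXIS",
    "TESTED_FREQ_RANGE",
]

#: Color direction of the nonopponent (L+M) diagonal, radians.
LUM_AXIS = np.pi / 4
#: Color direction of the opponent (L-M) diagonal, radians.
RG_AXIS = 3 * np.pi / 4
#: Temporal frequencies actually probed by the experiment, Hz.
TESTED_FREQ_RANGE = (1.0, 60.0)


@dataclass(frozen=True)
class ConeContrastPair:
    """Weber contrasts of the L- and M-cones for one modulation.

    The pair and its negation describe the same counterphase stimulus.
    """

    L: float
    M: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L) and np.isfinite(self.M)):
            raise ValueError("cone contrasts must be finite")

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.L, self.M))

    def __neg__(self) -> "ConeContrastPair":
        return ConeContrastPair(-self.L, -self.M)


def cone_contrast(stim_excitation, background_excitation):
    """Weber cone contrast ``(stim - background) / background``.

    Parameters are cone excitations in any common unit; the result is
    dimensionless and invariant to rescaling both by the same factor.
    """
    bg = np.asarray(background_excitation, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background excitation must be positive")
    out = (np.asarray(stim_excitation, dtype=float) - bg) / bg
    return out if out.ndim else float(out)


def canonical_direction(direction):
    """Reduce a color direction to the fundamental half-turn [0, pi)."""
    return np.mod(direction, np.pi)


def direction_amplitude(c: ConeContrastPair) -> tuple[float, float]:
    """Polar form of a cone-contrast pair.

    Returns ``(direction, amplitude)`` with the direction canonical in
    [0, pi); the L+M diagonal maps to pi/4 and L-M to 3pi/4.  The zero
    vector has amplitude 0 and an undefined (NaN) direction.
    """
    amp = c.amplitude
    if amp == 0.0:
        return float("nan"), 0.0
    return float(canonical_direction(np.arctan2(c.M, c.L))), amp


def unit_vector(direction) -> ConeContrastPair:
    """Unit-amplitude cone-contrast pair (L, M) along ``direction``."""
    return ConeContrastPair(float(np.cos(direction)), float(np.sin(direction)))


@dataclass(frozen=True)
class GamutModel:
    """Elliptical model of the maximum producible modulation amplitude.

    ``a_lum`` is the semi-axis along the L+M diagonal and ``a_rg`` along
    L-M, both in units of cone contrast.  The true display boundary
    depends on the primaries and background; this parametric stand-in
    keeps the qualitative feature that opponent modulations run out of
    gamut at far smaller amplitudes than nonopponent ones.
    """

    a_lum: float = 1.0
    a_rg: float = 0.16

    def __post_init__(self) -> None:
        if self.a_lum <= 0 or self.a_rg <= 0:
            raise ValueError("gamut semi-axes must be positive")

    def limit(self, direction):
        return gamut_limit(self, direction)


def gamut_limit(g: GamutModel, direction):
    """Maximum amplitude the display can produce along ``direction``.

    Radius of the gamut ellipse along the given color direction; the
    function is continuous and pi-periodic.
    """
    u = np.asarray(direction, dtype=float) - LUM_AXIS  # angle from the L+M axis
    r = (g.a_lum * g.a_rg) / np.sqrt(
        (g.a_rg * np.cos(u)) ** 2 + (g.a_lum * np.sin(u)) ** 2
    )
    return r if r.ndim else float(r)


@dataclass(frozen=True)
class StimulusCondition:
    """One color direction x temporal frequency x amplitude at a location.

    ``location`` is a :class:`tcsfield.field.FieldLocation`; it is typed
    loosely here to keep the geometry module free of the spatial one.
    """

    color_direction: float
    temporal_frequency: float
    amplitude: float = 1.0
    location: object | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "color_direction", float(canonical_direction(self.color_direction))
        )
        if self.temporal_frequency <= 0:
            raise ValueError("temporal frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        lo, hi = TESTED_FREQ_RANGE
        if not (lo <= self.temporal_frequency <= hi):
            warnings.warn(
                f"temporal frequency {self.temporal_frequency:g} Hz is outside "
                f"the tested range {lo:g}-{hi:g} Hz",
                stacklevel=3,
            )
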