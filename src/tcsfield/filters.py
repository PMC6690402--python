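"""Temporal filters and the two-mechanism detection model.

Detection is assumed to be mediated by two linear mechanisms, a luminance
(LUM) detector responding to a weighted sum of L- and M-cone contrast and
a red-green (RG) detector responding to their difference.  Each mechanism
has a temporal transfer function built as the difference of two low-pass
cascades,

    H1(w) = (i 2 pi tau w + 1)^(-n)
    H(w)  = xi (H1(w) - zeta H2(w)),

where tau is a time constant in seconds, n the (real-valued) number of
low-pass stages, xi an overall gain and zeta the transience: zeta = 0
gives a pure low-pass filter, zeta > 0 a bandpass one.  Mechanism outputs
combine by energy, so predicted detection contours in the LM plane are
ellipses whose shape and orientation change with temporal frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .stimulus import RG_AXIS, unit_vector

__all__ = [
    "TemporalFilter",
    "MechanismSet",
    "DetectionEllipse",
    "CrossingResult",
    "lowpass_response",
    "filter_response",
    "contrast_sensitivity",
    "detection_threshold",
    "detection_ellipse",
    "mechanism_crossing_frequency",
    "sensitivity_quadratic_form",
]


def lowpass_response(omega, tau, n):
    """Complex gain of an n-stage low-pass cascade at frequency ``omega`` (Hz).

    ``(i 2 pi tau omega + 1)^(-n)`` on the principal branch, so the
    magnitude is ``(1 + (2 pi tau omega)^2)^(-n/2)`` and the phase
    ``-n atan(2 pi tau omega)``.
    """
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be positive")
    if np.any(np.asarray(n) < 1):
        raise ValueError("n must be >= 1")
    return (1j * 2 * np.pi * np.asarray(tau) * np.asarray(omega, dtype=float) + 1) ** (
        -np.asarray(n)
    )


@dataclass(frozen=True)
class TemporalFilter:
    """Six parameters of one mechanism's temporal transfer function.

    xi : overall gain (> 0)
    zeta : transience in [0, 1]; 0 is pure low-pass
    tau1, tau2 : time constants of the two cascades, seconds in (0, 1]
    n1, n2 : real-valued stage counts, >= 1
    """

    xi: float = 1.0
    zeta: float = 0.0
    tau1: float = 0.01
    tau2: float = 0.1
    n1: float = 3.0
    n2: float = 3.0

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must lie in [0, 1]")
        for tau in (self.tau1, self.tau2):
            if not 0.0 < tau <= 1.0:
                raise ValueError("time constants must lie in (0, 1] s")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("stage counts must be >= 1")

    def response(self, omega):
        return filter_response(self, omega)

    def with_xi(self, xi: float) -> "TemporalFilter":
        return replace(self, xi=xi)


def filter_response(f: TemporalFilter, omega):
    """Complex transfer function ``xi (H1 - zeta H2)`` at ``omega`` Hz.

    The subtraction is done on the complex responses; take ``abs`` of the
    result for the magnitude response.  Because the two cascades rotate
    phase at different rates, the magnitude can exceed the DC value
    ``xi (1 - zeta)``.
    """
    h1 = lowpass_response(omega, f.tau1, f.n1)
    h2 = lowpass_response(omega, f.tau2, f.n2)
    return f.xi * (h1 - f.zeta * h2)


@dataclass(frozen=True)
class MechanismSet:
    """LUM and RG temporal filters plus the LUM cone-weight angle theta.

    The RG mechanism weights L- and M-cones equally and oppositely (its
    weight vector points along 3pi/4).  The LUM weight vector is
    ``(cos theta, sin theta)`` with theta in (0, pi/2), so both cone
    classes contribute with positive sign.
    """

    lum: TemporalFilter
    rg: TemporalFilter
    theta: float = np.pi / 4

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < np.pi / 2:
            raise ValueError("theta must lie in (0, pi/2)")

    @property
    def lum_weights(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta)])

    @property
    def rg_weights(self) -> np.ndarray:
        return np.array([np.cos(RG_AXIS), np.sin(RG_AXIS)])


def contrast_sensitivity(m: MechanismSet, omega, direction):
    """Model contrast sensitivity for a unit stimulus along ``direction``.

    The (L, M) cone contrasts of the unit stimulus are projected onto the
    two mechanisms' weight vectors, scaled by the magnitude responses
    ``|H(omega)|``, and combined by energy:

        sqrt( (|H_RG| w_RG.c)^2 + (|H_LUM| w_LUM.c)^2 ).

    ``omega`` and ``direction`` broadcast as numpy arrays.
    """
    omega = np.asarray(omega, dtype=float)
    direction = np.asarray(direction, dtype=float)
    h_lum = np.abs(filter_response(m.lum, omega))
    h_rg = np.abs(filter_response(m.rg, omega))
    c_l, c_m = np.cos(direction), np.sin(direction)
    wl, wr = m.lum_weights, m.rg_weights
    proj_lum = wl[0] * c_l + wl[1] * c_m
    proj_rg = wr[0] * c_l + wr[1] * c_m
    s = np.sqrt((h_rg * proj_rg) ** 2 + (h_lum * proj_lum) ** 2)
    return s if s.ndim else float(s)


def detection_threshold(m: MechanismSet, omega, direction):
    """Threshold modulation amplitude: the reciprocal of sensitivity.

    Directions invisible to both mechanisms get an infinite threshold
    rather than an error.
    """
    s = np.asarray(contrast_sensitivity(m, omega, direction))
    with np.errstate(divide="ignore"):
        t = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), np.inf)
    return t if t.ndim else float(t)


def sensitivity_quadratic_form(m: MechanismSet, omega) -> np.ndarray:
    """2x2 matrix Q with sensitivity^2 = c' Q c for unit cone contrast c."""
    h_lum = abs(filter_response(m.lum, omega))
    h_rg = abs(filter_response(m.rg, omega))
    wl, wr = m.lum_weights, m.rg_weights
    return h_rg**2 * np.outer(wr, wr) + h_lum**2 * np.outer(wl, wl)


@dataclass(frozen=True)
class DetectionEllipse:
    """Threshold contour in the LM plane at one temporal frequency.

    ``semi_major``/``semi_minor`` are threshold amplitudes along the
    principal axes; ``orientation`` is the color direction of the major
    axis in [0, pi).  ``degenerate`` flags an unbounded contour (one
    mechanism blind and the other unable to cover the plane).
    """

    semi_major: float
    semi_minor: float
    orientation: float
    degenerate: bool = False

    def boundary(self, t) -> np.ndarray:
        """Points (L, M) on the ellipse at parameter angles ``t``."""
        t = np.asarray(t, dtype=float)
        ca, sa = np.cos(self.orientation), np.sin(self.orientation)
        x = self.semi_major * np.cos(t)
        y = self.semi_minor * np.sin(t)
        return np.stack([ca * x - sa * y, sa * x + ca * y], axis=-1)


def detection_ellipse(m: MechanismSet, omega: float) -> DetectionEllipse:
    """Eigendecomposition of the sensitivity quadratic form at ``omega``.

    Semi-axis thresholds are inverse square roots of the eigenvalues of Q;
    the major axis (largest threshold) direction is the eigenvector of the
    smallest eigenvalue.  The orientation generally rotates with temporal
    frequency because the mechanisms are not orthogonal.
    """
    q = sensitivity_quadratic_form(m, omega)
    evals, evecs = np.linalg.eigh(q)  # ascending eigenvalues
    degenerate = bool(evals[0] <= 0)
    small = max(evals[0], np.finfo(float).tiny)
    semi_major = float(1.0 / np.sqrt(small)) if not degenerate else np.inf
    semi_minor = float(1.0 / np.sqrt(evals[1]))
    v = evecs[:, 0]
    orientation = float(np.mod(np.arctan2(v[1], v[0]), np.pi))
    return DetectionEllipse(semi_major, semi_minor, orientation, degenerate)


@dataclass(frozen=True)
class CrossingResult:
    """Frequencies where the two gain-normalized magnitude responses meet."""

    frequencies: np.ndarray
    degenerate: bool = False


def mechanism_crossing_frequency(
    m: MechanismSet,
    f_min: float = 0.1,
    f_max: float = 60.0,
    n_grid: int = 4096,
    tol: float = 1e-12,
) -> CrossingResult:
    """Frequencies where |H_LUM|/xi_LUM equals |H_RG|/xi_RG.

    The gain-normalized magnitudes isolate the shape of each mechanism's
    tuning from its overall sensitivity; their crossing is the frequency
    at which the non-gain components of the model confer equal
    sensitivity.  Sign changes of the difference on a log-frequency grid
    are polished by bracketed root finding.  Identical normalized filters
    yield a degenerate result (all frequencies cross).
    """
    grid = np.logspace(np.log10(f_min), np.log10(f_max), n_grid)

    def diff(freq):
        return np.abs(filter_response(m.lum, freq)) / m.lum.xi - np.abs(
            filter_response(m.rg, freq)
        ) / m.rg.xi

    d = diff(grid)
    if np.max(np.abs(d)) < tol:
        return CrossingResult(grid.copy(), degenerate=True)
    roots = []
    sign = np.sign(d)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(brentq(diff, grid[i], grid[i + 1]))
    # grid points that are exact roots
    for f0 in grid[np.abs(d) == 0]:
        roots.append(float(f0))
    return CrossingResult(np.array(sorted(roots)), degenerate=False)
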