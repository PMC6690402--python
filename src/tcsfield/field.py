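"""Visual-field coordinates and the spatial gain field of the mechanisms.

The temporal/chromatic model describes sensitivity at one visual-field
location.  Across the field only the two mechanism gains xi_LUM and
xi_RG change, each following an exponential decline with eccentricity
whose log10 is linear in polar coordinates:

    log10 xi = b0 + b1 r + b2 r cos(2 phi) + b3 r sin(2 phi)

with r the eccentricity in degrees of visual angle and phi the polar
angle from the right horizontal meridian (positive = upper field).  The
slope along the horizontal meridian is b1 + b2 and along the vertical
meridian b1 - b2; b3 introduces an upper/lower asymmetry that vanishes
on the vertical meridian.  Four model variants constrain b3: forced to
zero in both mechanisms (symmetric), shared between them (yoked, 18 free
parameters in total), luminance-only, or fit separately (unconstrained).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .filters import MechanismSet, TemporalFilter, filter_response

__all__ = [
    "FieldLocation",
    "SpatialGain",
    "ObserverModel",
    "VARIANTS",
    "N_FREE_PARAMS",
    "SHARED_PARAM_NAMES",
    "to_polar",
    "to_cartesian",
    "xi_at_location",
    "sensitivity_at",
    "threshold_at",
    "make_variant",
    "pack_params",
]

VARIANTS = ("symmetric", "yoked", "luminance-only", "unconstrained")

#: Mechanism-shape parameters shared across visual field locations, in the
#: canonical packing order used by fitting and JSON serialization.
SHARED_PARAM_NAMES = (
    "zeta_lum",
    "n_lum_1",
    "n_lum_2",
    "tau_lum_1",
    "tau_lum_2",
    "zeta_rg",
    "n_rg_1",
    "n_rg_2",
    "tau_rg_1",
    "tau_rg_2",
    "theta",
)

#: Free-parameter counts of the four spatial variants.
N_FREE_PARAMS = {
    "symmetric": 17,
    "yoked": 18,
    "luminance-only": 18,
    "unconstrained": 19,
}


def to_polar(h, v):
    """Polar visual-field coordinates (r deg, phi rad) from (h, v) deg."""
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    r = np.hypot(h, v)
    phi = np.arctan2(v, h)
    if r.ndim:
        return r, phi
    return float(r), float(phi)


def to_cartesian(r, phi):
    """Inverse of :func:`to_polar`."""
    r = np.asarray(r, dtype=float)
    phi = np.asarray(phi, dtype=float)
    h, v = r * np.cos(phi), r * np.sin(phi)
    if h.ndim:
        return h, v
    return float(h), float(v)


@dataclass(frozen=True)
class FieldLocation:
    """A stimulus location in the visual field, degrees of visual angle.

    Mirror-symmetric left/right location pairs are treated as a single
    location; the canonical representative has h >= 0.
    """

    h: float
    v: float

    @classmethod
    def from_polar(cls, r: float, phi: float) -> "FieldLocation":
        h, v = to_cartesian(r, phi)
        return cls(h, v)

    @property
    def r(self) -> float:
        return to_polar(self.h, self.v)[0]

    @property
    def phi(self) -> float:
        return to_polar(self.h, self.v)[1]

    def canonical(self) -> "FieldLocation":
        return self if self.h >= 0 else FieldLocation(-self.h, self.v)


@dataclass(frozen=True)
class SpatialGain:
    """Coefficients of the log10 gain field of one mechanism.

    b0 is the log10 gain at the fovea; b1, b2, b3 are slopes per degree
    of eccentricity (radial, horizontal/vertical anisotropy, upper/lower
    asymmetry).
    """

    b0: float
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0

    def xi(self, r, phi):
        return xi_at_location(self, r, phi)


def xi_at_location(g: SpatialGain, r, phi):
    """Mechanism gain ``10**(b0 + b1 r + b2 r cos 2phi + b3 r sin 2phi)``."""
    r = np.asarray(r, dtype=float)
    phi = np.asarray(phi, dtype=float)
    log_xi = g.b0 + g.b1 * r + g.b2 * r * np.cos(2 * phi) + g.b3 * r * np.sin(2 * phi)
    out = 10.0**log_xi
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ObserverModel:
    """Full spatial observer: shared mechanism shapes plus two gain fields.

    The xi fields of the embedded temporal filters are unused (fixed at
    1); location-specific gains come from the SpatialGain fields.
    """

    mechanisms: MechanismSet
    lum_gain: SpatialGain
    rg_gain: SpatialGain
    variant: str = "yoked"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "symmetric":
            if self.lum_gain.b3 != 0.0 or self.rg_gain.b3 != 0.0:
                raise ValueError("symmetric variant requires b3 = 0 in both gains")
        elif self.variant == "yoked":
            if self.lum_gain.b3 != self.rg_gain.b3:
                raise ValueError("yoked variant requires a shared b3")
        elif self.variant == "luminance-only":
            if self.rg_gain.b3 != 0.0:
                raise ValueError("luminance-only variant requires rg b3 = 0")

    def mechanisms_at(self, r, phi) -> MechanismSet:
        """Mechanism set with gains evaluated at one location."""
        return MechanismSet(
            lum=self.mechanisms.lum.with_xi(xi_at_location(self.lum_gain, r, phi)),
            rg=self.mechanisms.rg.with_xi(xi_at_location(self.rg_gain, r, phi)),
            theta=self.mechanisms.theta,
        )


def sensitivity_at(obs: ObserverModel, direction, omega, r, phi):
    """Contrast sensitivity of the spatial model, vectorized over arrays.

    Each mechanism's magnitude response is scaled by its location-specific
    gain before the energy combination.
    """
    omega = np.asarray(omega, dtype=float)
    direction = np.asarray(direction, dtype=float)
    h_lum = np.abs(filter_response(obs.mechanisms.lum, omega)) * xi_at_location(
        obs.lum_gain, r, phi
    )
    h_rg = np.abs(filter_response(obs.mechanisms.rg, omega)) * xi_at_location(
        obs.rg_gain, r, phi
    )
    wl = obs.mechanisms.lum_weights
    wr = obs.mechanisms.rg_weights
    c_l, c_m = np.cos(direction), np.sin(direction)
    s = np.sqrt(
        (h_rg * (wr[0] * c_l + wr[1] * c_m)) ** 2
        + (h_lum * (wl[0] * c_l + wl[1] * c_m)) ** 2
    )
    return s if s.ndim else float(s)


def threshold_at(obs: ObserverModel, direction, omega, r, phi):
    """Threshold amplitude (reciprocal sensitivity) of the spatial model."""
    s = np.asarray(sensitivity_at(obs, direction, omega, r, phi))
    with np.errstate(divide="ignore"):
        t = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), np.inf)
    return t if t.ndim else float(t)


def make_variant(free_params, variant: str) -> ObserverModel:
    """Assemble an ObserverModel from a flat parameter vector.

    Layout: the 11 shared mechanism-shape parameters (see
    ``SHARED_PARAM_NAMES``), then b0, b1, b2 for LUM, b0, b1, b2 for RG,
    then the variant's b3 block (none / shared / LUM-only / both).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    p = np.asarray(free_params, dtype=float)
    expected = N_FREE_PARAMS[variant]
    if p.size != expected:
        raise ValueError(
            f"variant {variant!r} takes {expected} parameters, got {p.size}"
        )
    (zl, nl1, nl2, tl1, tl2, zr, nr1, nr2, tr1, tr2, theta) = p[:11]
    b_lum = p[11:14]
    b_rg = p[14:17]
    if variant == "symmetric":
        b3_lum = b3_rg = 0.0
    elif variant == "yoked":
        b3_lum = b3_rg = p[17]
    elif variant == "luminance-only":
        b3_lum, b3_rg = p[17], 0.0
    else:  # unconstrained
        b3_lum, b3_rg = p[17], p[18]
    mech = MechanismSet(
        lum=TemporalFilter(xi=1.0, zeta=zl, tau1=tl1, tau2=tl2, n1=nl1, n2=nl2),
        rg=TemporalFilter(xi=1.0, zeta=zr, tau1=tr1, tau2=tr2, n1=nr1, n2=nr2),
        theta=theta,
    )
    return ObserverModel(
        mechanisms=mech,
        lum_gain=SpatialGain(*b_lum, b3=b3_lum),
        rg_gain=SpatialGain(*b_rg, b3=b3_rg),
        variant=variant,
    )


def pack_params(obs: ObserverModel) -> np.ndarray:
    """Inverse of :func:`make_variant` for the model's own variant."""
    m = obs.mechanisms
    shared = [
        m.lum.zeta,
        m.lum.n1,
        m.lum.n2,
        m.lum.tau1,
        m.lum.tau2,
        m.rg.zeta,
        m.rg.n1,
        m.rg.n2,
        m.rg.tau1,
        m.rg.tau2,
        m.theta,
    ]
    spatial = [
        obs.lum_gain.b0,
        obs.lum_gain.b1,
        obs.lum_gain.b2,
        obs.rg_gain.b0,
        obs.rg_gain.b1,
        obs.rg_gain.b2,
    ]
    if obs.variant == "symmetric":
        tail = []
    elif obs.variant == "yoked":
        tail = [obs.lum_gain.b3]
    elif obs.variant == "luminance-only":
        tail = [obs.lum_gain.b3]
    else:
        tail = [obs.lum_gain.b3, obs.rg_gain.b3]
    return np.array(shared + spatial + tail)


def as_variant(obs: ObserverModel, variant: str) -> ObserverModel:
    """Re-tag a model under a (compatible) nesting variant."""
    return replace(obs, variant=variant)
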