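"""Ground-truth observer presets for the four study subjects.

Each preset is a full 18-parameter yoked observer: the shared temporal /
chromatic shape parameters of the LUM and RG mechanisms plus the spatial
gain fields of both.  Values are the published fitted parameters for two
macaque (M1, M2) and two human (H1, H2) observers, kept exactly as
printed (two significant figures in most entries; several time constants
and transience values sit on the fitting box at 1.00 or 0.00).
"""

from __future__ import annotations

from .field import ObserverModel, SpatialGain
from .filters import MechanismSet, TemporalFilter

__all__ = ["SUBJECTS", "SPECIES", "table2_preset", "preset_dict"]

SUBJECTS = ("M1", "M2", "H1", "H2")

#: Species of each subject: rhesus macaque (monkey) or human.
SPECIES = {"M1": "monkey", "M2": "monkey", "H1": "human", "H2": "human"}

_PRESETS: dict[str, dict[str, float]] = {
    "M1": dict(
        zeta_lum=0.56, n_lum_1=4.05, n_lum_2=5.45, tau_lum_1=5e-3, tau_lum_2=0.09,
        zeta_rg=0.15, n_rg_1=1.32, n_rg_2=4.74, tau_rg_1=0.03, tau_rg_2=1.00,
        theta=0.78,
        b0_lum=1.33, b1_lum=-0.03, b2_lum=5e-3,
        b0_rg=1.82, b1_rg=-0.06, b2_rg=0.013,
        b3=-6e-4,
    ),
    "M2": dict(
        zeta_lum=0.69, n_lum_1=2.87, n_lum_2=2.87, tau_lum_1=7e-3, tau_lum_2=0.13,
        zeta_rg=0.00, n_rg_1=1.32, n_rg_2=2.70, tau_rg_1=0.02, tau_rg_2=0.14,
        theta=0.80,
        b0_lum=1.51, b1_lum=-0.03, b2_lum=6e-3,
        b0_rg=1.66, b1_rg=-0.05, b2_rg=0.02,
        b3=1e-3,
    ),
    "H1": dict(
        zeta_lum=0.52, n_lum_1=3.86, n_lum_2=5.36, tau_lum_1=8e-3, tau_lum_2=0.35,
        zeta_rg=0.61, n_rg_1=1.80, n_rg_2=1.87, tau_rg_1=0.03, tau_rg_2=0.77,
        theta=0.49,
        b0_lum=1.59, b1_lum=-0.04, b2_lum=4e-3,
        b0_rg=2.30, b1_rg=-0.10, b2_rg=0.01,
        b3=-7e-3,
    ),
    "H2": dict(
        zeta_lum=0.42, n_lum_1=4.05, n_lum_2=9.03, tau_lum_1=6e-3, tau_lum_2=1.00,
        zeta_rg=0.40, n_rg_1=3.20, n_rg_2=3.45, tau_rg_1=0.01, tau_rg_2=1.00,
        theta=0.71,
        b0_lum=1.62, b1_lum=-0.05, b2_lum=8e-3,
        b0_rg=2.14, b1_rg=-0.12, b2_rg=0.03,
        b3=-1e-3,
    ),
}


def preset_dict(subject: str) -> dict[str, float]:
    """Raw parameter dictionary of one subject's preset."""
    try:
        return dict(_PRESETS[subject])
    except KeyError:
        raise ValueError(
            f"unknown subject {subject!r}; choose one of {SUBJECTS}"
        ) from None


def table2_preset(subject: str) -> ObserverModel:
    """Published 18-parameter yoked observer model for one subject."""
    p = preset_dict(subject)
    mech = MechanismSet(
        lum=TemporalFilter(
            xi=1.0, zeta=p["zeta_lum"], tau1=p["tau_lum_1"], tau2=p["tau_lum_2"],
            n1=p["n_lum_1"], n2=p["n_lum_2"],
        ),
        rg=TemporalFilter(
            xi=1.0, zeta=p["zeta_rg"], tau1=p["tau_rg_1"], tau2=p["tau_rg_2"],
            n1=p["n_rg_1"], n2=p["n_rg_2"],
        ),
        theta=p["theta"],
    )
    return ObserverModel(
        mechanisms=mech,
        lum_gain=SpatialGain(p["b0_lum"], p["b1_lum"], p["b2_lum"], b3=p["b3"]),
        rg_gain=SpatialGain(p["b0_rg"], p["b1_rg"], p["b2_rg"], b3=p["b3"]),
        variant="yoked",
    )
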