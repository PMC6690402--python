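"""Threshold-table and parameter-file I/O.

A threshold dataset is a pandas DataFrame with one row per threshold
measurement.  Internal columns (angles in radians):

    subject        observer label
    r_deg          eccentricity, degrees of visual angle
    phi_rad        polar angle from the horizontal meridian, radians
    color_dir_rad  color direction in the LM plane, radians in [0, pi)
    tf_hz          temporal frequency, Hz
    threshold      modulation amplitude at threshold (dimensionless)
    censored       1 if the threshold is a gamut-edge lower bound

On disk the same table uses degrees (``phi_deg``, ``color_dir_deg``) and
the column name ``amplitude``, which is friendlier to hand inspection.
Fitted models are serialized as flat JSON parameter dictionaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .field import ObserverModel, SpatialGain
from .filters import MechanismSet, TemporalFilter

__all__ = [
    "INTERNAL_COLUMNS",
    "thresholds_to_csv",
    "thresholds_from_csv",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

SCHEMA_VERSION = 1

INTERNAL_COLUMNS = [
    "subject",
    "r_deg",
    "phi_rad",
    "color_dir_rad",
    "tf_hz",
    "threshold",
    "censored",
]


def thresholds_to_csv(df: pd.DataFrame, path) -> None:
    """Write a threshold table with angles in degrees."""
    out = pd.DataFrame(
        {
            "subject": df["subject"],
            "r_deg": df["r_deg"],
            "phi_deg": np.degrees(df["phi_rad"]),
            "color_dir_deg": np.degrees(df["color_dir_rad"]),
            "tf_hz": df["tf_hz"],
            "amplitude": df["threshold"],
            "censored": df["censored"].astype(int),
        }
    )
    out.to_csv(path, index=False)


def thresholds_from_csv(path) -> pd.DataFrame:
    """Read a threshold table, converting angles to radians."""
    raw = pd.read_csv(path)
    return pd.DataFrame(
        {
            "subject": raw["subject"],
            "r_deg": raw["r_deg"].astype(float),
            "phi_rad": np.radians(raw["phi_deg"].astype(float)),
            "color_dir_rad": np.radians(raw["color_dir_deg"].astype(float)),
            "tf_hz": raw["tf_hz"].astype(float),
            "threshold": raw["amplitude"].astype(float),
            "censored": raw["censored"].astype(bool),
        }
    )


def model_to_dict(obs: ObserverModel, subject: str | None = None) -> dict:
    """Flat JSON-ready parameter dictionary of an observer model."""
    m = obs.mechanisms
    d = {
        "schema_version": SCHEMA_VERSION,
        "subject": subject,
        "variant": obs.variant,
        "zeta_lum": m.lum.zeta,
        "n_lum_1": m.lum.n1,
        "n_lum_2": m.lum.n2,
        "tau_lum_1": m.lum.tau1,
        "tau_lum_2": m.lum.tau2,
        "zeta_rg": m.rg.zeta,
        "n_rg_1": m.rg.n1,
        "n_rg_2": m.rg.n2,
        "tau_rg_1": m.rg.tau1,
        "tau_rg_2": m.rg.tau2,
        "theta": m.theta,
        "b0_lum": obs.lum_gain.b0,
        "b1_lum": obs.lum_gain.b1,
        "b2_lum": obs.lum_gain.b2,
        "b3_lum": obs.lum_gain.b3,
        "b0_rg": obs.rg_gain.b0,
        "b1_rg": obs.rg_gain.b1,
        "b2_rg": obs.rg_gain.b2,
        "b3_rg": obs.rg_gain.b3,
    }
    return d


def model_from_dict(d: dict) -> ObserverModel:
    """Rebuild an observer model from its parameter dictionary."""
    mech = MechanismSet(
        lum=TemporalFilter(
            xi=1.0, zeta=d["zeta_lum"], tau1=d["tau_lum_1"], tau2=d["tau_lum_2"],
            n1=d["n_lum_1"], n2=d["n_lum_2"],
        ),
        rg=TemporalFilter(
            xi=1.0, zeta=d["zeta_rg"], tau1=d["tau_rg_1"], tau2=d["tau_rg_2"],
            n1=d["n_rg_1"], n2=d["n_rg_2"],
        ),
        theta=d["theta"],
    )
    return ObserverModel(
        mechanisms=mech,
        lum_gain=SpatialGain(d["b0_lum"], d["b1_lum"], d["b2_lum"], d["b3_lum"]),
        rg_gain=SpatialGain(d["b0_rg"], d["b1_rg"], d["b2_rg"], d["b3_rg"]),
        variant=d.get("variant", "unconstrained"),
    )


def save_model(obs: ObserverModel, path, subject: str | None = None) -> None:
    Path(path).write_text(json.dumps(model_to_dict(obs, subject), indent=2))


def load_model(path) -> ObserverModel:
    return model_from_dict(json.loads(Path(path).read_text()))
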