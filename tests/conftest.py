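import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tcsfield as t

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def m1():
    return t.table2_preset("M1")


@pytest.fixture(scope="session")
def m2():
    return t.table2_preset("M2")


@pytest.fixture(scope="session")
def all_presets():
    return {s: t.table2_preset(s) for s in t.SUBJECTS}


def make_local_dataset(mech, n=60, seed=0, sigma=0.0, r=5.0, phi=0.0):
    """Noise-controlled single-location dataset from a mechanism set.

    ``mech`` carries its own gains (xi fields), so thresholds come from
    the location-free model.
    """
    rng = np.random.default_rng(seed)
    dirs = rng.uniform(0.02, np.pi - 0.02, size=n)
    tf = 10.0 ** rng.uniform(0.0, np.log10(60.0), size=n)
    thr = t.detection_threshold(mech, tf, dirs)
    thr = thr * 10.0 ** rng.normal(0.0, sigma, size=n)
    return pd.DataFrame(
        {
            "subject": "synthetic",
            "r_deg": r,
            "phi_rad": phi,
            "color_dir_rad": dirs,
            "tf_hz": tf,
            "threshold": thr,
            "censored": False,
        }
    )


@pytest.fixture(scope="session")
def m1_local_mechanisms(m1):
    """M1's mechanism set with the gains it has at (r=5, phi=0)."""
    return m1.mechanisms_at(5.0, 0.0)
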