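"""Synthetic threshold datasets emulating the study's measurements.

The raw subject data of the study are not packaged, so analyses run on
synthetic datasets drawn from the published ground-truth observer
presets.  The generator reproduces the shape of the real design:

* the per-subject measurement counts, split over opponent/nonopponent
  color directions crossed with low (<= 5 Hz) / high (> 5 Hz) temporal
  frequencies;
* a grid of visual-field locations spanning 2-14 degrees of
  eccentricity on and off the horizontal meridian (the vertical meridian
  is untestable in a left/right 2AFC design);
* multiplicative lognormal measurement noise on thresholds, default
  sigma = 0.10 log10 units, calibrated so the 10th/90th percentile
  spread of measured/predicted ratios matches the published 0.77/1.40;
* censoring at the display-gamut edge: thresholds beyond the gamut are
  recorded at the gamut limit and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .field import ObserverModel, threshold_at
from .presets import SUBJECTS, table2_preset  # noqa: F401  (re-exported)
from .stimulus import GamutModel, gamut_limit

__all__ = [
    "CELLS",
    "TABLE1_COUNTS",
    "NoiseModel",
    "DesignSpec",
    "default_locations",
    "default_design",
    "generate_thresholds",
    "generate_trialwise",
    "table2_preset",
]

#: Design cells: opponent/nonopponent color direction x low/high frequency.
CELLS = ("opponent_low", "nonopponent_low", "opponent_high", "nonopponent_high")

#: Published per-subject measurement counts per design cell
#: (total, opponent <=5 Hz, nonopponent <=5 Hz, opponent >5 Hz, nonopponent >5 Hz).
TABLE1_COUNTS = {
    "M1": (344, 56, 86, 69, 133),
    "M2": (724, 117, 193, 151, 263),
    "H1": (220, 35, 60, 39, 86),
    "H2": (272, 41, 77, 46, 108),
}

#: Frequency split between the low and high design cells, Hz.
CELL_SPLIT_HZ = 5.0


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal threshold noise.

    ``sigma_log10`` is the standard deviation of the additive Gaussian
    noise on log10 threshold; the noise is median-unbiased by
    construction.
    """

    sigma_log10: float = 0.10

    def __post_init__(self) -> None:
        if self.sigma_log10 < 0:
            raise ValueError("sigma_log10 must be nonnegative")


@dataclass(frozen=True)
class DesignSpec:
    """Locations and per-location condition counts of a measurement design.

    ``counts`` has shape (n_locations, 4) with columns ordered as in
    :data:`CELLS`.
    """

    locations: tuple[tuple[float, float], ...]  # (r_deg, phi_rad)
    counts: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.locations), len(CELLS)):
            raise ValueError("counts must have shape (n_locations, 4)")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell_totals(self) -> dict[str, int]:
        return {c: int(self.counts[:, i].sum()) for i, c in enumerate(CELLS)}


def default_locations(n_locations: int = 15) -> tuple[tuple[float, float], ...]:
    """Default visual-field grid: eccentricities 2-14 deg, three polar angles.

    Locations are canonical right-hemifield representatives; phi = 0 is
    the horizontal meridian, +/- pi/4 the upper and lower obliques.
    """
    n_r = int(np.ceil(n_locations / 3))
    rs = np.linspace(2.0, 14.0, n_r)
    phis = (-np.pi / 4, 0.0, np.pi / 4)
    locs = [(float(r), float(p)) for r in rs for p in phis]
    return tuple(locs[:n_locations])


def _spread_evenly(count: int, n: int) -> np.ndarray:
    """Split ``count`` into ``n`` integers differing by at most 1."""
    base, rem = divmod(count, n)
    out = np.full(n, base, dtype=int)
    out[:rem] += 1
    return out


def default_design(
    subject: str, n_locations: int = 15, total: int | None = None
) -> DesignSpec:
    """Design emulating one subject's published measurement counts.

    Cell totals follow the subject's published row; if ``total`` is
    given, cell counts are rescaled proportionally to that total.  Each
    cell's count is spread over the location grid as evenly as possible
    (per-location counts differ by at most 1).
    """
    if subject not in TABLE1_COUNTS:
        raise ValueError(f"unknown subject {subject!r}; choose one of {SUBJECTS}")
    _, *cells = TABLE1_COUNTS[subject]
    cells = np.asarray(cells, dtype=float)
    if total is not None:
        scaled = cells * (total / cells.sum())
        cells = np.floor(scaled).astype(int)
        # distribute the rounding remainder by largest fractional part
        rem = total - cells.sum()
        order = np.argsort(-(scaled - np.floor(scaled)))
        cells[order[: int(rem)]] += 1
    locs = default_locations(n_locations)
    counts = np.stack(
        [_spread_evenly(int(c), len(locs)) for c in cells.astype(int)], axis=1
    )
    return DesignSpec(locations=locs, counts=counts)


def _sample_cell_conditions(cell: str, n: int, rng: np.random.Generator):
    """Directions and frequencies for ``n`` conditions of one design cell.

    Opponent stimuli (L- and M-cone modulations of opposite sign) have
    directions in (pi/2, pi); nonopponent in (0, pi/2).  Frequencies are
    log-uniform within the cell's band, mirroring the nearly continuous
    distribution of tested conditions.
    """
    opp = cell.startswith("opponent")
    lo, hi = (np.pi / 2, np.pi) if opp else (0.0, np.pi / 2)
    margin = 0.02 * (hi - lo)
    direction = rng.uniform(lo + margin, hi - margin, size=n)
    if cell.endswith("low"):
        f_lo, f_hi = 1.0, CELL_SPLIT_HZ
    else:
        f_lo, f_hi = CELL_SPLIT_HZ, 60.0
    tf = 10.0 ** rng.uniform(np.log10(f_lo), np.log10(f_hi), size=n)
    return direction, tf


def generate_thresholds(
    obs: ObserverModel,
    design: DesignSpec,
    noise: NoiseModel = NoiseModel(),
    gamut: GamutModel = GamutModel(),
    seed: int | np.random.Generator = 0,
    subject: str = "synthetic",
) -> pd.DataFrame:
    """Draw a threshold dataset from a ground-truth observer.

    Each designed condition yields ``model threshold x 10**eps`` with
    ``eps ~ N(0, sigma_log10^2)``; draws beyond the display gamut are
    recorded at the gamut limit with ``censored = True``.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (r, phi), loc_counts in zip(design.locations, design.counts):
        for cell, n in zip(CELLS, loc_counts):
            if n == 0:
                continue
            direction, tf = _sample_cell_conditions(cell, int(n), rng)
            true_thr = threshold_at(obs, direction, tf, r, phi)
            eps = rng.normal(0.0, noise.sigma_log10, size=int(n))
            thr = true_thr * 10.0**eps
            limit = gamut_limit(gamut, direction)
            censored = thr > limit
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "r_deg": r,
                        "phi_rad": phi,
                        "color_dir_rad": direction,
                        "tf_hz": tf,
                        "threshold": np.where(censored, limit, thr),
                        "censored": censored,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_trialwise(
    obs: ObserverModel,
    design: DesignSpec,
    seed: int = 0,
    gamut: GamutModel = GamutModel(),
    slope: float = 3.0,
    lapse: float = 0.01,
    n_trials: int = 40,
):
    """Trial-level simulation: adaptive sessions at every design location.

    Runs the full 2AFC protocol (corner conditions, Gaussian-process
    condition placement, 40-trial adaptive staircases) with the given
    observer as ground truth.  Slower but higher-fidelity than
    :func:`generate_thresholds`.  Returns ``(trial_log, thresholds)``.
    """
    from .adaptive import PsychometricObserver, run_session

    rng = np.random.default_rng(seed)
    psy = PsychometricObserver(model=obs, slope=slope, lapse_rate=lapse)
    logs, thrs = [], []
    for i, ((r, phi), loc_counts) in enumerate(
        zip(design.locations, design.counts)
    ):
        n_conditions = int(loc_counts.sum())
        if n_conditions == 0:
            continue
        log, meas = run_session(
            psy,
            r=r,
            phi=phi,
            n_conditions=n_conditions,
            rng=rng,
            gamut=gamut,
            n_trials=n_trials,
            session=i,
        )
        logs.append(log)
        thrs.append(meas)
    return (
        pd.concat(logs, ignore_index=True),
        pd.concat(thrs, ignore_index=True),
    )
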