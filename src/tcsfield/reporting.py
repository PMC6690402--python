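"""Residual diagnostics, sensitivity curves, and the species comparison.

Residuals are log10(measured threshold) - log10(predicted threshold);
their exponentiated form, the measured/predicted ratio, is what the
summaries report.  Censored (gamut-edge) measurements are excluded from
every residual analysis because they are bounds, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .field import ObserverModel, sensitivity_at
from .fitting import predict_thresholds

__all__ = [
    "BinSpec",
    "residuals",
    "residual_summary",
    "residual_autocorrelation_map",
    "median_residual_by_location",
    "species_comparison",
    "tcsf_curves",
]


def residuals(data: pd.DataFrame, model: ObserverModel) -> pd.DataFrame:
    """One residual record per uncensored measurement.

    Adds ``predicted``, ``residual`` (log10 units) and ``ratio``
    (= 10**residual) columns to a copy of the uncensored rows.
    """
    pred = predict_thresholds(model, data)
    out = data.loc[~data["censored"].astype(bool)].copy()
    out["predicted"] = pred[~data["censored"].astype(bool).to_numpy()]
    out["residual"] = np.log10(out["threshold"]) - np.log10(out["predicted"])
    out["ratio"] = 10.0 ** out["residual"]
    return out.reset_index(drop=True)


def residual_summary(res: pd.DataFrame) -> dict:
    """Median and 10th/90th percentile of measured/predicted ratios.

    Quantiles use the linear-interpolation rule between order statistics.
    With fewer than 10 records the percentiles are reported as None.
    """
    ratios = res["ratio"].to_numpy(float)
    if ratios.size == 0:
        raise ValueError("no residual records")
    out = {"median_ratio": float(np.median(ratios)), "n": int(ratios.size)}
    if ratios.size >= 10:
        out["p10_ratio"] = float(np.quantile(ratios, 0.10))
        out["p90_ratio"] = float(np.quantile(ratios, 0.90))
    else:
        out["p10_ratio"] = out["p90_ratio"] = None
    return out


@dataclass(frozen=True)
class BinSpec:
    """Binning of the (color direction x temporal frequency) plane.

    Frequency bins span each nominal centre times/divided by
    ``freq_factor``; direction bins span the nominal direction +/-
    ``dir_halfwidth_deg``.  The default non-overlapping nominal grids
    tile the tested ranges.
    """

    freq_centers: tuple = tuple(np.logspace(0, np.log10(60.0), 10))
    freq_factor: float = 1.5
    dir_centers_deg: tuple = tuple(np.arange(10.0, 180.0, 20.0))
    dir_halfwidth_deg: float = 10.0

    def freq_bin(self, tf) -> np.ndarray:
        """Index of the nominal frequency bin containing each value, or -1."""
        tf = np.asarray(tf, dtype=float)
        out = np.full(tf.shape, -1, dtype=int)
        for i, c in enumerate(self.freq_centers):
            m = (tf >= c / self.freq_factor) & (tf <= c * self.freq_factor)
            out[m & (out == -1)] = i
        return out

    def dir_bin(self, direction_rad) -> np.ndarray:
        """Index of the direction bin (circular, period pi), or -1."""
        d = np.degrees(np.mod(direction_rad, np.pi))
        out = np.full(d.shape if np.ndim(d) else (), -1, dtype=int)
        d = np.atleast_1d(d)
        out = np.atleast_1d(out)
        for i, c in enumerate(self.dir_centers_deg):
            delta = np.abs((d - c + 90.0) % 180.0 - 90.0)
            out[(delta <= self.dir_halfwidth_deg) & (out == -1)] = i
        return out


def _median_map(res: pd.DataFrame, bins: BinSpec) -> np.ndarray:
    fb = bins.freq_bin(res["tf_hz"].to_numpy())
    db = bins.dir_bin(res["color_dir_rad"].to_numpy())
    nf, nd = len(bins.freq_centers), len(bins.dir_centers_deg)
    grid = np.full((nd, nf), np.nan)
    for i in range(nd):
        for j in range(nf):
            m = (db == i) & (fb == j)
            if m.any():
                grid[i, j] = np.median(res["residual"].to_numpy()[m])
    return grid


def residual_autocorrelation_map(
    res: pd.DataFrame, bins: BinSpec = BinSpec()
) -> dict:
    """2-D autocorrelation of the binned median-residual map.

    Residuals are pooled over visual-field locations, median-binned on
    the direction x log-frequency grid, and autocorrelated in Pearson
    form: the map mean is subtracted, products are averaged pairwise-
    complete over non-empty bins, and the result is normalized by the
    map variance, so the zero-lag value is exactly 1.  The direction
    axis is circular with period pi (it wraps); the frequency axis is
    not.  Returns the correlation map, the per-lag pair counts, and the
    lag grids.
    """
    grid = _median_map(res, bins)
    valid = ~np.isnan(grid)
    if valid.sum() < 2:
        raise ValueError("need at least two non-empty bins")
    mu = np.nanmean(grid)
    var = np.nanmean((grid - mu) ** 2)
    centered = np.where(valid, grid - mu, 0.0)
    nd, nf = grid.shape
    freq_lags = np.arange(-(nf - 1), nf)
    dir_lags = np.arange(-(nd // 2), nd - nd // 2)
    corr = np.full((dir_lags.size, freq_lags.size), np.nan)
    counts = np.zeros_like(corr, dtype=int)
    for a, dl in enumerate(dir_lags):
        rolled = np.roll(centered, dl, axis=0)
        rolled_valid = np.roll(valid, dl, axis=0)
        for b, fl in enumerate(freq_lags):
            if fl >= 0:
                x = centered[:, fl:] * rolled[:, : nf - fl]
                v = rolled_valid[:, : nf - fl] & valid[:, fl:]
            else:
                x = centered[:, :fl] * rolled[:, -fl:]
                v = rolled_valid[:, -fl:] & valid[:, :fl]
            n = int(v.sum())
            counts[a, b] = n
            if n > 0 and var > 0:
                corr[a, b] = float(x[v].sum() / n / var)
    return {
        "corr": corr,
        "counts": counts,
        "dir_lags": dir_lags,
        "freq_lags": freq_lags,
    }


def median_residual_by_location(res: pd.DataFrame) -> pd.DataFrame:
    """Median measured/predicted ratio at each canonical location."""
    out = (
        res.groupby(["r_deg", "phi_rad"])["ratio"]
        .median()
        .rename("median_ratio")
        .reset_index()
    )
    out["log_median_ratio"] = np.log10(out["median_ratio"])
    return out


def species_comparison(
    datasets: dict[str, pd.DataFrame],
    species: dict[str, str],
    band: tuple[float, float] = (1.0, 1.5),
    statistic: str = "mean",
) -> dict:
    """Normalized sensitivity comparison between species in a frequency band.

    Sensitivities (reciprocal uncensored thresholds, log10 units) are
    normalized within each (subject, location) by subtracting that set's
    own mean (or max) log sensitivity, then pooled across locations.
    Treating subject as a random effect with a between-subject species
    contrast, the test aggregates the band's normalized values to one
    mean per subject and compares species on those subject means (the
    balanced mixed-model F-test reduces to exactly this two-sample
    comparison); the t-test itself is delegated to scipy.
    """
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")
    frames = []
    for subject, df in datasets.items():
        d = df.loc[~df["censored"].astype(bool)].copy()
        d["log_sens"] = -np.log10(d["threshold"])
        agg = {"mean": "mean", "max": "max"}[statistic]
        ref = d.groupby(["r_deg", "phi_rad"])["log_sens"].transform(agg)
        d["norm_log_sens"] = d["log_sens"] - ref
        d["subject"] = subject
        d["species"] = species[subject]
        frames.append(d)
    pooled = pd.concat(frames, ignore_index=True)
    lo, hi = band
    in_band = pooled[(pooled["tf_hz"] >= lo) & (pooled["tf_hz"] <= hi)]
    if len(in_band) == 0:
        raise ValueError(f"no measurements in the {lo}-{hi} Hz band")
    if in_band["species"].nunique() < 2:
        raise ValueError("need measurements from both species in the band")
    table = (
        in_band.groupby(["species", "subject"])["norm_log_sens"]
        .agg(["mean", "median", "count"])
        .reset_index()
    )
    from scipy import stats

    subj_means = table.set_index("species")["mean"]
    human = subj_means.loc[["human"]].to_numpy(float)
    monkey = subj_means.loc[["monkey"]].to_numpy(float)
    tt = stats.ttest_ind(human, monkey)
    return {
        "table": table,
        "band_hz": band,
        "species_effect": float(human.mean() - monkey.mean()),
        "p_value": float(tt.pvalue),
        "n": int(len(in_band)),
    }


def tcsf_curves(
    obs: ObserverModel,
    r: float,
    phi: float,
    directions=(np.pi / 4, 3 * np.pi / 4),
    freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Temporal contrast sensitivity curves of a model at one location.

    Sensitivity sampled on a log-frequency grid (default 1-60 Hz) for
    each requested color direction; rows are (direction, tf, sensitivity).
    """
    if freqs is None:
        freqs = np.logspace(0.0, np.log10(60.0), 100)
    rows = []
    for d in directions:
        s = sensitivity_at(obs, d, freqs, r, phi)
        rows.append(
            pd.DataFrame(
                {"color_dir_rad": d, "tf_hz": freqs, "sensitivity": s}
            )
        )
    return pd.concat(rows, ignore_index=True)
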