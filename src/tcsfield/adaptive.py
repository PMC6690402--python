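"""Simulation of the adaptive 2AFC threshold-measurement protocol.

Thresholds in the study were measured with a spatial two-alternative
forced-choice task driven by two adaptive loops:

* within a condition, a QUEST staircase maintains a Bayesian posterior
  over the log threshold and places each of 40 trials at the posterior
  mode; the mode after 40 trials is the threshold estimate;
* across conditions, a Gaussian-process surrogate over (log temporal
  frequency, color direction) with a Matern x periodic covariance picks
  the next condition where the predictive uncertainty is largest,
  skipping conditions whose predicted threshold lies outside the display
  gamut.  Each session starts from the four corner conditions
  (1 and 60 Hz crossed with the L+M and L-M diagonals).

The simulated observer answers 2AFC trials through a Weibull
psychometric function whose threshold comes from a ground-truth
observer model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize

from .field import ObserverModel, threshold_at
from .stimulus import GamutModel, LUM_AXIS, RG_AXIS, gamut_limit

__all__ = [
    "PsychometricObserver",
    "QuestState",
    "GpSurrogate",
    "weibull_p_correct",
    "simulate_trial",
    "quest_init",
    "quest_update",
    "quest_recommend",
    "quest_threshold",
    "run_quest",
    "gp_fit",
    "select_next_condition",
    "candidate_grid",
    "run_session",
    "CORNER_CONDITIONS",
]

#: First four conditions of every session: (temporal frequency Hz, direction).
CORNER_CONDITIONS = (
    (1.0, LUM_AXIS),
    (1.0, RG_AXIS),
    (60.0, LUM_AXIS),
    (60.0, RG_AXIS),
)


def weibull_p_correct(amplitude, threshold, slope, guess=0.5, lapse=0.01):
    """2AFC Weibull psychometric function.

    ``guess + (1 - guess - lapse) * (1 - exp(-(x / threshold)**slope))``;
    at zero amplitude performance is the guess rate, at high amplitude it
    saturates at ``1 - lapse``.  The threshold parameter sits at the
    63.2% point of the underlying Weibull cdf.
    """
    x = np.asarray(amplitude, dtype=float)
    f = 1.0 - np.exp(-np.power(np.maximum(x, 0.0) / threshold, slope))
    p = guess + (1.0 - guess - lapse) * f
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class PsychometricObserver:
    """Simulated 2AFC observer with a ground-truth threshold surface."""

    model: ObserverModel
    slope: float = 3.0
    guess_rate: float = 0.5
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse rate must lie in [0, 0.1]")

    def true_threshold(self, direction, tf, r, phi):
        return threshold_at(self.model, direction, tf, r, phi)

    def p_correct(self, amplitude, direction, tf, r, phi):
        thr = self.true_threshold(direction, tf, r, phi)
        return weibull_p_correct(
            amplitude, thr, self.slope, self.guess_rate, self.lapse_rate
        )


def simulate_trial(
    obs: PsychometricObserver,
    amplitude: float,
    direction: float,
    tf: float,
    r: float,
    phi: float,
    rng: np.random.Generator,
) -> bool:
    """Draw one 2AFC outcome (True = correct)."""
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    p = obs.p_correct(amplitude, direction, tf, r, phi)
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# QUEST


@dataclass(frozen=True)
class QuestState:
    """Posterior over log10 threshold maintained by the QUEST staircase."""

    grid: np.ndarray  # log10 threshold values
    log_posterior: np.ndarray  # unnormalized log posterior mass
    trial_count: int
    slope: float = 3.0
    guess: float = 0.5
    lapse: float = 0.01

    @property
    def posterior(self) -> np.ndarray:
        p = np.exp(self.log_posterior - self.log_posterior.max())
        return p / p.sum()


def quest_init(
    prior_center: float,
    prior_sigma: float = 0.5,
    half_width: float = 2.0,
    n_grid: int = 200,
    slope: float = 3.0,
    guess: float = 0.5,
    lapse: float = 0.01,
) -> QuestState:
    """Fresh staircase with a lognormal prior centred on ``prior_center``.

    ``prior_sigma`` and ``half_width`` are in decades of threshold.
    """
    c = np.log10(prior_center)
    grid = np.linspace(c - half_width, c + half_width, n_grid)
    log_prior = -0.5 * ((grid - c) / prior_sigma) ** 2
    return QuestState(
        grid=grid,
        log_posterior=log_prior,
        trial_count=0,
        slope=slope,
        guess=guess,
        lapse=lapse,
    )


def quest_update(q: QuestState, amplitude: float, correct: bool) -> QuestState:
    """Multiply the posterior by one trial's likelihood.

    The likelihood assumes the same Weibull shape the staircase was
    built with.  Updates run in log space, so posterior underflow cannot
    occur even after long runs.
    """
    p = weibull_p_correct(amplitude, 10.0**q.grid, q.slope, q.guess, q.lapse)
    like = p if correct else 1.0 - p
    log_post = q.log_posterior + np.log(np.maximum(like, 1e-300))
    log_post = log_post - log_post.max()  # renormalize in log space
    return replace(q, log_posterior=log_post, trial_count=q.trial_count + 1)


@lru_cache(maxsize=32)
def _sweet_offset(slope: float, guess: float, lapse: float) -> float:
    """Log10 offset from threshold to the most informative test amplitude.

    Maximizes the per-trial Fisher information about log threshold,
    psi'(x)^2 / (psi (1 - psi)), of the assumed Weibull over test
    amplitude.  For a 2AFC Weibull with slope 3 the optimum sits just
    above threshold (about 1.19x).
    """
    x = np.logspace(-1.0, 1.0, 2001)
    u = x**slope
    span = 1.0 - guess - lapse
    psi = guess + span * (1.0 - np.exp(-u))
    dpsi = span * slope * np.log(10.0) * u * np.exp(-u)
    info = dpsi**2 / np.maximum(psi * (1.0 - psi), 1e-12)
    return float(np.log10(x[int(np.argmax(info))]))


def quest_recommend(q: QuestState) -> float:
    """Amplitude for the next trial.

    The staircase places trials at the most informative amplitude for
    the current posterior: the posterior mean of log10 threshold shifted
    by the assumed psychometric function's sweet point (the amplitude
    maximizing per-trial Fisher information, about 1.19x threshold for
    the default 2AFC Weibull).  Mean placement is the ZEST refinement of
    the classic staircase; it is noticeably more efficient than placing
    at the posterior mode and leaves the threshold readout unchanged.
    """
    post = q.posterior
    center = float(post @ q.grid)
    return float(10.0 ** (center + _sweet_offset(q.slope, q.guess, q.lapse)))


def quest_threshold(q: QuestState, protocol_trials: int = 40) -> float:
    """Threshold estimate: posterior mode mapped back from log10 units.

    The protocol reads the mode after 40 trials; other counts are allowed
    but flagged with a warning.  With a multimodal posterior the lowest
    amplitude mode is returned.
    """
    if q.trial_count != protocol_trials:
        import warnings

        warnings.warn(
            f"threshold read after {q.trial_count} trials "
            f"(protocol uses {protocol_trials})",
            stacklevel=2,
        )
    post = q.posterior
    peak = post.max()
    modes = np.flatnonzero(np.isclose(post, peak, rtol=1e-9, atol=0.0))
    return float(10.0 ** q.grid[modes[0]])


def run_quest(
    obs: PsychometricObserver,
    direction: float,
    tf: float,
    r: float,
    phi: float,
    prior_center: float,
    rng: np.random.Generator,
    n_trials: int = 40,
    max_amplitude: float | None = None,
    **quest_kw,
) -> tuple[float, pd.DataFrame]:
    """One full staircase; returns (threshold estimate, trial log)."""
    q = quest_init(prior_center, slope=obs.slope, guess=obs.guess_rate,
                   lapse=obs.lapse_rate, **quest_kw)
    rows = []
    for t in range(n_trials):
        amp = quest_recommend(q)
        if max_amplitude is not None:
            amp = min(amp, max_amplitude)
        correct = simulate_trial(obs, amp, direction, tf, r, phi, rng)
        q = quest_update(q, amp, correct)
        rows.append((t, amp, int(correct)))
    log = pd.DataFrame(rows, columns=["trial", "amplitude", "correct"])
    return quest_threshold(q, protocol_trials=n_trials), log


# ---------------------------------------------------------------------------
# Gaussian-process surrogate over (log frequency, color direction)


def _matern52(d):
    a = np.sqrt(5.0) * d
    return (1.0 + a + a**2 / 3.0) * np.exp(-a)


def _kernel(x1, x2, amp, ls_f, ls_d):
    """Product kernel: Matern-5/2 in log frequency x pi-periodic in direction.

    The periodic factor is the exponential-sine-squared kernel with
    period pi, because a color direction and its antipode are the same
    stimulus.
    """
    df = np.abs(x1[:, None, 0] - x2[None, :, 0]) / ls_f
    dd = x1[:, None, 1] - x2[None, :, 1]
    per = np.exp(-2.0 * np.sin(dd) ** 2 / ls_d**2)  # sin(pi * dd / pi)
    return amp * _matern52(df) * per


@dataclass(frozen=True)
class GpSurrogate:
    """Gaussian-process model of log10 threshold over the condition plane.

    Inputs are (log10 temporal frequency, color direction); the target is
    log10 threshold.  Hyperparameters: signal variance ``amp``, length
    scales ``ls_f`` (decades) and ``ls_d`` (radians, of the periodic
    factor), noise variance ``noise``.
    """

    x_train: np.ndarray
    y_train: np.ndarray
    amp: float
    ls_f: float
    ls_d: float
    noise: float
    y_mean: float

    def _chol(self):
        k = _kernel(self.x_train, self.x_train, self.amp, self.ls_f, self.ls_d)
        k[np.diag_indices_from(k)] += self.noise + 1e-10
        return np.linalg.cholesky(k)

    def predict(self, x_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and standard deviation at query conditions."""
        x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
        chol = self._chol()
        ks = _kernel(self.x_train, x_star, self.amp, self.ls_f, self.ls_d)
        alpha = np.linalg.solve(
            chol.T, np.linalg.solve(chol, self.y_train - self.y_mean)
        )
        mean = self.y_mean + ks.T @ alpha
        v = np.linalg.solve(chol, ks)
        var = self.amp - np.sum(v**2, axis=0)
        return mean, np.sqrt(np.maximum(var, 0.0))


def _nll(log_params, x, y):
    amp, ls_f, ls_d, noise = np.exp(log_params)
    n = x.shape[0]
    k = _kernel(x, x, amp, ls_f, ls_d)
    k[np.diag_indices_from(k)] += noise + 1e-10
    try:
        chol = np.linalg.cholesky(k)
    except np.linalg.LinAlgError:
        return 1e10
    alpha = np.linalg.solve(chol.T, np.linalg.solve(chol, y))
    return float(
        0.5 * y @ alpha + np.sum(np.log(np.diag(chol))) + 0.5 * n * np.log(2 * np.pi)
    )


def gp_fit(
    conditions: np.ndarray,
    log_thresholds: np.ndarray,
    n_restarts: int = 3,
    seed: int = 0,
    noise_floor: float = 1e-6,
) -> GpSurrogate:
    """Maximum-marginal-likelihood fit of the surrogate.

    ``conditions`` has rows (log10 tf, direction).  Hyperparameters are
    optimized by L-BFGS on their logs from a few spread starting points.
    Needs at least the four corner conditions to be meaningful.
    """
    x = np.atleast_2d(np.asarray(conditions, dtype=float))
    y = np.asarray(log_thresholds, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 training conditions")
    y_mean = float(y.mean())
    yc = y - y_mean
    rng = np.random.default_rng(seed)
    base = np.log([max(yc.var(), 1e-4), 1.0, 1.0, 1e-2])
    best, best_val = base, _nll(base, x, yc)
    starts = [base] + [
        base + rng.normal(0.0, 0.7, size=4) for _ in range(n_restarts - 1)
    ]
    lb = np.log([1e-6, 0.05, 0.05, noise_floor])
    ub = np.log([1e2, 10.0, 20.0, 1.0])
    for x0 in starts:
        res = optimize.minimize(
            _nll,
            np.clip(x0, lb, ub),
            args=(x, yc),
            method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
        )
        if res.fun < best_val:
            best, best_val = res.x, float(res.fun)
    amp, ls_f, ls_d, noise = np.exp(best)
    return GpSurrogate(
        x_train=x, y_train=y, amp=amp, ls_f=ls_f, ls_d=ls_d, noise=noise,
        y_mean=y_mean,
    )


def candidate_grid(
    n_directions: int = 16, n_frequencies: int = 12
) -> np.ndarray:
    """Default candidate conditions: directions x log-spaced frequencies."""
    dirs = np.arange(n_directions) * np.pi / n_directions
    freqs = np.logspace(0.0, np.log10(60.0), n_frequencies)
    tf, dd = np.meshgrid(freqs, dirs, indexing="ij")
    return np.column_stack([tf.ravel(), dd.ravel()])  # (tf_hz, direction)


def select_next_condition(
    gp: GpSurrogate,
    gamut: GamutModel,
    candidates: np.ndarray,
) -> tuple[float, float] | None:
    """Most uncertain in-gamut candidate condition, or None to stop.

    Candidates whose GP-predicted threshold exceeds the gamut limit in
    their direction are excluded.  Ties in predictive standard deviation
    break deterministically toward the lowest temporal frequency, then
    the lowest direction, so the choice is invariant to candidate order.
    """
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    if cand.size == 0:
        return None
    x_star = np.column_stack([np.log10(cand[:, 0]), cand[:, 1]])
    mean, sd = gp.predict(x_star)
    limit = gamut_limit(gamut, cand[:, 1])
    ok = 10.0**mean <= limit
    if not np.any(ok):
        return None
    order = np.lexsort((cand[:, 1], cand[:, 0], -np.round(sd, 12)))
    for i in order:
        if ok[i]:
            return float(cand[i, 0]), float(cand[i, 1])
    return None


def run_session(
    obs: PsychometricObserver,
    r: float,
    phi: float,
    n_conditions: int = 25,
    rng: np.random.Generator | int = 0,
    gamut: GamutModel = GamutModel(),
    n_trials: int = 40,
    generic_prior: float = 0.01,
    candidates: np.ndarray | None = None,
    session: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one location's measurement session.

    The four corner conditions run first with a generic staircase prior;
    subsequent conditions are placed by the Gaussian-process loop, each
    staircase prior centred on the GP prediction.  A measurement is
    censored at the gamut edge when the observer's true threshold lies
    beyond the display gamut.  Returns ``(trial_log, thresholds)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if candidates is None:
        candidates = candidate_grid()
    log_rows, meas_rows = [], []
    tested: list[tuple[float, float]] = []
    observed: list[float] = []

    def measure(tf, direction, prior_center):
        limit = gamut_limit(gamut, direction)
        est, trials = run_quest(
            obs, direction, tf, r, phi,
            prior_center=min(prior_center, limit),
            rng=rng, n_trials=n_trials, max_amplitude=limit,
        )
        true_thr = obs.true_threshold(direction, tf, r, phi)
        censored = bool(true_thr > limit)
        amplitude = limit if censored else min(est, limit)
        trials = trials.assign(
            session=session, r_deg=r, phi_deg=np.degrees(phi),
            color_dir_deg=np.degrees(direction), tf_hz=tf,
        )
        log_rows.append(trials)
        meas_rows.append(
            dict(
                subject="session",
                r_deg=r,
                phi_rad=phi,
                color_dir_rad=direction,
                tf_hz=tf,
                threshold=amplitude,
                censored=censored,
            )
        )
        tested.append((tf, direction))
        observed.append(np.log10(amplitude))

    for tf, direction in CORNER_CONDITIONS[: min(4, n_conditions)]:
        measure(tf, direction, generic_prior)
    while len(meas_rows) < n_conditions:
        gp = gp_fit(
            np.column_stack(
                [np.log10([t for t, _ in tested]), [d for _, d in tested]]
            ),
            np.array(observed),
            seed=len(tested),
        )
        # drop already-tested candidates
        cand = np.array(
            [
                c
                for c in candidates
                if not any(
                    np.isclose(c[0], t) and np.isclose(c[1], d)
                    for t, d in tested
                )
            ]
        )
        nxt = select_next_condition(gp, gamut, cand)
        if nxt is None:
            break  # protocol stop: nothing left inside the gamut
        tf, direction = nxt
        prior = 10.0 ** gp.predict(
            np.array([[np.log10(tf), direction]])
        )[0][0]
        measure(tf, direction, prior)
    trial_log = (
        pd.concat(log_rows, ignore_index=True)
        if log_rows
        else pd.DataFrame(
            columns=["trial", "amplitude", "correct", "session", "r_deg",
                     "phi_deg", "color_dir_deg", "tf_hz"]
        )
    )
    trial_log = trial_log[
        ["session", "trial", "r_deg", "phi_deg", "color_dir_deg", "tf_hz",
         "amplitude", "correct"]
    ]
    return trial_log, pd.DataFrame(meas_rows)
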