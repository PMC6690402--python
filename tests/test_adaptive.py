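"""Simulated 2AFC observer, QUEST staircase, GP condition placement."""

import numpy as np
import pytest

import tcsfield as t
from tcsfield.adaptive import (
    CORNER_CONDITIONS,
    GpSurrogate,
    PsychometricObserver,
    _kernel,
    candidate_grid,
    gp_fit,
    quest_init,
    quest_recommend,
    quest_threshold,
    quest_update,
    run_quest,
    run_session,
    select_next_condition,
    simulate_trial,
    weibull_p_correct,
)
from tcsfield.stimulus import GamutModel, gamut_limit


class _FixedThresholdObserver:
    """Observer with a constant true threshold (no spatial model)."""

    slope = 3.0
    guess_rate = 0.5
    lapse_rate = 0.01

    def __init__(self, threshold=0.05):
        self.threshold = threshold

    def true_threshold(self, *args):
        return self.threshold

    def p_correct(self, amplitude, *args):
        return weibull_p_correct(
            amplitude, self.threshold, self.slope, self.guess_rate,
            self.lapse_rate,
        )


class TestPsychometricFunction:
    def test_guess_rate_at_zero_amplitude(self):
        assert weibull_p_correct(0.0, 0.05, 3.0, 0.5, 0.01) == pytest.approx(0.5)

    def test_ceiling_at_high_amplitude(self):
        assert weibull_p_correct(5.0, 0.05, 3.0, 0.5, 0.01) == pytest.approx(
            0.99, abs=1e-9
        )

    def test_monotone_in_amplitude(self):
        amps = np.linspace(0, 0.3, 100)
        p = weibull_p_correct(amps, 0.05, 3.0)
        assert np.all(np.diff(p) >= 0)

    def test_monte_carlo_matches_closed_form_at_threshold(self):
        """Empirical P(correct) at threshold matches the Weibull value."""
        obs = _FixedThresholdObserver(0.05)
        rng = np.random.default_rng(0)
        n = 10_000
        hits = sum(
            simulate_trial(obs, 0.05, 0.5, 4.0, 5.0, 0.0, rng)
            for _ in range(n)
        )
        expected = weibull_p_correct(0.05, 0.05, 3.0, 0.5, 0.01)
        assert hits / n == pytest.approx(expected, abs=3 * 0.5 / np.sqrt(n))

    def test_invalid_lapse_rejected(self, m1):
        with pytest.raises(ValueError):
            PsychometricObserver(model=m1, lapse_rate=0.5)


class TestQuest:
    def test_fresh_staircase_recommends_near_prior_center(self):
        q = quest_init(0.02)
        # symmetric prior: posterior mean is the center; placement sits at
        # the documented sweet-point multiple (~1.19x) above it
        assert quest_recommend(q) == pytest.approx(0.02 * 1.19, rel=0.02)

    def test_posterior_is_proper_after_updates(self):
        q = quest_init(0.05)
        rng = np.random.default_rng(1)
        for _ in range(60):
            amp = quest_recommend(q)
            q = quest_update(q, amp, bool(rng.random() < 0.7))
            assert q.posterior.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(q.posterior >= 0)

    def test_incorrect_at_high_amplitude_shifts_mode_up(self):
        q = quest_init(0.05)
        mode_before = q.grid[np.argmax(q.posterior)]
        q = quest_update(q, 0.5, False)
        mode_after = q.grid[np.argmax(q.posterior)]
        assert mode_after >= mode_before

    def test_readout_off_protocol_count_warns(self):
        q = quest_init(0.05)
        q = quest_update(q, 0.05, True)
        with pytest.warns(UserWarning, match="protocol"):
            quest_threshold(q)

    def test_deterministic_given_seed(self):
        obs = _FixedThresholdObserver(0.05)
        est1, log1 = run_quest(
            obs, 0.5, 4.0, 5.0, 0.0, 0.05, np.random.default_rng(42)
        )
        est2, log2 = run_quest(
            obs, 0.5, 4.0, 5.0, 0.0, 0.05, np.random.default_rng(42)
        )
        assert est1 == est2
        assert log1.equals(log2)

    def test_forty_trial_calibration(self):
        """40-trial estimates land within 15% of truth in >= 80% of runs."""
        obs = _FixedThresholdObserver(0.05)
        rng = np.random.default_rng(0)
        ests = np.array(
            [run_quest(obs, 0.5, 4.0, 5.0, 0.0, 0.05, rng)[0]
             for _ in range(200)]
        )
        frac = np.mean(np.abs(ests - 0.05) / 0.05 <= 0.15)
        assert frac >= 0.80

    def test_consistency_with_many_trials(self):
        obs = _FixedThresholdObserver(0.05)
        rng = np.random.default_rng(3)
        ests = [
            run_quest(obs, 0.5, 4.0, 5.0, 0.0, 0.05, rng, n_trials=1000)[0]
            for _ in range(20)
        ]
        assert np.median(np.abs(np.log10(np.array(ests) / 0.05))) < 0.02


class TestGp:
    def _training_set(self, rng, n=12):
        x = np.column_stack(
            [rng.uniform(0, np.log10(60), n), rng.uniform(0, np.pi, n)]
        )
        y = np.sin(x[:, 0]) + 0.3 * np.cos(2 * x[:, 1])
        return x, y

    def test_direction_kernel_is_pi_periodic(self):
        x1 = np.array([[0.5, 0.3]])
        x2 = np.array([[0.5, 0.3 + np.pi]])
        k_same = _kernel(x1, x1, 1.0, 1.0, 1.0)[0, 0]
        k_shift = _kernel(x1, x2, 1.0, 1.0, 1.0)[0, 0]
        assert k_shift == pytest.approx(k_same, rel=1e-12)

    def test_predictive_sd_smaller_at_training_points(self):
        rng = np.random.default_rng(0)
        x, y = self._training_set(rng)
        gp = gp_fit(x, y, seed=0)
        _, sd_train = gp.predict(x)
        far = np.array([[np.log10(7.0), 1.0]])  # interior, away from data
        _, sd_far = gp.predict(far)
        assert sd_train.max() <= sd_far[0] + 1e-9

    def test_predictive_mean_matches_direct_gram_solve(self):
        """Cholesky path agrees with an explicit Gram-matrix solve."""
        rng = np.random.default_rng(1)
        x, y = self._training_set(rng)
        gp = gp_fit(x, y, seed=0)
        grid = np.column_stack(
            [rng.uniform(0, np.log10(60), 200), rng.uniform(0, np.pi, 200)]
        )
        mean, _ = gp.predict(grid)
        k = _kernel(x, x, gp.amp, gp.ls_f, gp.ls_d)
        k[np.diag_indices_from(k)] += gp.noise + 1e-10
        ks = _kernel(x, grid, gp.amp, gp.ls_f, gp.ls_d)
        direct = gp.y_mean + ks.T @ np.linalg.solve(k, y - gp.y_mean)
        np.testing.assert_allclose(mean, direct, atol=1e-8)

    def test_interpolates_noiseless_data(self):
        rng = np.random.default_rng(2)
        x, y = self._training_set(rng, n=8)
        gp = gp_fit(x, y, seed=0, noise_floor=1e-8)
        mean, _ = gp.predict(x)
        np.testing.assert_allclose(mean, y, atol=5e-2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gp_fit(np.zeros((3, 2)), np.zeros(3))

    def test_no_negative_information(self):
        """Observing a condition shrinks the predictive sd there."""
        rng = np.random.default_rng(4)
        x, y = self._training_set(rng, n=6)
        new = np.array([[np.log10(5.0), 0.9]])
        gp_before = GpSurrogate(
            x_train=x, y_train=y, amp=0.5, ls_f=1.0, ls_d=1.0,
            noise=1e-6, y_mean=float(y.mean()),
        )
        _, sd_before = gp_before.predict(new)
        gp_after = GpSurrogate(
            x_train=np.vstack([x, new]), y_train=np.r_[y, 0.1],
            amp=0.5, ls_f=1.0, ls_d=1.0, noise=1e-6,
            y_mean=float(np.r_[y, 0.1].mean()),
        )
        _, sd_after = gp_after.predict(new)
        assert sd_after[0] <= sd_before[0] + 1e-9


class TestConditionSelection:
    def _corner_gp(self, y=(-1.5, -1.6, -0.3, -0.5)):
        x = np.array(
            [[np.log10(f), d] for f, d in CORNER_CONDITIONS]
        )
        return gp_fit(x, np.array(y), seed=0)

    def test_selects_interior_point_after_corners(self):
        gp = self._corner_gp()
        big = GamutModel(100.0, 100.0)
        tf, d = select_next_condition(gp, big, candidate_grid())
        assert 1.0 < tf < 60.0

    def test_out_of_gamut_candidates_never_selected(self):
        gp = self._corner_gp(y=(0.5, 0.5, 0.5, 0.5))  # predicted thr ~ 3.2
        gamut = GamutModel(1.0, 0.16)
        cand = candidate_grid()
        got = select_next_condition(gp, gamut, cand)
        assert got is None  # everything predicted beyond the gamut

    def test_gamut_filter_spares_in_gamut_candidates(self):
        gp = self._corner_gp()
        gamut = GamutModel(1.0, 0.16)
        tf, d = select_next_condition(gp, gamut, candidate_grid())
        mean, _ = gp.predict(np.array([[np.log10(tf), d]]))
        assert 10.0 ** mean[0] <= gamut_limit(gamut, d)

    def test_selection_invariant_to_candidate_order(self):
        gp = self._corner_gp()
        big = GamutModel(100.0, 100.0)
        cand = candidate_grid()
        rng = np.random.default_rng(0)
        shuffled = cand[rng.permutation(len(cand))]
        assert select_next_condition(gp, big, cand) == select_next_condition(
            gp, big, shuffled
        )


class TestSession:
    def test_output_size_and_determinism(self, m1):
        psy = PsychometricObserver(model=m1)
        log1, meas1 = run_session(psy, r=5.0, phi=0.0, n_conditions=8, rng=9)
        log2, meas2 = run_session(psy, r=5.0, phi=0.0, n_conditions=8, rng=9)
        assert len(meas1) == 8
        assert (log1.groupby(["tf_hz", "color_dir_deg"]).size() == 40).all()
        assert meas1.equals(meas2)
        assert log1.equals(log2)

    def test_censoring_matches_true_threshold_vs_gamut(self, m1):
        psy = PsychometricObserver(model=m1)
        gamut = GamutModel(1.0, 0.16)
        _, meas = run_session(
            psy, r=12.0, phi=0.0, n_conditions=6, rng=2, gamut=gamut
        )
        truth = psy.true_threshold(
            meas.color_dir_rad.to_numpy(), meas.tf_hz.to_numpy(),
            meas.r_deg.to_numpy(), meas.phi_rad.to_numpy(),
        )
        limit = gamut_limit(gamut, meas.color_dir_rad.to_numpy())
        np.testing.assert_array_equal(meas.censored.to_numpy(), truth > limit)
        # censored rows sit exactly at the gamut edge
        np.testing.assert_allclose(
            meas.threshold.to_numpy()[meas.censored], limit[meas.censored]
        )

    def test_steep_observer_recovers_generating_thresholds(self, m1):
        """Near-deterministic observer: session estimates track the model."""
        psy = PsychometricObserver(model=m1, slope=8.0, lapse_rate=0.0)
        _, meas = run_session(
            psy, r=5.0, phi=0.0, n_conditions=10, rng=5,
            gamut=GamutModel(100.0, 100.0),
        )
        truth = psy.true_threshold(
            meas.color_dir_rad.to_numpy(), meas.tf_hz.to_numpy(),
            meas.r_deg.to_numpy(), meas.phi_rad.to_numpy(),
        )
        err = np.abs(np.log10(meas.threshold.to_numpy() / truth))
        assert np.median(err) < 0.05


class TestEndToEnd:
    def test_session_thresholds_refit_to_generating_surface(self, m1):
        """Trial-level pipeline: sessions -> yoked fit -> surface within 10%.

        A scaled-down version of the full protocol (9 locations x 12
        conditions) keeps the simulation fast; the check is the median
        absolute log ratio between fitted and generating thresholds at
        the measured conditions.
        """
        from tcsfield.fitting import fit_global, predict_thresholds

        design = t.default_design("M1", n_locations=9, total=108)
        _, meas = t.generate_trialwise(m1, design, seed=21)
        meas = meas[~meas.censored].reset_index(drop=True)
        fit = fit_global(meas, "yoked", n_starts=6, seed=0)
        truth = t.threshold_at(
            m1, meas.color_dir_rad.to_numpy(), meas.tf_hz.to_numpy(),
            meas.r_deg.to_numpy(), meas.phi_rad.to_numpy(),
        )
        pred = predict_thresholds(fit.model, meas)
        assert np.median(np.abs(np.log10(pred / truth))) < np.log10(1.10)
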