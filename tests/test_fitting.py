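"""Objective, per-location and global fits, cross-validation machinery."""

import numpy as np
import pandas as pd
import pytest

import tcsfield as t
from tcsfield.fitting import (
    _Data,
    _loss,
    _polish_nm,
    _predict_local,
    LOCAL_BOUNDS,
    fit_global,
    fit_local,
    iterative_refit,
    loo_cv,
    objective,
    paired_improvement_pvalue,
    parameter_constancy_test,
    predict_local,
    predict_thresholds,
    summarize_cv_errors,
)
from conftest import make_local_dataset


def dataset_from_thresholds(thr, dirs, tf, censored=None, r=5.0, phi=0.0):
    n = len(thr)
    return pd.DataFrame(
        {
            "subject": "synthetic",
            "r_deg": r,
            "phi_rad": phi,
            "color_dir_rad": dirs,
            "tf_hz": tf,
            "threshold": thr,
            "censored": np.zeros(n, bool) if censored is None else censored,
        }
    )


class TestObjective:
    def test_perfect_predictions_give_zero(self, m1):
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=40), t.NoiseModel(0.0),
            gamut=t.GamutModel(100.0, 100.0), seed=0,
        )
        assert objective(m1, df) == pytest.approx(0.0, abs=1e-12)

    def test_single_factor_of_two(self, m1):
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=1), t.NoiseModel(0.0),
            gamut=t.GamutModel(100.0, 100.0), seed=0,
        ).iloc[:1]
        df.loc[:, "threshold"] *= 2.0
        assert objective(m1, df) == pytest.approx(np.log10(2.0), abs=1e-12)

    def test_hand_computed_ratios(self, m1):
        """Ratios (10, 1, 0.1) contribute 1 + 0 + 1 = 2 to the loss."""
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=3), t.NoiseModel(0.0),
            gamut=t.GamutModel(100.0, 100.0), seed=0,
        ).iloc[:3].copy()
        df["threshold"] = df["threshold"].to_numpy() * np.array([10.0, 1.0, 0.1])
        assert objective(m1, df) == pytest.approx(2.0, abs=1e-10)

    def test_censored_points_do_not_contribute(self, m1):
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=30), t.NoiseModel(0.05),
            gamut=t.GamutModel(100.0, 100.0), seed=1,
        )
        base = objective(m1, df)
        extra = df.iloc[:5].copy()
        extra["censored"] = True
        extra["threshold"] = 0.16
        assert objective(m1, pd.concat([df, extra])) == pytest.approx(base)

    def test_scale_invariance_of_threshold_units(self, m1):
        """Rescaling measured and predicted together cancels in the ratio."""
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=30), t.NoiseModel(0.05),
            gamut=t.GamutModel(100.0, 100.0), seed=1,
        )
        pred = predict_thresholds(m1, df)
        res = np.abs(np.log10(df.threshold.to_numpy()) - np.log10(pred))
        for k in (0.1, 3.0):
            scaled = np.abs(
                np.log10(k * df.threshold.to_numpy()) - np.log10(k * pred)
            )
            np.testing.assert_allclose(scaled, res, rtol=1e-9)

    def test_all_censored_is_an_error(self, m1):
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=10), t.NoiseModel(0.0),
            gamut=t.GamutModel(100.0, 100.0), seed=0,
        )
        df["censored"] = True
        with pytest.raises(ValueError, match="uncensored"):
            objective(m1, df)


class TestFitLocal:
    def test_noise_free_fixed_point(self, m1_local_mechanisms):
        """Init at truth on noise-free data stays at objective ~ 0."""
        df = make_local_dataset(m1_local_mechanisms, n=60, seed=2, sigma=0.0)
        m = m1_local_mechanisms
        truth = np.array([
            np.log10(m.lum.xi), m.lum.zeta, m.lum.n1, m.lum.n2,
            m.lum.tau1, m.lum.tau2,
            np.log10(m.rg.xi), m.rg.zeta, m.rg.n1, m.rg.n2,
            m.rg.tau1, m.rg.tau2, m.theta,
        ])
        fit = fit_local(df, init=truth, n_starts=0, seed=0)
        assert fit.objective == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.params, truth, atol=1e-4)

    def test_noise_free_recovery_of_threshold_surface(self, m1_local_mechanisms):
        """Perturbed starts recover the generating thresholds to ~1%.

        Parameter ridges are tolerated; the check is on predicted
        thresholds at the measured conditions, not on parameter values.
        """
        df = make_local_dataset(m1_local_mechanisms, n=80, seed=3, sigma=0.0)
        fit = fit_local(df, n_starts=8, seed=1)
        pred = predict_local(fit, df)
        ratio = pred / df.threshold.to_numpy()
        assert np.median(np.abs(np.log10(ratio))) < np.log10(1.01)

    def test_l1_tracks_majority_under_gross_outlier(self, m1_local_mechanisms):
        df = make_local_dataset(m1_local_mechanisms, n=50, seed=4, sigma=0.0)
        df.loc[0, "threshold"] *= 30.0  # one wild staircase estimate
        fit = fit_local(df, n_starts=6, seed=0)
        clean = df.iloc[1:]
        res_l1 = np.abs(
            np.log10(predict_local(fit, clean)) - np.log10(clean.threshold)
        )

        # reference: same machinery with a squared loss
        d = _Data(df)

        def l2_fun(p):
            pred = _predict_local(p, d.dirs, d.tf)
            return float(np.sum((d.log_thr - np.log10(pred)) ** 2))

        x0 = fit.params
        x_l2, _, _ = _polish_nm(l2_fun, x0, LOCAL_BOUNDS, 5200)
        res_l2 = np.abs(
            np.log10(_predict_local(x_l2, clean.color_dir_rad.to_numpy(),
                                    clean.tf_hz.to_numpy()))
            - np.log10(clean.threshold)
        )
        assert np.median(res_l1) < np.median(res_l2)

    def test_too_few_points_warns(self, m1_local_mechanisms):
        df = make_local_dataset(m1_local_mechanisms, n=8, seed=5, sigma=0.0)
        with pytest.warns(UserWarning, match="13-parameter"):
            fit_local(df, n_starts=1, seed=0, maxiter=50)


class TestIterativeRefit:
    def test_objectives_nonincreasing_and_stop_when_converged(self, m1):
        datasets = {}
        for i, (r, phi) in enumerate([(3.0, 0.0), (8.0, 0.5), (12.0, -0.5)]):
            mech = m1.mechanisms_at(r, phi)
            datasets[(r, phi)] = make_local_dataset(
                mech, n=40, seed=10 + i, sigma=0.05, r=r, phi=phi
            )
        fits = iterative_refit(datasets, seed=0, n_starts=3)
        for key, fit in fits.items():
            hist = fit.meta["objective_history"]
            assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))
        # a second pass from the converged state should stop immediately
        inits = {k: fits[k].params for k in fits}
        fits2 = iterative_refit(datasets, inits=inits, seed=0, n_starts=0)
        for key in fits:
            assert fits2[key].objective <= fits[key].objective + 1e-6

    def test_requires_two_locations(self, m1_local_mechanisms):
        df = make_local_dataset(m1_local_mechanisms, n=20, seed=0)
        with pytest.raises(ValueError):
            iterative_refit({"only": df})


class TestFitGlobal:
    def test_noise_free_yoked_recovery(self, m1):
        """Noise-free data from the yoked truth refits to ~zero loss."""
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=150), t.NoiseModel(0.0),
            gamut=t.GamutModel(100.0, 100.0), seed=6,
        )
        fit = fit_global(df, "yoked", n_starts=6, seed=0)
        assert fit.objective < 0.05
        m = fit.model
        assert m.lum_gain.b1 + m.lum_gain.b2 == pytest.approx(-0.025, abs=0.0025)
        assert m.rg_gain.b1 + m.rg_gain.b2 == pytest.approx(-0.047, abs=0.0047)

    def test_symmetric_truth_fits_yoked_b3_near_zero(self, m1):
        sym = t.make_variant(t.pack_params(m1)[:17], "symmetric")
        df = t.generate_thresholds(
            sym, t.default_design("M1", total=200), t.NoiseModel(0.10),
            gamut=t.GamutModel(100.0, 100.0), seed=7,
        )
        fit = fit_global(df, "yoked", n_starts=6, seed=0)
        assert abs(fit.model.lum_gain.b3) < 0.01

    def test_nested_variant_objective_ordering(self, m1):
        """A yoked fit started from the symmetric optimum can't be worse."""
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=120), t.NoiseModel(0.10), seed=8,
        )
        sym = fit_global(df, "symmetric", n_starts=4, seed=0)
        yoked = fit_global(
            df, "yoked", n_starts=4, seed=0,
            starts=[np.r_[sym.params, 0.0]],
        )
        assert yoked.objective <= sym.objective + 1e-9

    def test_few_locations_warns(self, m1):
        design = t.DesignSpec(
            locations=((5.0, 0.0),), counts=np.array([[5, 5, 5, 5]])
        )
        df = t.generate_thresholds(m1, design, t.NoiseModel(0.0), seed=0)
        with pytest.warns(UserWarning, match="eccentricities"):
            fit_global(df, "yoked", n_starts=1, seed=0, maxiter=50)


class TestLooCv:
    def test_noise_free_errors_vanish(self, m1):
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=60), t.NoiseModel(0.0),
            gamut=t.GamutModel(100.0, 100.0), seed=9,
        )
        errs, idx = loo_cv(df, "yoked", seed=0, max_folds=10, n_starts=4)
        assert errs.size == idx.size == 10
        assert np.median(np.abs(errs)) < 5e-3

    def test_error_vector_length_matches_uncensored(self, m1):
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=40), t.NoiseModel(0.05),
            gamut=t.GamutModel(100.0, 100.0), seed=10,
        )
        errs, idx = loo_cv(df, "yoked", seed=0, n_starts=3)
        assert errs.size == (~df.censored).sum()

    def test_warm_matches_cold_starts(self, m1):
        """Warm-started folds agree with cold restarts on held-out errors."""
        df = t.generate_thresholds(
            m1, t.default_design("M1", total=100), t.NoiseModel(0.0),
            gamut=t.GamutModel(100.0, 100.0), seed=11,
        )
        warm, idx_w = loo_cv(df, "yoked", seed=3, max_folds=5, n_starts=3)
        cold, idx_c = loo_cv(
            df, "yoked", seed=3, max_folds=5, warm=False, n_starts=3
        )
        np.testing.assert_array_equal(idx_w, idx_c)
        assert np.median(np.abs(warm - cold)) < 1e-3


class TestCvSummary:
    def test_medians_invariant_to_point_order(self):
        rng = np.random.default_rng(0)
        errors = {v: rng.normal(0, 0.1, 40) for v in
                  ("symmetric", "yoked", "luminance-only", "unconstrained")}
        perm = rng.permutation(40)
        shuffled = {v: e[perm] for v, e in errors.items()}
        a = summarize_cv_errors(errors, seed=5, n_boot=200)
        b = summarize_cv_errors(shuffled, seed=5, n_boot=200)
        assert a[0] == b[0]  # median |error| per variant
        for v in a[1]:
            assert a[1][v] == pytest.approx(b[1][v], abs=1e-12)
        assert a[3] == b[3]

    def test_winner_is_lowest_median(self):
        errors = {
            "yoked": np.full(11, 0.01),
            "symmetric": np.full(11, 0.03),
            "luminance-only": np.full(11, 0.02),
            "unconstrained": np.full(11, 0.015),
        }
        med, ratios, se, winner = summarize_cv_errors(errors, n_boot=50)
        assert winner == "yoked"
        assert all(v < 0 for v in ratios.values())


class TestParameterConstancy:
    def test_identical_error_vectors_give_half(self):
        e = np.abs(np.random.default_rng(0).normal(0, 0.1, 25))
        assert paired_improvement_pvalue(e, e.copy()) == 0.5

    def test_clear_improvement_gives_small_p(self):
        e = np.abs(np.random.default_rng(0).normal(0, 0.1, 25))
        assert paired_improvement_pvalue(e + 0.05, e) < 0.01

    def test_location_constant_data_rarely_rejects(self, m1):
        """Shape parameters constant in truth: p should usually be > 0.1."""
        wins = 0
        n_sim = 6
        for sim in range(n_sim):
            df = t.generate_thresholds(
                m1,
                t.default_design("M1", n_locations=4, total=60),
                t.NoiseModel(0.10),
                gamut=t.GamutModel(100.0, 100.0),
                seed=100 + sim,
            )
            p = parameter_constancy_test(
                df, "theta", seed=sim, max_folds=8, warm_maxiter=500,
                fit_maxiter=4000,
            )
            wins += p > 0.1
        assert wins >= 0.8 * n_sim

    def test_strongly_varying_theta_is_detected(self, m1):
        """Power check: theta swinging across locations gives a small p."""
        import dataclasses

        frames = []
        for i, (r, phi) in enumerate([(3, 0.0), (7, 0.5), (11, -0.5), (14, 0.0)]):
            mech = m1.mechanisms_at(r, phi)
            swung = dataclasses.replace(mech, theta=(0.25, 1.25)[i % 2])
            frames.append(
                make_local_dataset(swung, n=25, seed=50 + i, sigma=0.03,
                                   r=float(r), phi=phi)
            )
        df = pd.concat(frames, ignore_index=True)
        p = parameter_constancy_test(
            df, "theta", seed=0, max_folds=16, warm_maxiter=600
        )
        assert p < 0.05
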