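"""Shared-slope MLE, group bootstrap and correction-rate computations."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from tempattn.errors import DegenerateDataError
from tempattn.psychometric import (
    GUESS,
    PsychometricCurve,
    SharedSlopePsychometric,
    correction_rates,
    fit_group_thresholds_bootstrap,
    fit_shared_slope_thresholds,
)


def make_2afc_trials(
    thresholds, slope=0.14, lapse=0.01, n_per_level=600, n_contrasts=8,
    seed=0, subject_id="s01", spread=2.0,
):
    """Binomial 2AFC data from a known cumulative-Gaussian observer."""
    rng = np.random.default_rng(seed)
    intervals = 0.7 + 0.075 * np.arange(len(thresholds))
    rows = []
    for iv, thr in zip(intervals, thresholds):
        curve = PsychometricCurve(thr, slope, lapse=lapse)
        contrasts = np.geomspace(thr / spread, thr * spread, n_contrasts)
        c = contrasts[rng.integers(0, n_contrasts, n_per_level)]
        correct = rng.random(n_per_level) < curve.p_correct(c)
        orient = np.where(rng.random(n_per_level) < 0.5, "left", "right")
        resp = np.where(correct, orient, np.where(orient == "left", "right", "left"))
        rows.append(
            pd.DataFrame(
                {"subject_id": subject_id, "interval_s": iv, "contrast": c,
                 "orientation": orient, "response": resp}
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestPsychometricCurve:
    def test_threshold_is_75_percent_point(self):
        curve = PsychometricCurve(0.5, 0.14)
        assert curve.p_correct(0.5) == pytest.approx(0.75, abs=1e-12)

    def test_monotone_and_guess_floor(self):
        curve = PsychometricCurve(0.5, 0.14)
        c = np.geomspace(1e-4, 10, 200)
        p = curve.p_correct(c)
        assert np.all(np.diff(p) >= 0)
        assert p[0] == pytest.approx(GUESS, abs=1e-6)


class TestSharedSlopeFit:
    def test_simulate_and_refit_recovery(self):
        true_thr = np.array([0.4, 0.5, 0.6])
        errs, slopes = [], []
        for seed in range(20):
            trials = make_2afc_trials(true_thr, slope=0.14, seed=seed)
            est = SharedSlopePsychometric().fit(trials)
            errs.append(np.abs(est.thresholds_ - true_thr) / true_thr)
            slopes.append(est.slope_)
        assert np.median(np.stack(errs), axis=0).max() < 0.10
        assert abs(np.median(slopes) - 0.14) / 0.14 < 0.2

    def test_guess_rate_responding_is_degenerate(self):
        rng = np.random.default_rng(1)
        n = 1200
        c = np.geomspace(1e-4, 3e-4, 4)[rng.integers(0, 4, n)]  # far below threshold
        orient = np.where(rng.random(n) < 0.5, "left", "right")
        correct = rng.random(n) < 0.5
        trials = pd.DataFrame(
            {"interval_s": 1.0, "contrast": c, "orientation": orient,
             "response": np.where(correct, orient,
                                  np.where(orient == "left", "right", "left"))}
        )
        trials = pd.concat(
            [trials, make_2afc_trials([0.5], seed=2).assign(interval_s=1.1)],
            ignore_index=True,
        )
        with pytest.raises(DegenerateDataError):
            SharedSlopePsychometric().fit(trials)

    def test_all_correct_level_errors_naming_interval(self):
        trials = make_2afc_trials([0.5, 0.6], seed=3)
        lev = trials[trials["interval_s"] == 0.7].index
        trials.loc[lev, "response"] = trials.loc[lev, "orientation"]
        with pytest.raises(DegenerateDataError, match="0.7"):
            SharedSlopePsychometric().fit(trials)

    def test_scale_equivariance_on_log_axis(self):
        trials = make_2afc_trials([0.4, 0.5, 0.6], seed=4)
        a = SharedSlopePsychometric().fit(trials)
        b = SharedSlopePsychometric().fit(trials.assign(contrast=trials.contrast * 2))
        np.testing.assert_allclose(b.thresholds_, 2 * a.thresholds_, rtol=1e-4)
        assert b.slope_ == pytest.approx(a.slope_, rel=1e-4)

    def test_too_few_contrasts_rejected(self):
        trials = make_2afc_trials([0.5], seed=5)
        trials["contrast"] = 0.5  # a single contrast level carries no slope info
        with pytest.raises(DegenerateDataError, match="distinct contrasts"):
            SharedSlopePsychometric().fit(trials)

    def test_wrapper_returns_profile(self):
        trials = make_2afc_trials([0.4, 0.5], seed=6)
        prof, slope = fit_shared_slope_thresholds(trials)
        assert prof.stage == "raw"
        assert prof.thresholds.shape == (2,)
        assert slope > 0


class TestCorrectionRates:
    def test_all_correct(self):
        trials = pd.DataFrame(
            {"subject_id": "s", "interval_s": [0.7, 0.7, 0.8], "contrast": 1.0,
             "orientation": ["left"] * 3, "response": ["left"] * 3}
        )
        out = correction_rates(trials)
        assert (out["prop_correct"] == 1.0).all()

    def test_guessing_is_near_chance(self):
        rng = np.random.default_rng(7)
        n = 4000
        orient = np.where(rng.random(n) < 0.5, "left", "right")
        resp = np.where(rng.random(n) < 0.5, "left", "right")
        trials = pd.DataFrame(
            {"subject_id": "s", "interval_s": 1.0, "contrast": 0.1,
             "orientation": orient, "response": resp}
        )
        p = correction_rates(trials)["prop_correct"].iloc[0]
        assert abs(p - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_hand_counted_ratio(self):
        # 6 correct / 2 wrong at one level
        trials = pd.DataFrame(
            {"subject_id": "s", "interval_s": 1.0, "contrast": 0.5,
             "orientation": ["left"] * 8,
             "response": ["left"] * 6 + ["right"] * 2}
        )
        out = correction_rates(trials, per="group")
        assert out["prop_correct"].iloc[0] == pytest.approx(0.75)
        assert out["n_trials"].iloc[0] == 8


class TestGroupBootstrap:
    @staticmethod
    def _group(seed, n_subjects=6, thr=(0.4, 0.5, 0.6), n_per_level=150):
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(n_subjects):
            off = 1.0 + 0.1 * rng.standard_normal()
            frames.append(
                make_2afc_trials(
                    np.asarray(thr) * off, n_per_level=n_per_level,
                    seed=int(rng.integers(2**31)), subject_id=f"s{i:02d}",
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_no_bootstrap_gives_point_estimates_only(self):
        out = fit_group_thresholds_bootstrap(self._group(0), n_boot=0)
        assert "boot_sd" not in out.columns
        assert len(out) == 3

    def test_identical_clones_have_zero_sd(self):
        one = make_2afc_trials([0.4, 0.5, 0.6], seed=1, subject_id="s00")
        clones = pd.concat(
            [one.assign(subject_id=f"s{i:02d}") for i in range(5)],
            ignore_index=True,
        )
        out = fit_group_thresholds_bootstrap(clones, n_boot=20, seed=0)
        assert np.allclose(out["boot_sd"], 0.0, atol=1e-8)

    def test_bootstrap_sd_tracks_sampling_sd(self):
        # oracle: SD of point estimates over fresh simulated groups
        fresh = np.stack(
            [
                fit_group_thresholds_bootstrap(self._group(100 + i), n_boot=0)[
                    "threshold"
                ].to_numpy()
                for i in range(60)
            ]
        )
        sampling_sd = fresh.std(axis=0, ddof=1)
        boot_sds = np.stack(
            [
                fit_group_thresholds_bootstrap(self._group(i), n_boot=100, seed=i)[
                    "boot_sd"
                ].to_numpy()
                for i in range(4)
            ]
        )
        # bootstrap SDs from single small groups are noisy; their average
        # should sit near the true sampling SD
        ratio = boot_sds.mean(axis=0) / sampling_sd
        assert np.all(ratio > 0.6) and np.all(ratio < 1.6)

    def test_seed_determinism(self):
        g = self._group(3)
        a = fit_group_thresholds_bootstrap(g, n_boot=15, seed=9)
        b = fit_group_thresholds_bootstrap(g, n_boot=15, seed=9)
        pd.testing.assert_frame_equal(a, b)
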