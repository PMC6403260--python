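"""2AFC contrast-threshold estimation.

A cumulative-Gaussian psychometric function on log10 contrast with guess
rate 0.5 and a small fixed lapse is fitted by maximum likelihood.  For one
subject the fit shares a single slope across all cue-target intervals while
each interval gets its own threshold; the reported threshold is the contrast
at 75% correct.  A group-level variant pools subjects and bootstraps them
with replacement to attach an SD to each threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from .errors import DegenerateDataError, FitFailureError

__all__ = [
    "PsychometricCurve",
    "ThresholdProfile",
    "SharedSlopePsychometric",
    "GroupBootstrapThresholds",
    "fit_shared_slope_thresholds",
    "fit_group_thresholds_bootstrap",
    "correction_rates",
    "ensure_correct",
]

GUESS = 0.5


def _z75(lapse: float) -> float:
    # Phi offset between the function midpoint and the 75%-correct point
    return float(ndtri(0.25 / (0.5 - lapse)))


def p_correct(contrast, log10_alpha, slope, lapse=0.01):
    """P(correct) = 0.5 + (0.5 - lapse) * Phi((log10 c - log10 alpha) / slope)."""
    z = (np.log10(np.asarray(contrast, dtype=float)) - log10_alpha) / slope
    return GUESS + (0.5 - lapse) * ndtr(z)


@dataclass(frozen=True)
class PsychometricCurve:
    """2AFC curve summarised by its 75%-correct contrast and log10 slope."""

    threshold_75: float
    slope: float
    guess: float = GUESS
    lapse: float = 0.01

    @property
    def log10_alpha(self) -> float:
        return float(np.log10(self.threshold_75) - self.slope * _z75(self.lapse))

    def p_correct(self, contrast):
        return p_correct(contrast, self.log10_alpha, self.slope, self.lapse)


@dataclass(frozen=True)
class ThresholdProfile:
    """One subject's thresholds as a function of cue-target interval."""

    subject_id: str
    intervals: np.ndarray
    thresholds: np.ndarray
    stage: str = "raw"  # raw | smoothed | centered

    def __post_init__(self):
        object.__setattr__(self, "intervals", np.asarray(self.intervals, float))
        object.__setattr__(self, "thresholds", np.asarray(self.thresholds, float))
        if self.intervals.shape != self.thresholds.shape:
            raise ValueError("intervals and thresholds must have equal length")

    def with_values(self, thresholds, stage, intervals=None) -> "ThresholdProfile":
        return replace(
            self,
            thresholds=np.asarray(thresholds, float),
            stage=stage,
            intervals=self.intervals if intervals is None else np.asarray(intervals, float),
        )


def ensure_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach a boolean ``correct`` column; drops no-response (missed) trials."""
    df = trials
    if "response" in df.columns:
        df = df[df["response"] != "none"]
    if "correct" not in df.columns:
        df = df.assign(correct=(df["response"] == df["orientation"]))
    return df


def _cells(df: pd.DataFrame):
    """Aggregate trials to (interval index, log10 contrast, n, n_correct) cells."""
    g = (
        df.groupby(["interval_s", "contrast"], sort=True)["correct"]
        .agg(["sum", "count"])
        .reset_index()
    )
    intervals = np.sort(df["interval_s"].unique())
    idx = np.searchsorted(intervals, g["interval_s"].to_numpy())
    return (
        intervals,
        idx,
        np.log10(g["contrast"].to_numpy(float)),
        g["count"].to_numpy(float),
        g["sum"].to_numpy(float),
    )


class SharedSlopePsychometric(BaseEstimator):
    """Per-interval thresholds with one common slope, fitted jointly by MLE.

    Parameters
    ----------
    lapse : float
        Fixed lapse rate (not estimated).
    slope_init : float
        Starting value for the shared log10-contrast slope.
    maxiter : int
        Optimiser iteration cap.

    Attributes
    ----------
    intervals_ : ndarray of interval durations (s)
    thresholds_ : ndarray of 75%-correct contrasts, one per interval
    slope_ : float, shared slope on the log10-contrast axis
    nll_ : float, negative log-likelihood at the optimum
    """

    def __init__(self, lapse: float = 0.01, slope_init: float = 0.15, maxiter: int = 1000):
        self.lapse = lapse
        self.slope_init = slope_init
        self.maxiter = maxiter

    def fit(self, X: pd.DataFrame, y=None):
        df = ensure_correct(X)
        if df.empty:
            raise DegenerateDataError("no scorable trials")
        intervals, idx, logc, n, k = _cells(df)
        n_lev = len(intervals)
        for j, lev in enumerate(intervals):
            m = idx == j
            if len(np.unique(logc[m])) < 3:
                raise DegenerateDataError(
                    f"interval {lev:g}s has trials at < 3 distinct contrasts"
                )
            if k[m].sum() == n[m].sum() or k[m].sum() == 0:
                raise DegenerateDataError(
                    f"interval {lev:g}s is all-correct or all-wrong at every contrast"
                )
        lapse = self.lapse
        lo_b, hi_b = logc.min() - 2.0, logc.max() + 2.0

        def nll(theta):
            a = theta[idx]
            s = np.exp(theta[-1])
            p = GUESS + (0.5 - lapse) * ndtr((logc - a) / s)
            p = np.clip(p, 1e-12, 1.0 - 1e-12)
            return -(k * np.log(p) + (n - k) * np.log1p(-p)).sum()

        # empirical starts: contrast nearest ~75% correct per interval
        a0 = np.empty(n_lev)
        for j in range(n_lev):
            m = idx == j
            frac = k[m] / n[m]
            a0[j] = logc[m][np.argmin(np.abs(frac - 0.75))]
        bounds = [(lo_b, hi_b)] * n_lev + [(np.log(5e-3), np.log(5.0))]
        best = None
        for s0 in (self.slope_init, self.slope_init * 3, self.slope_init / 3):
            res = minimize(
                nll,
                np.append(a0, np.log(s0)),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.maxiter},
            )
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise DegenerateDataError("shared-slope MLE failed to converge")
        theta = best.x
        eps = 1e-6
        at_bound = (theta[:n_lev] < lo_b + eps) | (theta[:n_lev] > hi_b - eps)
        if at_bound.any():
            lev = intervals[np.where(at_bound)[0][0]]
            raise DegenerateDataError(
                f"threshold unidentified (hit search bound) at interval {lev:g}s"
            )
        # likelihood-flatness check: a decade shift in a threshold must cost
        # a non-trivial amount of log-likelihood, else the level is pure guessing
        for j, lev in enumerate(intervals):
            deltas = []
            for shift in (-1.0, 1.0):
                probe = theta.copy()
                probe[j] += shift
                deltas.append(nll(probe) - best.fun)
            if min(deltas) < 2.0:
                raise DegenerateDataError(
                    f"threshold uninformative (flat likelihood) at interval {lev:g}s"
                )
        self.intervals_ = intervals
        self.log10_alpha_ = theta[:n_lev]
        self.slope_ = float(np.exp(theta[-1]))
        self.thresholds_ = 10.0 ** (self.log10_alpha_ + self.slope_ * _z75(lapse))
        self.nll_ = float(best.fun)
        self.n_trials_ = int(n.sum())
        return self

    def predict(self, X: pd.DataFrame):
        """P(correct) for rows with ``interval_s`` and ``contrast`` columns."""
        j = np.searchsorted(self.intervals_, X["interval_s"].to_numpy(float))
        return p_correct(
            X["contrast"].to_numpy(float), self.log10_alpha_[j], self.slope_, self.lapse
        )

    def profile(self, subject_id: str = "subject") -> ThresholdProfile:
        return ThresholdProfile(subject_id, self.intervals_, self.thresholds_, "raw")


def fit_shared_slope_thresholds(
    trials: pd.DataFrame, subject_id: str | None = None, lapse: float = 0.01
):
    """Fit one subject's shared-slope thresholds; returns (profile, slope)."""
    if subject_id is not None:
        trials = trials[trials["subject_id"] == subject_id]
    est = SharedSlopePsychometric(lapse=lapse).fit(trials)
    sid = subject_id or str(trials["subject_id"].iloc[0]) if "subject_id" in trials else "subject"
    return est.profile(sid), est.slope_


class GroupBootstrapThresholds(BaseEstimator):
    """Group-level thresholds with a subject-resampling bootstrap SD.

    All subjects' trials are pooled and fitted with the shared-slope model;
    ``n_boot`` replicates resample subjects with replacement and refit, and
    the SD of each threshold over replicates is reported.  A degenerate
    replicate is redrawn (at most 10 attempts).
    """

    def __init__(self, n_boot: int = 10000, seed: int | None = None, lapse: float = 0.01):
        self.n_boot = n_boot
        self.seed = seed
        self.lapse = lapse

    def fit(self, X: pd.DataFrame, y=None):
        df = ensure_correct(X)
        subjects = np.sort(df["subject_id"].unique())
        if len(subjects) < 5:
            raise DegenerateDataError(f"need >= 5 subjects, got {len(subjects)}")
        base = SharedSlopePsychometric(lapse=self.lapse).fit(df)
        self.intervals_ = base.intervals_
        self.thresholds_ = base.thresholds_
        self.slope_ = base.slope_
        self.boot_sd_ = None
        self.boot_thresholds_ = None
        if self.n_boot:
            rng = np.random.default_rng(self.seed)
            by_subj = {s: g for s, g in df.groupby("subject_id")}
            boots = np.empty((self.n_boot, len(self.intervals_)))
            for b in range(self.n_boot):
                for attempt in range(10):
                    pick = rng.choice(subjects, size=len(subjects), replace=True)
                    sample = pd.concat([by_subj[s] for s in pick], ignore_index=True)
                    try:
                        est = SharedSlopePsychometric(lapse=self.lapse).fit(sample)
                    except DegenerateDataError:
                        continue
                    boots[b] = est.thresholds_
                    break
                else:
                    raise FitFailureError(
                        f"bootstrap replicate {b} degenerate after 10 redraws"
                    )
            self.boot_thresholds_ = boots
            self.boot_sd_ = boots.std(axis=0, ddof=1)
        return self


def fit_group_thresholds_bootstrap(
    trials: pd.DataFrame, n_boot: int = 10000, seed: int | None = None, lapse: float = 0.01
) -> pd.DataFrame:
    """Pooled group thresholds per interval, with bootstrap SDs if n_boot > 0."""
    est = GroupBootstrapThresholds(n_boot=n_boot, seed=seed, lapse=lapse).fit(trials)
    out = pd.DataFrame(
        {"interval_s": est.intervals_, "threshold": est.thresholds_}
    )
    if est.boot_sd_ is not None:
        out["boot_sd"] = est.boot_sd_
    return out


def correction_rates(trials: pd.DataFrame, per: str = "subject") -> pd.DataFrame:
    """Proportion correct per interval (and subject), with trial counts."""
    df = ensure_correct(trials)
    keys = ["subject_id", "interval_s"] if per == "subject" else ["interval_s"]
    out = df.groupby(keys)["correct"].agg(["count", "mean"]).reset_index()
    return out.rename(columns={"count": "n_trials", "mean": "prop_correct"})
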