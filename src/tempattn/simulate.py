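"""Synthetic observers for the temporal-attention psychophysics designs.

Three designs are emulated, matching the study conditions the analysis
expects:

* Experiment 1 -- 2AFC orientation discrimination, cue-target intervals
  700-1300 ms in 75 ms steps (9 levels), 10 log-spaced contrasts spanning
  each observer's 52.5%- to 97.5%-correct range, 900 trials per subject.
* Experiment 2A/2B -- same intervals plus a shorter/longer-than-one-second
  duration judgment; contrasts span 85-97.5% correct (2A) or sit at one
  fixed high contrast (2B); 360 trials per subject, with undetected targets
  recorded as misses and dropped from the judgment analysis.
* Experiment 3 -- intervals 500-3000 ms in 250 ms steps (11 levels),
  10 blocks of 110 trials.

True threshold-vs-interval profiles come from the predictive attention
model itself (``predicted_threshold``), plus a Gaussian between-subject
offset; duration judgments follow a scalar-noise decision rule whose 50%
point is the subject's PSE.  Every draw is governed by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import InvalidParameterError
from .hazard import (
    IntervalDistribution,
    MissParams,
    NoiseParams,
    PredictiveParams,
    QuadratureSpec,
    ScalingParams,
    predicted_threshold,
)
from .psychometric import GUESS, p_correct as _p_correct, _z75

__all__ = [
    "EXP1_INTERVALS",
    "EXP3_INTERVALS",
    "DesignSpec",
    "ObserverSpec",
    "ObserverPopulation",
    "design",
    "default_population",
    "make_observers",
    "simulate_trials",
    "simulate_study",
]

EXP1_INTERVALS = np.round(np.arange(0.700, 1.300 + 1e-9, 0.075), 4)  # 9 levels
EXP3_INTERVALS = np.round(np.arange(0.500, 3.000 + 1e-9, 0.250), 4)  # 11 levels


@dataclass(frozen=True)
class DesignSpec:
    """Trial counts, interval grid and contrast-placement rule of one design."""

    experiment: str                 # '1', '2A', '2B', '3'
    intervals: np.ndarray
    n_contrasts: int
    anchor_lo: float                # proportion correct at the lowest contrast
    anchor_hi: float
    n_trials: int
    duration_task: bool = False

    def __post_init__(self):
        object.__setattr__(self, "intervals", np.asarray(self.intervals, float))
        if not np.all(np.diff(self.intervals) > 0):
            raise InvalidParameterError("interval grid must be strictly increasing")

    @property
    def dist(self) -> IntervalDistribution:
        return IntervalDistribution(self.intervals.min(), self.intervals.max())


_DESIGNS = {
    "1": dict(intervals=EXP1_INTERVALS, n_contrasts=10, anchor_lo=0.525,
              anchor_hi=0.975, n_trials=900),
    "2A": dict(intervals=EXP1_INTERVALS, n_contrasts=10, anchor_lo=0.85,
               anchor_hi=0.975, n_trials=360, duration_task=True),
    # one fixed high contrast, ~2.3x the 97.5%-correct contrast
    "2B": dict(intervals=EXP1_INTERVALS, n_contrasts=1, anchor_lo=0.975,
               anchor_hi=0.975, n_trials=360, duration_task=True),
    "3": dict(intervals=EXP3_INTERVALS, n_contrasts=10, anchor_lo=0.525,
              anchor_hi=0.975, n_trials=1100),
}

_2B_CONTRAST_FACTOR = 2.3  # fixed-contrast designs sit this far above the hi anchor


def design(experiment: str) -> DesignSpec:
    """Preset design for one of the experiments ('1', '2A', '2B', '3')."""
    try:
        return DesignSpec(experiment=experiment, **_DESIGNS[experiment])
    except KeyError:
        raise InvalidParameterError(f"unknown experiment {experiment!r}") from None


@dataclass(frozen=True)
class ObserverSpec:
    """One simulated observer's generative parameters."""

    subject_id: str
    thresholds: np.ndarray      # true 75%-correct contrast per interval (%)
    slope: float                # log10-contrast psychometric slope
    lapse: float = 0.01
    pse: float = 1.29           # duration perceived as one second (s)
    duration_weber: float = 0.1
    detect_gain: float = 1.6    # detection slope relative to discrimination


@dataclass(frozen=True)
class ObserverPopulation:
    """Population-level truth: attention model + observer variability.

    The attention parameters sit at the model's plausible operating point
    (w = 0.11, mu = 106 ms, k = 0.5); beta0/beta1 place the threshold curves
    on the percent-contrast scales typical of the two interval ranges, and
    the psychometric slopes match the spread of the printed contrast-anchor
    ranges.
    """

    w: float = 0.11
    mu: float | None = 0.106
    k: float = 0.5
    beta0: float = 0.81
    beta1: float = -0.16
    slope: float = 0.14
    sigma_subj: float = 0.05    # SD of between-subject threshold offset (%)
    lapse: float = 0.01
    pse_mean: float = 1.29
    pse_sd: float = 0.15
    duration_weber: float = 0.1
    quad: QuadratureSpec = field(default_factory=lambda: QuadratureSpec(128, 8.0))

    def scaled_for(self, experiment: str) -> "ObserverPopulation":
        """Per-experiment scaling/slope defaults (wider range = larger contrasts)."""
        if experiment == "3":
            return replace(self, beta0=2.06, beta1=-1.6, slope=0.10, sigma_subj=0.12)
        return self

    def true_curve(self, dsn: DesignSpec, intervals=None) -> np.ndarray:
        pop = self.scaled_for(dsn.experiment)
        t = dsn.intervals if intervals is None else np.asarray(intervals, float)
        return predicted_threshold(
            t,
            dsn.dist,
            ScalingParams(pop.beta0, pop.beta1),
            MissParams(pop.k),
            NoiseParams(pop.w),
            None if pop.mu is None else PredictiveParams(pop.mu),
            pop.quad,
        )


def default_population(experiment: str = "1") -> ObserverPopulation:
    return ObserverPopulation().scaled_for(experiment)


def make_observers(
    n: int, dsn: DesignSpec, truth: ObserverPopulation, seed: int | None = None
) -> list[ObserverSpec]:
    """Draw ``n`` observers around the population's true threshold curve."""
    if n < 1:
        raise InvalidParameterError("need n >= 1 observers")
    pop = truth.scaled_for(dsn.experiment)
    rng = np.random.default_rng(seed)
    base = pop.true_curve(dsn)
    observers = []
    for i in range(n):
        thr = base + pop.sigma_subj * rng.standard_normal()
        if np.any(thr <= 0):
            raise InvalidParameterError(
                "population parameters imply non-positive thresholds"
            )
        pse = pop.pse_mean + pop.pse_sd * rng.standard_normal()
        pse = float(np.clip(pse, 0.3, None))
        observers.append(
            ObserverSpec(
                subject_id=f"s{i + 1:02d}",
                thresholds=thr,
                slope=pop.slope,
                lapse=pop.lapse,
                pse=pse,
                duration_weber=pop.duration_weber,
            )
        )
    return observers


def _contrast_grid(obs: ObserverSpec, dsn: DesignSpec) -> np.ndarray:
    """Analytic stand-in for the calibration block: log-spaced contrasts whose
    endpoints hit the design's anchor correction rates on the observer's own
    (interval-averaged) psychometric curve."""
    c75 = float(np.exp(np.mean(np.log(obs.thresholds))))
    log_alpha = np.log10(c75) - obs.slope * _z75(obs.lapse)

    def c_at(p):
        z = ndtri((p - GUESS) / (0.5 - obs.lapse))
        return 10.0 ** (log_alpha + obs.slope * z)

    if dsn.n_contrasts == 1:
        return np.array([_2B_CONTRAST_FACTOR * c_at(dsn.anchor_hi)])
    return np.geomspace(c_at(dsn.anchor_lo), c_at(dsn.anchor_hi), dsn.n_contrasts)


def simulate_trials(
    obs: ObserverSpec, dsn: DesignSpec, seed: int | None = None
) -> pd.DataFrame:
    """Simulate one observer's trial table for a design."""
    rng = np.random.default_rng(seed)
    n = dsn.n_trials
    iv_idx = rng.integers(0, dsn.intervals.size, n)
    interval = dsn.intervals[iv_idx]
    grid = _contrast_grid(obs, dsn)
    contrast = grid[rng.integers(0, grid.size, n)]
    orientation = np.where(rng.random(n) < 0.5, "left", "right")
    log_alpha_j = np.log10(obs.thresholds) - obs.slope * _z75(obs.lapse)
    p = _p_correct(contrast, log_alpha_j[iv_idx], obs.slope, obs.lapse)
    correct = rng.random(n) < p
    response = np.where(
        correct, orientation, np.where(orientation == "left", "right", "left")
    )
    # detection: 50% at the 75%-correct contrast, steeper than discrimination
    p_det = ndtr(
        obs.detect_gain
        * (np.log10(contrast) - np.log10(obs.thresholds[iv_idx]))
        / obs.slope
    )
    if dsn.duration_task:
        detected = rng.random(n) < p_det
        perceived = rng.normal(interval / obs.pse, obs.duration_weber * interval)
        judgment = np.where(perceived > 1.0, "longer", "shorter")
        judgment = np.where(detected, judgment, "missing")
        response = np.where(detected, response, "none")
        correct = correct & detected
    else:
        detected = np.ones(n, bool)
        judgment = np.full(n, "missing")
    return pd.DataFrame(
        {
            "subject_id": obs.subject_id,
            "experiment": dsn.experiment,
            "interval_s": interval,
            "contrast": contrast,
            "orientation": orientation,
            "response": response,
            "detected": detected,
            "duration_judgment": judgment,
            "correct": correct,
        }
    )


def simulate_study(
    dsn: DesignSpec,
    truth: ObserverPopulation | None = None,
    n_subjects: int = 15,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full study; returns (trial table, truth record).

    The truth record stores every generative parameter so recovery studies
    can score themselves against it.
    """
    truth = (truth or ObserverPopulation()).scaled_for(dsn.experiment)
    ss = np.random.SeedSequence(0 if seed is None else seed)
    obs_seed, *trial_seeds = ss.spawn(n_subjects + 1)
    observers = make_observers(
        n_subjects, dsn, truth, np.random.default_rng(obs_seed).integers(2**31)
    )
    frames = [
        simulate_trials(o, dsn, np.random.default_rng(s).integers(2**31))
        for o, s in zip(observers, trial_seeds)
    ]
    trials = pd.concat(frames, ignore_index=True)
    record = {
        "experiment": dsn.experiment,
        "n_subjects": n_subjects,
        "seed": seed,
        "population": {
            k: (v if not isinstance(v, QuadratureSpec) else vars(v))
            for k, v in vars(truth).items()
        },
        "observers": [
            {
                "subject_id": o.subject_id,
                "thresholds": o.thresholds.tolist(),
                "slope": o.slope,
                "pse": o.pse,
            }
            for o in observers
        ],
        "true_curve": truth.true_curve(dsn).tolist(),
    }
    return trials, record
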