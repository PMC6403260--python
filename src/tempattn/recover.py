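"""Simulate-and-refit recovery studies.

Two canned studies quantify whether the estimation machinery can recover
its own generating parameters under the study conditions:

* :func:`recover_attention_params` -- threshold curves generated by the
  predictive attention model on the narrow-range (7 smoothed points) and
  wide-range (11 points) interval grids, perturbed with Gaussian residual
  noise (SD = 5% of each curve's range), then jointly refitted.
* :func:`recover_duration_pse` -- full synthetic duration-judgment studies
  fitted with the hierarchical Bayesian model; reports the posterior KDE
  mode of the population-mean PSE per seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import AttentionModelRegression, ThresholdCurve
from .hazard import QuadratureSpec
from .simulate import (
    EXP1_INTERVALS,
    ObserverPopulation,
    design,
    simulate_study,
)
from .stats import moving_average
from .duration import HierarchicalDurationModel

__all__ = ["true_threshold_curves", "recover_attention_params", "recover_duration_pse"]


def true_threshold_curves(
    truth: ObserverPopulation | None = None,
) -> tuple[ThresholdCurve, ThresholdCurve]:
    """Noise-free model curves on the two analysis grids.

    The narrow-range curve lives on the 7-point moving-average grid (the
    window-3 smoothing of 9 levels), the wide-range curve on all 11 levels.
    """
    truth = truth or ObserverPopulation()
    d1, d3 = design("1"), design("3")
    grid1 = moving_average(EXP1_INTERVALS, 3)
    y1 = truth.true_curve(d1, grid1)
    y3 = truth.scaled_for("3").true_curve(d3)
    return (
        ThresholdCurve(grid1, y1, d1.dist, label="exp1"),
        ThresholdCurve(d3.intervals, y3, d3.dist, label="exp3"),
    )


def recover_attention_params(
    n_replicates: int = 20,
    noise_frac: float = 0.05,
    seed: int | None = None,
    truth: ObserverPopulation | None = None,
    variant: str = "predictive",
    quad: QuadratureSpec | None = None,
    n_starts: int = 10,
) -> pd.DataFrame:
    """Noise-perturbed curve refits; one row per replicate (w, mu, rss)."""
    truth = truth or ObserverPopulation()
    c1, c3 = true_threshold_curves(truth)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        noisy = []
        for c in (c1, c3):
            sd = noise_frac * np.ptp(c.thresholds)
            noisy.append(
                ThresholdCurve(
                    c.intervals,
                    c.thresholds + sd * rng.standard_normal(c.thresholds.size),
                    c.dist,
                    c.label,
                )
            )
        fit = AttentionModelRegression(
            variant=variant,
            k=truth.k,
            quad=quad,
            n_starts=n_starts,
            seed=int(rng.integers(2**31)),
        ).fit(noisy)
        rows.append(
            {"replicate": rep, "w": fit.w_, "mu": fit.mu_, "rss": fit.rss_}
        )
    return pd.DataFrame(rows)


def recover_duration_pse(
    n_seeds: int = 10,
    n_subjects: int = 15,
    n_chains: int = 4,
    n_iter: int = 20000,
    seed: int | None = None,
    truth: ObserverPopulation | None = None,
) -> pd.DataFrame:
    """Hierarchical-fit PSE recovery across replicate synthetic studies."""
    truth = truth or ObserverPopulation()
    base = 0 if seed is None else seed
    rows = []
    for i in range(n_seeds):
        rep_seed = int(
            np.random.default_rng(np.random.SeedSequence([base, i])).integers(2**31)
        )
        trials, _ = simulate_study(design("2A"), truth, n_subjects, rep_seed)
        model = HierarchicalDurationModel(
            n_chains=n_chains, n_iter=n_iter, seed=rep_seed
        ).fit(trials)
        rows.append(
            {
                "seed": rep_seed,
                "pse_mode": model.pse_mode_,
                "ci_lo": model.pse_ci95_[0],
                "ci_hi": model.pse_ci95_[1],
                "acceptance": model.posterior_.acceptance_rate,
            }
        )
    return pd.DataFrame(rows)
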