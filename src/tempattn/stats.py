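"""Descriptive and inferential statistics for threshold profiles.

The analysis chain for a within-subject threshold study: a per-subject
permutation test for short-term fluctuation (SD of successive-interval
threshold differences under label shuffling), a window-3 moving average,
subject centering (subtract each subject's mean, add back the grand mean),
one-way repeated-measures ANOVA, and Fisher's LSD pairwise comparisons off
the ANOVA's pooled error term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import GridMismatchError, MissingCellError
from .psychometric import ThresholdProfile

__all__ = [
    "PermutationResult",
    "AnovaResult",
    "moving_average",
    "smooth_profile",
    "center_profiles",
    "permutation_fluctuation_test",
    "rm_anova",
    "fisher_lsd",
]


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_one_sided: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    ms_error: float
    n_subjects: int
    n_levels: int
    zero_variance: bool = False


def moving_average(values, window: int = 3) -> np.ndarray:
    """Valid-region moving average; output is window-1 entries shorter."""
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if values.size < window:
        raise ValueError(f"need at least {window} values, got {values.size}")
    return np.convolve(values, np.full(window, 1.0 / window), mode="valid")


def smooth_profile(profile: ThresholdProfile, window: int = 3) -> ThresholdProfile:
    """Moving-average a profile; intervals are averaged the same way."""
    return profile.with_values(
        moving_average(profile.thresholds, window),
        "smoothed",
        intervals=moving_average(profile.intervals, window),
    )


def _as_matrix(profiles) -> tuple[np.ndarray, np.ndarray | None, list]:
    """Stack profiles / DataFrame / array into a (subjects x levels) matrix."""
    if isinstance(profiles, np.ndarray):
        return np.asarray(profiles, float), None, list(range(profiles.shape[0]))
    if isinstance(profiles, pd.DataFrame):
        return profiles.to_numpy(float), profiles.columns.to_numpy(float), list(profiles.index)
    grids = [p.intervals for p in profiles]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise GridMismatchError("profiles do not share an interval grid")
    mat = np.vstack([p.thresholds for p in profiles])
    return mat, grids[0], [p.subject_id for p in profiles]


def center_profiles(profiles):
    """Remove each subject's mean level, then restore the grand mean.

    Within-subject differences and the grand mean are preserved exactly.
    Accepts an ndarray, a wide DataFrame, or a list of profiles (returned in
    the same form, profiles with ``stage='centered'``).
    """
    mat, grid, ids = _as_matrix(profiles)
    centered = mat - mat.mean(axis=1, keepdims=True) + mat.mean()
    if isinstance(profiles, np.ndarray):
        return centered
    if isinstance(profiles, pd.DataFrame):
        return pd.DataFrame(centered, index=profiles.index, columns=profiles.columns)
    return [
        p.with_values(row, "centered") for p, row in zip(profiles, centered)
    ]


def permutation_fluctuation_test(
    profile, n_perm: int = 10000, seed: int | None = None
) -> PermutationResult:
    """Upper-tail permutation test for short-term threshold fluctuation.

    The statistic is the SD of differences between thresholds at successive
    interval durations; interval labels are shuffled ``n_perm`` times and the
    add-one estimator gives a one-sided p-value (large SD = fluctuation).
    """
    v = profile.thresholds if isinstance(profile, ThresholdProfile) else np.asarray(profile, float)
    if v.size < 4:
        raise ValueError(f"need >= 4 interval levels, got {v.size}")
    if np.ptp(v) == 0.0:
        return PermutationResult(0.0, np.zeros(n_perm), 1.0)
    obs = float(np.std(np.diff(v), ddof=1))
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(v, (n_perm, 1)), axis=1)
    null = np.std(np.diff(perm, axis=1), axis=1, ddof=1)
    tol = 1e-12 * max(1.0, abs(obs))
    p = (1.0 + np.count_nonzero(null >= obs - tol)) / (1.0 + n_perm)
    return PermutationResult(obs, null, float(p))


def rm_anova(profiles) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x levels matrix."""
    mat, _, _ = _as_matrix(profiles)
    if np.isnan(mat).any():
        raise MissingCellError("subject x interval matrix has missing cells")
    n_s, n_l = mat.shape
    grand = mat.mean()
    lev_m = mat.mean(axis=0)
    subj_m = mat.mean(axis=1)
    ss_eff = n_s * np.sum((lev_m - grand) ** 2)
    resid = mat - subj_m[:, None] - lev_m[None, :] + grand
    ss_err = float(np.sum(resid**2))
    df1, df2 = n_l - 1, (n_l - 1) * (n_s - 1)
    ms_err = ss_err / df2
    if ss_eff + ss_err == 0.0:
        return AnovaResult(0.0, df1, df2, 1.0, 0.0, 0.0, 0.0, 0.0, n_s, n_l, True)
    F = (ss_eff / df1) / ms_err if ms_err > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(
        float(F), df1, df2, p, float(ss_eff / (ss_eff + ss_err)),
        float(ss_eff), ss_err, float(ms_err), n_s, n_l,
    )


def fisher_lsd(profiles, level_a: int, level_b: int) -> dict:
    """Fisher's LSD pairwise comparison of two interval levels (by column index).

    Uses the repeated-measures ANOVA's pooled error term; no multiplicity
    correction.
    """
    mat, _, _ = _as_matrix(profiles)
    res = rm_anova(mat)
    if level_a == level_b:
        return {"t": 0.0, "df": res.df2, "p": 1.0}
    n_s = mat.shape[0]
    diff = mat[:, level_a].mean() - mat[:, level_b].mean()
    se = np.sqrt(2.0 * res.ms_error / n_s)
    t = diff / se if se > 0 else np.inf * np.sign(diff)
    p = float(2.0 * sps.t.sf(abs(t), res.df2))
    return {"t": float(t), "df": res.df2, "p": p}
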