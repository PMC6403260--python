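"""Shared fixtures, including an independent Monte-Carlo hazard oracle."""

from __future__ import annotations

import numpy as np
import pytest

from tempattn.hazard import IntervalDistribution


@pytest.fixture
def exp1_dist() -> IntervalDistribution:
    return IntervalDistribution(0.7, 1.3)


@pytest.fixture
def exp3_dist() -> IntervalDistribution:
    return IntervalDistribution(0.5, 3.0)


def mc_subjective_hazard(
    m: float,
    dist: IntervalDistribution,
    k: float,
    w: float,
    mu: float | None = None,
    n: int = 10**6,
    seed: int = 0,
    trunc_sd: float = 8.0,
):
    """Importance-weighting Monte-Carlo oracle for the subjective hazards.

    Samples t uniformly on the same extended range the quadrature covers,
    weights by the measurement likelihood p(m|t), and forms the ratio of
    weighted means of the numerator density (f, or the exponential
    look-ahead integral written out independently here) and of 1 - k F(t).
    Returns (estimate, delta-method standard error).
    """
    rng = np.random.default_rng(seed)
    ext = trunc_sd * w * dist.t_max
    lo = max(dist.t_min - ext, dist.t_min / 10.0)
    hi = dist.t_max + ext
    t = rng.uniform(lo, hi, n)
    sd = w * t
    p = np.exp(-0.5 * ((m - t) / sd) ** 2) / (np.sqrt(2 * np.pi) * sd)
    span = dist.t_max - dist.t_min
    F = np.clip((t - dist.t_min) / span, 0.0, 1.0)
    if mu is None:
        q = np.where((t >= dist.t_min) & (t <= dist.t_max), 1.0 / span, 0.0)
    else:
        # (1/mu) int_t^inf f(tau) exp(-(tau-t)/mu) dtau, written out by hand
        a = np.maximum(t, dist.t_min)
        q = np.where(
            t <= dist.t_max,
            (np.exp(-(a - t) / mu) - np.exp(-(dist.t_max - t) / mu)) / span,
            0.0,
        )
    num = q * p
    den = (1.0 - k * F) * p
    mn, md = num.mean(), den.mean()
    r = mn / md
    cov = np.cov(num, den)
    var_r = (cov[0, 0] + r**2 * cov[1, 1] - 2 * r * cov[0, 1]) / (n * md**2)
    return r, float(np.sqrt(max(var_r, 0.0)))


@pytest.fixture
def mc_oracle():
    return mc_subjective_hazard
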