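"""Hazard-rate models of temporal expectation.

The event (a near-threshold target) occurs at a time drawn uniformly from a
known interval range.  An observer tracking elapsed time anticipates the
event with an intensity described by a hazard function.  Four variants are
implemented:

* ``hazard_rate`` -- the miss-corrected hazard ``h(t) = f(t) / (1 - k F(t))``,
  where ``k = 1 - P(no detection | appeared)`` discounts targets that
  appeared but went unnoticed.
* ``predictive_hazard`` -- anticipation extends to the near future: the
  density ``f`` in the numerator is replaced by an exponentially weighted
  integral over upcoming times with time constant ``mu``.
* ``subjective_hazard`` -- elapsed time is known only through a noisy
  measurement ``m`` with scalar (Weber) noise, SD ``w * t``; the hazard is
  blurred accordingly.
* ``subjective_predictive_hazard`` -- both of the above.

``predicted_threshold`` maps the blurred hazard onto a contrast-threshold
curve via an affine scaling, which is what gets fitted to data.

All quadrature uses fixed uniform grids with nodes pinned to the support
edges, so the piecewise-smooth integrands are integrated segment by segment;
composite Simpson weights give fourth-order convergence, verified by the
halved-grid contract in :func:`quadrature_error`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, NumericalAccuracyError

__all__ = [
    "IntervalDistribution",
    "MissParams",
    "NoiseParams",
    "PredictiveParams",
    "ScalingParams",
    "QuadratureSpec",
    "hazard_rate",
    "measurement_likelihood",
    "subjective_hazard",
    "predictive_hazard",
    "subjective_predictive_hazard",
    "expected_subjective_hazard",
    "predicted_threshold",
    "quadrature_error",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class IntervalDistribution:
    """Continuous uniform distribution of cue-target intervals, in seconds."""

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.t_min < self.t_max):
            raise InvalidParameterError(
                f"need 0 < t_min < t_max, got [{self.t_min}, {self.t_max}]"
            )

    @property
    def span(self) -> float:
        return self.t_max - self.t_min

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.t_min) & (t <= self.t_max), 1.0 / self.span, 0.0)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        return np.clip((t - self.t_min) / self.span, 0.0, 1.0)


@dataclass(frozen=True)
class MissParams:
    """Miss correction ``k = 1 - P(ND|A)``; ``k=0.5`` for threshold-level targets."""

    k: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.k < 1.0):
            raise InvalidParameterError(f"k must lie in [0, 1), got {self.k}")


@dataclass(frozen=True)
class NoiseParams:
    """Scalar timing noise: measurement SD grows as ``w * t`` (Weber fraction w)."""

    w: float

    def __post_init__(self) -> None:
        if not self.w > 0.0:
            raise InvalidParameterError(f"Weber fraction w must be > 0, got {self.w}")


@dataclass(frozen=True)
class PredictiveParams:
    """Exponential look-ahead time constant ``mu`` (seconds); 0 = no look-ahead."""

    mu: float

    def __post_init__(self) -> None:
        if self.mu < 0.0:
            raise InvalidParameterError(f"mu must be >= 0, got {self.mu}")


@dataclass(frozen=True)
class ScalingParams:
    """Affine map from blurred hazard to contrast threshold (percent Michelson)."""

    beta0: float
    beta1: float


@dataclass(frozen=True)
class QuadratureSpec:
    """Fixed Simpson grid: nodes per axis and truncation half-width in SDs."""

    n_grid: int = 512
    trunc_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.n_grid < 64:
            raise InvalidParameterError(f"n_grid must be >= 64, got {self.n_grid}")
        if self.trunc_sd < 6.0:
            raise InvalidParameterError(f"trunc_sd must be >= 6, got {self.trunc_sd}")

    def halved(self) -> "QuadratureSpec":
        return QuadratureSpec(max(self.n_grid // 2, 64), self.trunc_sd)


def hazard_rate(t, dist: IntervalDistribution, miss: MissParams = MissParams()):
    """Miss-corrected hazard ``f(t) / (1 - k F(t))``; zero outside the support."""
    t = np.asarray(t, dtype=float)
    out = dist.pdf(t) / (1.0 - miss.k * dist.cdf(t))
    return out if out.ndim else float(out)


def measurement_likelihood(m, t, noise: NoiseParams):
    """Gaussian density of measurement ``m`` given true time ``t``: N(t, (w t)^2)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise InvalidParameterError("t must be > 0 (measurement SD is w*t)")
    m = np.asarray(m, dtype=float)
    sd = noise.w * t
    out = np.exp(-0.5 * ((m - t) / sd) ** 2) / (_SQRT2PI * sd)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# quadrature plumbing


def _simpson_weights(x: np.ndarray) -> np.ndarray:
    """Composite Simpson weights for a uniformly spaced, odd-length grid."""
    n = x.size
    h = (x[-1] - x[0]) / (n - 1)
    w = np.full(n, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return w * (h / 3.0)


def _time_segments(dist: IntervalDistribution, noise: NoiseParams, quad: QuadratureSpec):
    """Support of f split at its edges and extended by trunc_sd measurement SDs.

    Returns three (nodes, weights) pairs for [lo, t_min], [t_min, t_max] and
    [t_max, hi]; the extension is clipped below at t_min/10 so the SD ``w*t``
    stays positive.  Node counts are forced odd for the Simpson rule.
    """
    ext = quad.trunc_sd * noise.w * dist.t_max
    lo = max(dist.t_min - ext, dist.t_min / 10.0)
    hi = dist.t_max + ext
    bounds = [(lo, dist.t_min), (dist.t_min, dist.t_max), (dist.t_max, hi)]
    # distribute nodes by log-length (the measurement SD shrinks with t, so
    # low-t segments need denser sampling), but reserve at least 45% for the
    # support segment, whose edges carry the numerator's mass
    logl = np.array([np.log(b / a) for a, b in bounds])
    counts = np.maximum((quad.n_grid * logl / logl.sum()).astype(int), 8)
    short = int(0.45 * quad.n_grid) - counts[1]
    if short > 0:
        counts[1] += short
        counts[0] = max(counts[0] - short * counts[0] // (counts[0] + counts[2]), 8)
        counts[2] = max(quad.n_grid - counts[0] - counts[1], 8)
    segs = []
    for (a, b), n in zip(bounds, counts):
        x = np.linspace(a, b, n | 1)
        segs.append((x, _simpson_weights(x)))
    return segs


def _pred_numerator(t, dist: IntervalDistribution, mu: float):
    """Exponentially look-ahead-weighted density: (1/mu) * int_t^inf f(tau) e^{-(tau-t)/mu} dtau.

    Closed form for the uniform distribution; continuous in t and zero above
    the support.
    """
    t = np.asarray(t, dtype=float)
    f0 = 1.0 / dist.span
    # exponents clipped at 0: positive values only arise above the support,
    # where the result is overwritten with 0
    e_min = np.exp(np.minimum(-(dist.t_min - t) / mu, 0.0))
    e_max = np.exp(np.minimum(-(dist.t_max - t) / mu, 0.0))
    out = np.where(t < dist.t_min, f0 * (e_min - e_max), f0 * (1.0 - e_max))
    return np.where(t > dist.t_max, 0.0, out)


def predictive_hazard(
    t,
    dist: IntervalDistribution,
    miss: MissParams = MissParams(),
    pred: PredictiveParams = PredictiveParams(0.1),
):
    """Hazard with exponential look-ahead over future event times (closed form)."""
    if pred.mu == 0.0:
        return hazard_rate(t, dist, miss)
    t = np.asarray(t, dtype=float)
    out = _pred_numerator(t, dist, pred.mu) / (1.0 - miss.k * dist.cdf(t))
    return out if out.ndim else float(out)


def _gauss(mc, t, w):
    sd = w * t
    return np.exp(-0.5 * ((mc - t) / sd) ** 2) / (_SQRT2PI * sd)


def _layer_integral(mc, c, lo, mu, w, n_nodes):
    """``int_lo^c exp(-(c - t)/mu) p(m|t) dt`` via the substitution s=(c-t)/mu.

    The exponential boundary layer at the support edge has width mu, which a
    fixed t-grid cannot resolve when mu is small; on the s-grid it is always
    smooth.  Truncated at 45 e-foldings.
    """
    S = min((c - lo) / mu, 45.0)
    s = np.linspace(0.0, S, n_nodes | 1)
    ws = _simpson_weights(s)
    ts = c - mu * s
    p = _gauss(mc, ts, w)
    return mu * (p * np.exp(-s)) @ ws


def _global_ratio(mc, dist, k, w, mu, segs):
    """Support-extended-grid integrals (measurement SD resolved by the grid)."""
    f0 = 1.0 / dist.span
    num = 0.0
    den = 0.0
    for i, (x, wts) in enumerate(segs):
        p = _gauss(mc, x, w)
        den = den + p @ (wts * (1.0 - k * dist.cdf(x)))
        if i == 1:
            supp = p @ wts
    if mu is None:
        num = f0 * supp
    else:
        n_l = max(len(segs[0][0]), len(segs[2][0]))
        lo = segs[0][0][0]
        num = f0 * (
            supp
            + _layer_integral(mc, dist.t_min, lo, mu, w, n_l)
            - _layer_integral(mc, dist.t_max, lo, mu, w, n_l)
        )
    return num, den


def _local_ratio(mc, dist, k, w, mu, lo, hi, trunc_sd, n_grid):
    """Per-measurement window integrals for SDs far below the global cell size.

    Each measurement gets a window covering +/- trunc_sd measurement SDs
    around it (solving |m - t| = trunc_sd * w * t), split at the support
    edges so the density's jumps stay on segment boundaries.
    """
    m = mc.ravel()
    a = np.clip(m / (1.0 + trunc_sd * w), lo, hi)
    b = np.clip(m / (1.0 - trunc_sd * w), lo, hi)
    e1 = np.clip(dist.t_min, a, b)
    e2 = np.clip(dist.t_max, a, b)
    u = np.linspace(0.0, 1.0, (n_grid // 3) | 1)
    wu = _simpson_weights(u)
    f0 = 1.0 / dist.span
    num = np.zeros_like(m)
    den = np.zeros_like(m)
    for aa, bb, on_support in ((a, e1, False), (e1, e2, True), (e2, b, False)):
        t = aa[:, None] + (bb - aa)[:, None] * u[None, :]
        t = np.maximum(t, 1e-300)
        p = _gauss(mc, t, w) * (bb - aa)[:, None]
        den += (p * (1.0 - k * dist.cdf(t))) @ wu
        if mu is not None:
            num += (p * _pred_numerator(t, dist, mu)) @ wu
        elif on_support:
            num += f0 * (p @ wu)
    return num, den


def _blurred_ratio(m, dist, miss, noise, quad, pred=None):
    """Shared core of the two subjective hazards: ratio of t-integrals.

    numerator : int q(t) p(m|t) dt, with q = f (classical) or the look-ahead
                numerator (predictive)
    denominator: int (1 - k F(t)) p(m|t) dt
    both truncated to the support extended by trunc_sd measurement SDs; the
    Gaussians are not renormalised.
    """
    m = np.asarray(m, dtype=float)
    scalar = m.ndim == 0
    m = np.atleast_1d(m).ravel()
    if np.any(m <= 0.0):
        raise InvalidParameterError("measurement m must be > 0")
    segs = _time_segments(dist, noise, quad)
    lo, hi = segs[0][0][0], segs[2][0][-1]
    h_cell = max(x[1] - x[0] for x, _ in segs)
    mu = None if pred is None or pred.mu == 0.0 else pred.mu
    k, w = miss.k, noise.w
    num = np.empty_like(m)
    den = np.empty_like(m)
    # narrow-noise measurements need per-m windows; wide-noise ones are
    # resolved by (and must respect the truncation of) the global grid
    local = (quad.trunc_sd * w < 0.5) & (w * m < 5.0 * h_cell)
    for mask, fn in ((~local, "global"), (local, "local")):
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        for start in range(0, idx.size, 2048):  # bound matrix sizes
            ii = idx[start : start + 2048]
            mc = m[ii, None]
            if fn == "global":
                n, d = _global_ratio(mc, dist, k, w, mu, segs)
            else:
                n, d = _local_ratio(
                    mc, dist, k, w, mu, lo, hi, quad.trunc_sd, quad.n_grid
                )
            num[ii] = n
            den[ii] = d
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    return float(out[0]) if scalar else out


def subjective_hazard(
    m,
    dist: IntervalDistribution,
    miss: MissParams = MissParams(),
    noise: NoiseParams = NoiseParams(0.11),
    quad: QuadratureSpec = QuadratureSpec(),
):
    """Hazard given a Weber-noisy measurement m of elapsed time.

    ``int f(t) p(m|t) dt / int (1 - k F(t)) p(m|t) dt``
    """
    return _blurred_ratio(m, dist, miss, noise, quad, pred=None)


def subjective_predictive_hazard(
    m,
    dist: IntervalDistribution,
    miss: MissParams = MissParams(),
    noise: NoiseParams = NoiseParams(0.11),
    pred: PredictiveParams = PredictiveParams(0.106),
    quad: QuadratureSpec = QuadratureSpec(),
):
    """Subjective hazard with the look-ahead numerator in place of f(t)."""
    if pred.mu == 0.0:
        return subjective_hazard(m, dist, miss, noise, quad)
    return _blurred_ratio(m, dist, miss, noise, quad, pred=pred)


def expected_subjective_hazard(
    t,
    dist: IntervalDistribution,
    miss: MissParams = MissParams(),
    noise: NoiseParams = NoiseParams(0.11),
    pred: PredictiveParams | None = None,
    quad: QuadratureSpec = QuadratureSpec(),
):
    """Average the subjective hazard over measurements: int h_hat(m) p(m|t) dm.

    The m-grid spans t +/- trunc_sd * w * t per evaluation point.  This is the
    attention read-out the threshold model scales.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t).ravel()
    if np.any(t <= 0.0):
        raise InvalidParameterError("t must be > 0")
    sd = noise.w * t
    offsets = np.linspace(-quad.trunc_sd, quad.trunc_sd, quad.n_grid | 1)
    mgrid = t[:, None] + offsets[None, :] * sd[:, None]
    mgrid = np.maximum(mgrid, dist.t_min * 1e-3)
    hhat = _blurred_ratio(mgrid.ravel(), dist, miss, noise, quad, pred=pred)
    hhat = hhat.reshape(mgrid.shape)
    pm = np.exp(-0.5 * ((mgrid - t[:, None]) / sd[:, None]) ** 2) / (
        _SQRT2PI * sd[:, None]
    )
    wts = _simpson_weights(offsets)[None, :] * sd[:, None]
    out = (hhat * pm * wts).sum(axis=1)
    return float(out[0]) if scalar else out


def predicted_threshold(
    t,
    dist: IntervalDistribution,
    scaling: ScalingParams,
    miss: MissParams = MissParams(),
    noise: NoiseParams = NoiseParams(0.11),
    pred: PredictiveParams | None = None,
    quad: QuadratureSpec = QuadratureSpec(),
):
    """Predicted contrast threshold ``y(t) = beta0 + beta1 * E[h_hat(m) | t]``."""
    g = expected_subjective_hazard(t, dist, miss, noise, pred, quad)
    return scaling.beta0 + scaling.beta1 * g


def quadrature_error(
    m,
    dist: IntervalDistribution,
    miss: MissParams = MissParams(),
    noise: NoiseParams = NoiseParams(0.11),
    pred: PredictiveParams | None = None,
    quad: QuadratureSpec = QuadratureSpec(),
    raise_on_fail: bool = False,
    tol: float = 1e-4,
):
    """Max relative change in the subjective hazard when the grid is halved.

    The convergence contract requires this to stay below ``tol`` at the
    default spec; with ``raise_on_fail`` a violation raises
    :class:`NumericalAccuracyError`.
    """
    if pred is None:
        fine = subjective_hazard(m, dist, miss, noise, quad)
        coarse = subjective_hazard(m, dist, miss, noise, quad.halved())
    else:
        fine = subjective_predictive_hazard(m, dist, miss, noise, pred, quad)
        coarse = subjective_predictive_hazard(m, dist, miss, noise, pred, quad.halved())
    fine = np.atleast_1d(fine)
    coarse = np.atleast_1d(coarse)
    scale = np.maximum(np.abs(fine), 1e-300)
    err = float(np.max(np.abs(fine - coarse) / scale))
    if raise_on_fail and err > tol:
        raise NumericalAccuracyError(
            f"quadrature not converged: relative change {err:.2e} > {tol:.0e}"
        )
    return err
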