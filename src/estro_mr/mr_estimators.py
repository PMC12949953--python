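"""Two-sample MR estimators: Wald ratio, IVW, MR-Egger, weighted median,
and mode-based estimates.

All estimators consume harmonised effect pairs (beta_exposure, se_exposure,
beta_outcome, se_outcome) and return an :class:`MREstimate` on the scale
inherited from the inputs (log-odds or SD units per unit of biomarker).

Per-variant Wald ratios use the first-order delta approximation
``theta_j = bY_j / bX_j`` with ``sigma_j = seY_j / |bX_j|`` (exposure-beta
uncertainty ignored; a second-order variant is available behind a flag).
IVW is the zero-intercept weighted regression of outcome on exposure effects
with weights ``seY^-2``; the default variance model is multiplicative
random-effects with the dispersion factor floored at 1, i.e.
``se = se_fixed * max(1, sqrt(Q / (L - 1)))`` with Cochran's Q over the
per-variant ratios. MR-Egger adds a free intercept (the directional-pleiotropy
diagnostic) after re-orienting inputs so all exposure betas are non-negative,
and uses t-distribution inference with L - 2 degrees of freedom. The weighted
median interpolates the weight-ordered ratio distribution at cumulative
standardised weight 0.5; the mode-based estimators take the argmax of a
Gaussian-kernel smoothed ratio density. Median/mode standard errors come from
a seeded parametric bootstrap that resamples both sides of every pair.

Confidence intervals use the exact 97.5% normal quantile (t-quantile for
Egger), not the rounded 1.96.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    RoutingError,
    ValidationError,
)
from .harmonisation import HarmonisedPair

__all__ = [
    "MREstimate",
    "RatioSet",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimate",
    "p_from_ci",
    "weighted_median_point",
    "mode_point",
    "Z_975",
]

#: Exact two-sided 95% normal multiplier.
Z_975 = float(stats.norm.ppf(0.975))

METHODS = (
    "wald_ratio",
    "ivw",
    "mr_egger",
    "egger_intercept",
    "weighted_median",
    "weighted_mode",
    "simple_mode",
)


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with uncertainty and diagnostics."""

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q_stat: float | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValidationError(
                f"{self.method}: beta {self.beta} outside CI [{self.ci_low}, {self.ci_high}]"
            )
        if not (0 < self.p <= 1):
            raise ValidationError(f"{self.method}: p must be in (0, 1], got {self.p}")


def _normal_estimate(method, n_snp, beta, se, q_stat=None, df=None) -> MREstimate:
    z = abs(beta) / se if se > 0 else math.inf
    p = max(float(2 * stats.norm.sf(z)), 5e-324)
    return MREstimate(
        method=method,
        n_snp=n_snp,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z_975 * se),
        ci_high=float(beta + Z_975 * se),
        p=p,
        q_stat=q_stat,
        df=df,
    )


def _t_estimate(method, n_snp, beta, se, tdf, q_stat=None) -> MREstimate:
    tq = float(stats.t.ppf(0.975, tdf))
    p = max(float(2 * stats.t.sf(abs(beta) / se, tdf)), 5e-324)
    return MREstimate(
        method=method,
        n_snp=n_snp,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - tq * se),
        ci_high=float(beta + tq * se),
        p=p,
        q_stat=q_stat,
        df=tdf,
    )


def _arrays(pairs: Sequence[HarmonisedPair]):
    bx = np.array([p.beta_exposure for p in pairs], dtype=float)
    sx = np.array([p.se_exposure for p in pairs], dtype=float)
    by = np.array([p.beta_outcome for p in pairs], dtype=float)
    sy = np.array([p.se_outcome for p in pairs], dtype=float)
    return bx, sx, by, sy


class RatioSet:
    """Per-variant Wald ratios with first-order SEs and inverse-variance weights."""

    def __init__(self, theta: np.ndarray, sigma: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if np.any(sigma <= 0) or not np.all(np.isfinite(sigma)):
            raise ValidationError("ratio SEs must be positive and finite")
        self.theta = theta
        self.sigma = sigma
        self.weights = sigma**-2

    @classmethod
    def from_pairs(cls, pairs: Sequence[HarmonisedPair]) -> "RatioSet":
        bx, _, by, sy = _arrays(pairs)
        if np.any(bx == 0):
            raise ValidationError("Wald ratio undefined for beta_exposure = 0")
        return cls(by / bx, sy / np.abs(bx))

    def __len__(self) -> int:
        return len(self.theta)


def wald_ratio(pair: HarmonisedPair, second_order: bool = False) -> MREstimate:
    """Single-variant causal estimate, outcome effect over exposure effect.

    ``second_order=True`` adds the exposure-beta uncertainty term
    ``beta_outcome^2 * se_exposure^2 / beta_exposure^4`` to the variance.
    """
    if pair.beta_exposure == 0:
        raise ValidationError(f"{pair.rsid}: Wald ratio undefined for beta_exposure = 0")
    beta = pair.beta_outcome / pair.beta_exposure
    var = pair.se_outcome**2 / pair.beta_exposure**2
    if second_order:
        var += pair.beta_outcome**2 * pair.se_exposure**2 / pair.beta_exposure**4
    return _normal_estimate("wald_ratio", 1, beta, math.sqrt(var))


def ivw(
    pairs: Sequence[HarmonisedPair],
    effects_model: str = "multiplicative_random",
    min_variants: int = 2,
) -> MREstimate:
    """Inverse-variance-weighted estimate (zero-intercept weighted regression).

    ``effects_model`` is ``"fixed"`` or ``"multiplicative_random"`` (default;
    the fixed-effects SE is inflated by ``sqrt(Q/(L-1))`` when the per-variant
    ratios are overdispersed, floored at 1). Instruments with a single variant
    must be routed to :func:`wald_ratio` instead.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown effects model {effects_model!r}")
    L = len(pairs)
    if L < min_variants or L < 1:
        raise RoutingError(
            f"IVW requires >= {max(min_variants, 1)} variants, got {L}; "
            "use the Wald ratio for single-variant instruments"
        )
    bx, _, by, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ValidationError("IVW undefined when any beta_exposure = 0")
    w = sy**-2
    sww = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sww
    se = sww**-0.5
    theta = by / bx
    wq = (bx / sy) ** 2
    q = float(np.sum(wq * (theta - beta) ** 2))
    df = L - 1
    if effects_model == "multiplicative_random" and df >= 1:
        se *= max(1.0, math.sqrt(q / df))
    return _normal_estimate("ivw", L, beta, se, q_stat=q, df=df)


def mr_egger(pairs: Sequence[HarmonisedPair]) -> tuple[MREstimate, MREstimate]:
    """Weighted regression with a free intercept (directional pleiotropy).

    Inputs are re-oriented so every exposure beta is non-negative; weights are
    ``se_outcome^-2``; SEs use multiplicative scaling floored at 1 and
    inference is t-based with L - 2 degrees of freedom. Returns
    ``(slope, intercept)`` estimates.
    """
    L = len(pairs)
    if L < 3:
        raise InsufficientDataError(f"MR-Egger requires >= 3 variants, got {L}")
    bx, _, by, sy = _arrays(pairs)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = sy**-2
    X = np.column_stack([np.ones(L), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    tdf = L - 2
    scale = max(1.0, rss / tdf)
    cov = np.linalg.inv(xtwx) * scale
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    slope = _t_estimate("mr_egger", L, coef[1], se_slope, tdf, q_stat=rss)
    intercept = _t_estimate("egger_intercept", L, coef[0], se_int, tdf, q_stat=rss)
    return slope, intercept


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Median of the weight-ordered ratio distribution, linearly interpolated
    at cumulative standardised weights (each ratio centred at
    ``cum_j - w_j / 2``)."""
    theta = np.asarray(theta, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2
    if 0.5 <= cum[0]:
        return float(th[0])
    if 0.5 >= cum[-1]:
        return float(th[-1])
    j = int(np.searchsorted(cum, 0.5))
    frac = (0.5 - cum[j - 1]) / (cum[j] - cum[j - 1])
    return float(th[j - 1] + frac * (th[j] - th[j - 1]))


def _bootstrap_se(pairs, statistic, n_boot, seed) -> float:
    """Parametric bootstrap: resample per-variant betas on both sides from
    normal(beta, se), recompute the statistic, return the SD of the replicates."""
    bx, sx, by, sy = _arrays(pairs)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        est[b] = statistic(by_b / bx_b, sy / np.abs(bx_b))
    return float(np.std(est, ddof=1))


def weighted_median(
    pairs: Sequence[HarmonisedPair], n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimate; SE from a seeded parametric bootstrap."""
    if n_boot <= 0:
        raise ConfigurationError("n_boot must be a positive integer")
    if len(pairs) < 3:
        raise InsufficientDataError(f"weighted median requires >= 3 variants, got {len(pairs)}")
    ratios = RatioSet.from_pairs(pairs)
    beta = weighted_median_point(ratios.theta, ratios.weights)
    se = _bootstrap_se(
        pairs, lambda th, sg: weighted_median_point(th, sg**-2), n_boot, seed
    )
    return _normal_estimate("weighted_median", len(pairs), beta, se)


def _reference_bandwidth(theta: np.ndarray) -> float:
    """Normal-reference (Silverman-type) bandwidth of the ratio set:
    ``0.9 * min(sd, mad) * L^(-1/5)`` with the normal-consistent MAD."""
    th = np.asarray(theta, dtype=float)
    sd = float(np.std(th, ddof=1))
    mad = 1.4826 * float(np.median(np.abs(th - np.median(th))))
    candidates = [s for s in (sd, mad) if s > 0]
    if not candidates:
        return 0.0
    return 0.9 * min(candidates) * len(th) ** (-0.2)


def mode_point(
    theta: np.ndarray,
    weights: np.ndarray | None = None,
    bandwidth_factor: float = 1.0,
    grid_size: int = 512,
) -> float:
    """Argmax of the Gaussian-kernel smoothed (optionally weighted) ratio
    density, refined by bounded scalar optimisation around the best grid node."""
    th = np.asarray(theta, dtype=float)
    if weights is None:
        w = np.full(len(th), 1.0 / len(th))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    h = bandwidth_factor * _reference_bandwidth(th)
    if h <= 0 or np.ptp(th) == 0:
        return float(th[0])
    lo, hi = th.min() - 3 * h, th.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - th[None, :]) / h) ** 2) @ w
    i = int(np.argmax(dens))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid_size - 1)]

    def neg_density(x: float) -> float:
        return -float(np.exp(-0.5 * ((x - th) / h) ** 2) @ w)

    res = optimize.minimize_scalar(
        neg_density, bounds=(a, b), method="bounded", options={"xatol": 1e-12}
    )
    return float(res.x) if res.fun <= -dens[i] else float(grid[i])


def mode_estimate(
    pairs: Sequence[HarmonisedPair],
    weighting: str = "weighted",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimate (simple or inverse-variance weighted kernel density)."""
    if bandwidth_factor <= 0:
        raise ConfigurationError("bandwidth_factor must be positive")
    if weighting not in ("simple", "weighted"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if n_boot <= 0:
        raise ConfigurationError("n_boot must be a positive integer")
    if len(pairs) < 3:
        raise InsufficientDataError(f"mode estimate requires >= 3 variants, got {len(pairs)}")
    ratios = RatioSet.from_pairs(pairs)
    use_weights = weighting == "weighted"
    beta = mode_point(
        ratios.theta,
        ratios.weights if use_weights else None,
        bandwidth_factor=bandwidth_factor,
    )
    se = _bootstrap_se(
        pairs,
        lambda th, sg: mode_point(
            th, sg**-2 if use_weights else None, bandwidth_factor=bandwidth_factor
        ),
        n_boot,
        seed,
    )
    method = "weighted_mode" if use_weights else "simple_mode"
    return _normal_estimate(method, len(pairs), beta, se)


def p_from_ci(beta: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal p-value implied by a point estimate and its 95% CI.

    Recovers ``se = (ci_high - ci_low) / (2 * z_0.975)`` and
    ``p = 2 * (1 - Phi(|beta| / se))``; used to audit the internal
    consistency of published estimate/CI/p triples.
    """
    if not ci_low < ci_high:
        raise ValidationError(f"degenerate CI [{ci_low}, {ci_high}]")
    se = (ci_high - ci_low) / (2 * Z_975)
    return float(2 * stats.norm.sf(abs(beta) / se))
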