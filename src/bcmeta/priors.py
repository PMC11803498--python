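"""Hyperprior machinery for the bias-corrected meta-analysis models.

Three pieces live here:

* elicitation of the Beta prior on the probability of bias ``pi_B`` from a
  median and a 90% quantile (:func:`elicit_beta`);
* heterogeneity priors expressed as a scale-gamma on the precision, which
  induces a half-t prior on the standard deviation (half-Cauchy for one
  degree of freedom); and
* the truncation calculus of the Dirichlet-process bias component, linking
  the concentration parameter ``alpha``, the residual stick-breaking mass
  ``epsilon``, the truncation level ``K`` and the prior expected number of
  biased studies.

The DP calculus in brief: with stick-breaking weights ``q_k ~ Beta(1, a)``
the expected mass left after ``K - 1`` breaks is ``(a/(1+a))^(K-1)``, so the
level keeping the residual below ``epsilon`` is
``K = 1 + log(epsilon)/log(a/(1+a))``, which at ``epsilon = 0.01`` is
approximately ``1 + 5 a``.  Requiring the maximum number of bias clusters
not to exceed the prior expected number of biased studies
``N a0/(a0 + a1)`` bounds the uniform prior on ``alpha`` above by
``(N a0/(a0 + a1) - 1)/5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "HyperPriorConfig",
    "elicit_beta",
    "beta_quantiles",
    "alpha_max_bound",
    "truncation_K",
    "truncation_K_exact",
    "expected_biased_count",
    "tau_tail_probability",
]

#: residual stick-breaking mass used by the 1 + 5*alpha truncation rule
DEFAULT_EPSILON = 0.01

#: fixed lower bound of the uniform prior on the DP concentration; values
#: below this produce tiny stick-breaking weights and numerical trouble
ALPHA_MIN = 0.5


@dataclass(frozen=True)
class HyperPriorConfig:
    """Hyperparameters of the bias-corrected models.

    Parameters
    ----------
    sigma_mu
        Prior SD of the pooled effect location ``mu_theta`` (default 1e6, a
        locally flat prior).
    b_lower, b_upper
        Bounds of the uniform prior on the bias location ``mu_beta``.  The
        default (-15, 15) encodes bias of unknown direction; (0, 15) is the
        positive-bias sensitivity setting.
    s_theta, df_theta
        Scale and degrees of freedom of the scale-gamma prior on
        ``1/tau_theta**2``; the default (0.5, 1) makes ``tau_theta``
        half-Cauchy(0.5).
    s_beta, df_beta
        Same for the bias-scale ``tau_beta``.
    a0, a1
        Beta prior shapes for the probability of bias ``pi_B``.  The default
        Beta(0.5, 1) has mean 1/3 with a spike at zero.
    alpha_min, alpha_max
        Bounds of the uniform prior on the DP concentration.  ``alpha_max``
        may be left None and resolved from the dataset size via
        :func:`alpha_max_bound`.
    K
        DP truncation level; resolved as ``round(1 + 5 * alpha_max)`` when
        None.
    """

    sigma_mu: float = 1e6
    b_lower: float = -15.0
    b_upper: float = 15.0
    s_theta: float = 0.5
    df_theta: int = 1
    s_beta: float = 0.5
    df_beta: int = 1
    a0: float = 0.5
    a1: float = 1.0
    alpha_min: float = ALPHA_MIN
    alpha_max: float | None = None
    K: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_mu", "s_theta", "s_beta", "a0", "a1"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.b_lower < self.b_upper:
            raise ValueError("b_lower must be < b_upper")
        if self.alpha_max is not None and not self.alpha_min < self.alpha_max:
            raise ValueError(
                f"alpha_max ({self.alpha_max}) must exceed alpha_min ({self.alpha_min})"
            )
        if self.K is not None and self.K < 2:
            raise ValueError("DP truncation level K must be >= 2")

    def resolve(self, n_studies: int) -> "HyperPriorConfig":
        """Fill ``alpha_max`` and ``K`` from the dataset size if unset."""
        amax = self.alpha_max
        if amax is None:
            amax = alpha_max_bound(n_studies, self.a0, self.a1, alpha_min=self.alpha_min)
        k = self.K if self.K is not None else truncation_K(amax)
        return replace(self, alpha_max=amax, K=k)


def beta_quantiles(a0: float, a1: float, probs=(0.5, 0.9)) -> tuple[float, ...]:
    """Quantiles of a Beta(a0, a1) distribution."""
    return tuple(float(q) for q in stats.beta.ppf(probs, a0, a1))


def elicit_beta(
    median_target: float,
    q90_target: float,
    *,
    tol: float = 1e-10,
    bounds: tuple[float, float] = (1e-3, 1e3),
) -> tuple[float, float]:
    """Find Beta shapes whose median and 90th percentile match the targets.

    Used to turn a judgement of the form "the proportion of biased studies
    is around m, and it would be surprising if it exceeded q" into a
    Beta(a0, a1) prior on ``pi_B``.  Solved by root finding on the
    incomplete-beta inverse in log-shape space; the initial point comes from
    a normal-approximation moment match.
    """
    if not (0.0 < median_target < q90_target < 1.0):
        raise ValueError(
            "need 0 < median_target < q90_target < 1, got "
            f"({median_target}, {q90_target})"
        )

    def residual(log_shapes: np.ndarray) -> np.ndarray:
        a0, a1 = np.exp(log_shapes)
        med, q90 = stats.beta.ppf([0.5, 0.9], a0, a1)
        return np.array([med - median_target, q90 - q90_target])

    # moment-matched start: treat the two quantiles as a normal median/q90
    sd0 = max((q90_target - median_target) / 1.2816, 1e-3)
    m = median_target
    common = m * (1 - m) / sd0**2 - 1.0
    a0_init = max(m * common, 0.05)
    a1_init = max((1 - m) * common, 0.05)

    best = None
    for start in ((a0_init, a1_init), (1.0, 1.0), (2.0, 2.0), (0.5, 0.5)):
        sol = optimize.root(residual, np.log(start), method="hybr", tol=tol)
        res = float(np.max(np.abs(sol.fun)))
        if best is None or res < best[0]:
            best = (res, np.exp(sol.x))
        if res < 1e-8:
            break
    res, shapes = best
    a0, a1 = float(shapes[0]), float(shapes[1])
    lo, hi = bounds
    if res > 1e-6 or not (lo < a0 < hi and lo < a1 < hi):
        raise RuntimeError(
            f"Beta elicitation failed: best residual {res:.3g} at shapes "
            f"({a0:.4g}, {a1:.4g})"
        )
    return a0, a1


def expected_biased_count(n_studies: int, a0: float, a1: float) -> float:
    """Prior expected number of biased studies, ``N * a0 / (a0 + a1)``."""
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    if not (a0 > 0 and a1 > 0):
        raise ValueError("Beta shapes must be > 0")
    return n_studies * a0 / (a0 + a1)


def alpha_max_bound(
    n_studies: int, a0: float, a1: float, *, alpha_min: float = ALPHA_MIN
) -> float:
    """Upper bound of the uniform prior on the DP concentration.

    The supremum of ``alpha_max`` under the constraint that the maximum
    number of bias clusters ``1 + 5*alpha_max`` does not exceed the prior
    expected number of biased studies: ``(N*a0/(a0+a1) - 1)/5``.
    """
    if n_studies < 2:
        raise ValueError("n_studies must be >= 2")
    bound = (expected_biased_count(n_studies, a0, a1) - 1.0) / 5.0
    if bound <= alpha_min:
        raise ValueError(
            f"alpha_max bound {bound:.3g} does not exceed alpha_min {alpha_min}: "
            "the meta-analysis is too small (or the bias prior too pessimistic) "
            "for a DP bias component"
        )
    return bound


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def truncation_K(alpha_max: float) -> int:
    """Maximum number of DP clusters, ``round(1 + 5 * alpha_max)``.

    The 1 + 5*alpha rule is the ``epsilon = 0.01`` special case of
    :func:`truncation_K_exact`; rounding is half away from zero, the rule
    consistent with all published (alpha_max, K_max) pairs.
    """
    if not alpha_max > 0:
        raise ValueError("alpha_max must be > 0")
    return _round_half_away(1.0 + 5.0 * alpha_max)


def truncation_K_exact(alpha: float, epsilon: float = DEFAULT_EPSILON) -> int:
    """Smallest truncation level with expected residual mass <= epsilon.

    After ``K - 1`` stick breaks the expected remaining mass is
    ``(alpha/(1+alpha))**(K-1)``; solving for ``K`` gives
    ``1 + log(epsilon)/log(alpha/(1+alpha))``, rounded up.  Always at least
    2 (one break plus the residual atom).
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    k = 1.0 + math.log(epsilon) / math.log(alpha / (1.0 + alpha))
    return max(2, math.ceil(k))


def tau_tail_probability(scale: float, df: int, threshold: float) -> float:
    """P(tau > threshold) under the prior 1/tau^2 ~ Scale-Gamma(scale, df).

    The scale-gamma prior on the precision induces a half-t(df) prior with
    scale ``scale`` on the standard deviation; for df = 1 this is the
    half-Cauchy, with closed-form tail ``1 - (2/pi) * arctan(t/s)``.
    """
    if not (scale > 0 and df >= 1):
        raise ValueError("need scale > 0 and df >= 1")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if df == 1:
        return 1.0 - (2.0 / math.pi) * math.atan(threshold / scale)
    return float(2.0 * stats.t.sf(threshold / scale, df))
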