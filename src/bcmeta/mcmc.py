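"""Posterior samplers for the three meta-analysis models.

Three models share the normal likelihood ``y_i ~ N(theta_i^B, SE_i^2)``:

* **random effects** (``re``): no bias, ``theta_i^B = theta_i`` with
  ``theta_i ~ N(mu_theta, tau_theta^2)``;
* **parametric bias correction** (``bc_parametric``):
  ``theta_i^B = theta_i + I_i * beta_i`` with a single-normal bias
  distribution ``beta_i ~ N(mu_beta, tau_beta^2)`` and Bernoulli(pi_B)
  indicators;
* **BC-BNP** (``bc_bnp``): the bias distribution is a Dirichlet process
  with normal base measure, truncated at K stick-breaking components, so
  biased studies share discrete bias atoms and cluster.

All three are fitted by a blocked Gibbs sampler written against the
truncated stick-breaking representation.  Every full conditional is either
conjugate (normal locations, scale-gamma precisions via the Huang-Wand
auxiliary representation, Beta stick fractions and bias probability), a
truncated-normal (uniform-bounded locations) or a truncated-Gamma (the DP
concentration on its uniform support), sampled by inverse CDF.  The
indicator and cluster label of each study are drawn jointly as one
categorical over {unbiased} and the K atoms, with prior masses
``(1 - pi_B)`` and ``pi_B * w_k``, conditional on ``theta_i``.

These mixture posteriors can be multimodal (bias assignments that relabel
which group of studies is "clean" can fit the data comparably well); runs
start from a robust anchored state — pooled effect at the
inverse-variance-weighted mean, bias flags on studies far from the
tightest half-sample of effects — and the split-R-hat warning flags chains
that disagree.

Chains are advanced in lockstep as a vectorized (chains, ...) state; a
single master seed drives the whole fit, so identical configs reproduce
identical draws.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
from scipy import special

from .data import MetaDataset
from .priors import HyperPriorConfig

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "ConvergenceWarning",
    "compose_biased_effect",
    "stick_breaking_draw",
    "fit_random_effects",
    "fit_bc_parametric",
    "fit_bc_bnp",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when split-R-hat exceeds the 1.05 threshold."""


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout: 4 chains of 50,000 iterations with 10,000 burn-in by
    default, matching the settings used for the case-study analyses."""

    chains: int = 4
    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def fast(cls, seed: int = 0) -> "McmcConfig":
        """Short profile (4 x 5,000 / 1,000 burn-in) for smoke runs."""
        return cls(chains=4, iterations=5_000, burn_in=1_000, seed=seed)

    @property
    def kept(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


class PosteriorSamples:
    """MCMC draws for one model fit.

    ``draws`` maps parameter names to arrays of shape ``(chains, kept)``
    for scalars or ``(chains, kept, dim)`` for per-study / per-atom
    quantities; burn-in is already discarded.
    """

    def __init__(
        self,
        draws: Mapping[str, np.ndarray],
        model_tag: str,
        study_ids: list[str],
        dataset_hash: str,
        config: dict,
    ) -> None:
        self.draws = dict(draws)
        self.model_tag = model_tag
        self.study_ids = list(study_ids)
        self.dataset_hash = dataset_hash
        self.config = config

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def array(self, name: str) -> np.ndarray:
        """Draws keyed by chain: shape (chains, kept, ...)."""
        try:
            return self.draws[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; available: {sorted(self.draws)}"
            ) from None

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (chains*kept, ...)."""
        a = self.array(name)
        return a.reshape(-1, *a.shape[2:])

    def rhat(self, name: str) -> float:
        return split_rhat(self.array(name).astype(float))

    def ess(self, name: str) -> float:
        import arviz as az

        return float(az.ess(self.array(name).astype(float)))


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential-scale-reduction factor for (chains, draws)."""
    c, t = chains.shape
    half = t // 2
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    b = n * means.var(ddof=1)
    w = segs.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def compose_biased_effect(theta, beta, indicator):
    """Biased study effect ``theta + indicator * beta``."""
    ind = np.asarray(indicator)
    if not np.all((ind == 0) | (ind == 1)):
        raise ValueError("indicator must be 0 or 1")
    return theta + ind * beta


def stick_breaking_draw(alpha, K, base_mu, base_tau, rng):
    """One draw of a truncated DP: K stick-breaking weights and base atoms.

    ``w_k = q_k * prod_{j<k}(1 - q_j)`` with ``q_k ~ Beta(1, alpha)`` for
    ``k < K``; the final weight is the leftover stick so the weights sum to
    one.  Atoms are i.i.d. from the ``N(base_mu, base_tau^2)`` base measure.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    if K < 2:
        raise ValueError("K must be >= 2")
    if not base_tau > 0:
        raise ValueError("base_tau must be > 0")
    q = rng.beta(1.0, alpha, size=K - 1)
    w = np.empty(K)
    stick = 1.0
    for k in range(K - 1):
        w[k] = q[k] * stick
        stick *= 1.0 - q[k]
    w[K - 1] = 1.0 - w[: K - 1].sum()
    atoms = rng.normal(base_mu, base_tau, size=K)
    return w, atoms


# ----------------------------------------------------------------------
# vectorized sampling helpers (state axis 0 = chain)
# ----------------------------------------------------------------------

_U_EPS = 1e-15


def _trunc_normal(rng, mean, sd, lo, hi):
    """Inverse-CDF truncated-normal draws, elementwise over chains."""
    a = special.ndtr((lo - mean) / sd)
    b = special.ndtr((hi - mean) / sd)
    u = rng.uniform(np.clip(a, _U_EPS, 1 - _U_EPS), np.clip(b, _U_EPS, 1 - _U_EPS))
    out = mean + sd * special.ndtri(np.clip(u, _U_EPS, 1 - _U_EPS))
    return np.clip(out, lo, hi)


def _trunc_gamma(rng, shape, rate, lo, hi):
    """Inverse-CDF truncated-Gamma draws (shape scalar, rate per chain)."""
    rate = np.maximum(rate, 1e-12)
    a = special.gammainc(shape, rate * lo)
    b = special.gammainc(shape, rate * hi)
    u = rng.uniform(np.clip(a, _U_EPS, 1 - _U_EPS), np.clip(b, _U_EPS, 1 - _U_EPS))
    out = special.gammaincinv(shape, np.clip(u, _U_EPS, 1 - _U_EPS)) / rate
    return np.clip(out, lo, hi)


def _update_scale(rng, ss, n, aux, s, df):
    """Huang-Wand conjugate block for a scale-gamma precision prior.

    The prior ``1/tau^2 ~ Scale-Gamma(s, df)`` (inducing tau ~ half-t(df)
    with scale s) is represented as ``lam | a ~ Gamma(df/2, rate=df/a)``
    with ``a ~ InvGamma(1/2, 1/s^2)``.  Given the sum of squares ``ss`` of
    ``n`` centred normal observations, both conditionals are conjugate.
    """
    lam = rng.gamma((df + n) / 2.0, 1.0 / (df / aux + ss / 2.0))
    aux = 1.0 / rng.gamma((df + 1) / 2.0, 1.0 / (df * lam + 1.0 / s**2))
    return lam, aux


def _categorical_rows(rng, logp):
    """Sample one category per row of a (..., ncat) log-probability array."""
    logp = logp - logp.max(axis=-1, keepdims=True)
    p = np.exp(logp)
    cs = np.cumsum(p, axis=-1)
    u = rng.random(logp.shape[:-1]) * cs[..., -1]
    return (u[..., None] > cs).sum(axis=-1)


def _initial_outliers(y: np.ndarray) -> np.ndarray:
    """Initial bias flags: studies far from the tightest half-sample.

    The 'shorth' (shortest half) keeps a 50% breakdown point, so the
    initializer still finds a clean core when up to half the studies carry
    planted or real bias; an interquartile fence does not.  Affects only
    the starting state, not the stationary distribution.
    """
    n = y.size
    h = n // 2 + 1
    ys = np.sort(y)
    widths = ys[h - 1 :] - ys[: n - h + 1]
    start = int(np.argmin(widths))
    core = ys[start : start + h]
    center = core.mean()
    scale = max(core.std(ddof=1), 1e-3)
    return np.abs(y - center) > 2.5 * scale


def _init_common(data: MetaDataset, mcmc: McmcConfig):
    y, se = data.y, data.se
    w = 1.0 / se**2
    mu0 = float(np.sum(w * y) / np.sum(w))
    sd0 = max(float(np.std(y)) / 2.0, 0.05)
    rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed))
    return y, se, mu0, sd0, rng


def _check_convergence(samples: PosteriorSamples, names: list[str]) -> None:
    bad = []
    for name in names:
        r = samples.rhat(name)
        if r > 1.05:
            bad.append(f"{name}: R-hat={r:.3f}")
    if bad:
        warnings.warn(
            "possible non-convergence (threshold 1.05): " + "; ".join(bad),
            ConvergenceWarning,
            stacklevel=3,
        )


def _make_samples(store, model_tag, data, priors, mcmc, extra=None):
    config = {"mcmc": asdict(mcmc), "priors": asdict(priors)}
    if extra:
        config.update(extra)
    return PosteriorSamples(store, model_tag, data.study_ids, data.fingerprint(), config)


# ----------------------------------------------------------------------
# model 1: normal-normal random effects
# ----------------------------------------------------------------------

def fit_random_effects(
    data: MetaDataset,
    priors: HyperPriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    *,
    tau_fixed: float | None = None,
) -> PosteriorSamples:
    """Fit the noninformative normal-normal random effects model.

    ``tau_fixed`` pins the between-study SD (0 collapses the model to a
    common-effect analysis); used mainly for conjugate-limit checks.
    """
    priors = priors or HyperPriorConfig()
    mcmc = mcmc or McmcConfig()
    y, se, mu0, sd0, rng = _init_common(data, mcmc)
    C, N, T = mcmc.chains, len(data), mcmc.kept
    prec_y = 1.0 / se**2

    mu_t = np.full(C, mu0)
    lam_t = np.full(C, 1.0 / sd0**2)
    aux_t = np.full(C, priors.s_theta**2)
    theta = np.tile(y, (C, 1))
    if tau_fixed is not None:
        if tau_fixed < 0:
            raise ValueError("tau_fixed must be >= 0")
        lam_t = np.full(C, np.inf if tau_fixed == 0 else 1.0 / tau_fixed**2)

    store = {
        "mu_theta": np.empty((C, T)),
        "tau_theta": np.empty((C, T)),
        "theta": np.empty((C, T, N)),
        "theta_new": np.empty((C, T)),
    }
    keep = 0
    prior_prec_mu = 1.0 / priors.sigma_mu**2
    for it in range(mcmc.iterations):
        if tau_fixed == 0:
            # common effect: theta_i == mu, conjugate update from y directly
            prec = np.sum(prec_y) + prior_prec_mu
            mean = np.full(C, np.sum(prec_y * y)) / prec
            mu_t = mean + rng.standard_normal(C) / np.sqrt(prec)
            theta = np.tile(mu_t[:, None], (1, N))
        else:
            prec = prec_y[None, :] + lam_t[:, None]
            mean = (prec_y[None, :] * y[None, :] + (lam_t * mu_t)[:, None]) / prec
            theta = mean + rng.standard_normal((C, N)) / np.sqrt(prec)

            prec_mu = N * lam_t + prior_prec_mu
            mean_mu = lam_t * theta.sum(axis=1) / prec_mu
            mu_t = mean_mu + rng.standard_normal(C) / np.sqrt(prec_mu)

            if tau_fixed is None:
                ss = ((theta - mu_t[:, None]) ** 2).sum(axis=1)
                lam_t, aux_t = _update_scale(rng, ss, N, aux_t, priors.s_theta, priors.df_theta)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            tau = np.where(np.isinf(lam_t), 0.0, 1.0 / np.sqrt(lam_t))
            store["mu_theta"][:, keep] = mu_t
            store["tau_theta"][:, keep] = tau
            store["theta"][:, keep] = theta
            store["theta_new"][:, keep] = mu_t + tau * rng.standard_normal(C)
            keep += 1

    samples = _make_samples(store, "re", data, priors, mcmc, {"tau_fixed": tau_fixed})
    if tau_fixed is None and mcmc.kept > 10:
        _check_convergence(samples, ["mu_theta", "tau_theta"])
    return samples


# ----------------------------------------------------------------------
# model 2: parametric bias correction (single-normal bias distribution)
# ----------------------------------------------------------------------

def fit_bc_parametric(
    data: MetaDataset,
    priors: HyperPriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    *,
    pi_b_fixed: float | None = None,
    indicators_fixed: np.ndarray | None = None,
) -> PosteriorSamples:
    """Fit the bias-correction model with a parametric bias component.

    ``theta_i^B = theta_i + I_i beta_i`` with ``beta_i ~ N(mu_beta,
    tau_beta^2)``; the bias location has a uniform prior on
    ``[b_lower, b_upper]``.  ``pi_b_fixed`` / ``indicators_fixed`` clamp the
    bias probability or indicator vector (used for mixture-collapse checks).
    """
    priors = priors or HyperPriorConfig()
    mcmc = mcmc or McmcConfig()
    y, se, mu0, sd0, rng = _init_common(data, mcmc)
    C, N, T = mcmc.chains, len(data), mcmc.kept
    prec_y = 1.0 / se**2

    mu_t = np.full(C, mu0)
    lam_t = np.full(C, 1.0 / sd0**2)
    aux_t = np.full(C, priors.s_theta**2)
    lam_b = np.full(C, 1.0 / sd0**2)
    aux_b = np.full(C, priors.s_beta**2)
    out = _initial_outliers(y)
    ind = np.tile(out.astype(np.int8), (C, 1))
    if indicators_fixed is not None:
        ind = np.tile(np.asarray(indicators_fixed, dtype=np.int8), (C, 1))
    mu_b = np.full(
        C,
        float(np.clip(np.mean(y[out]) - mu0 if out.any() else 0.0, priors.b_lower, priors.b_upper)),
    )
    pi_b = np.full(C, pi_b_fixed if pi_b_fixed is not None else priors.a0 / (priors.a0 + priors.a1))
    theta = np.tile(y, (C, 1)) - ind * mu_b[:, None]
    beta = rng.normal(mu_b[:, None], 1.0 / np.sqrt(lam_b)[:, None], size=(C, N))

    store = {
        "mu_theta": np.empty((C, T)),
        "tau_theta": np.empty((C, T)),
        "mu_beta": np.empty((C, T)),
        "tau_beta": np.empty((C, T)),
        "pi_b": np.empty((C, T)),
        "theta": np.empty((C, T, N)),
        "theta_b": np.empty((C, T, N)),
        "beta": np.empty((C, T, N)),
        "indicator": np.empty((C, T, N), dtype=np.int8),
        "theta_new": np.empty((C, T)),
    }
    keep = 0
    prior_prec_mu = 1.0 / priors.sigma_mu**2
    with np.errstate(divide="ignore"):
        for it in range(mcmc.iterations):
            tau2_t = 1.0 / lam_t
            tau2_b = 1.0 / lam_b
            # indicators: theta_i and beta_i collapsed, then redrawn
            if indicators_fixed is None:
                var0 = tau2_t[:, None] + se[None, :] ** 2
                var1 = var0 + tau2_b[:, None]
                r0 = y[None, :] - mu_t[:, None]
                r1 = r0 - mu_b[:, None]
                logit = (
                    np.log(pi_b / (1.0 - pi_b))[:, None]
                    + 0.5 * (np.log(var0) - np.log(var1))
                    + 0.5 * (r0**2 / var0 - r1**2 / var1)
                )
                ind = (rng.random((C, N)) < special.expit(logit)).astype(np.int8)

            # theta_i | I (beta_i still collapsed for biased studies)
            prec_obs = np.where(ind == 1, 1.0 / (tau2_b[:, None] + se[None, :] ** 2), prec_y[None, :])
            offset = ind * mu_b[:, None]
            prec = prec_obs + lam_t[:, None]
            mean = ((y[None, :] - offset) * prec_obs + (lam_t * mu_t)[:, None]) / prec
            theta = mean + rng.standard_normal((C, N)) / np.sqrt(prec)

            # beta_i | theta_i: conjugate where biased, prior draw otherwise
            prec_b = np.where(ind == 1, prec_y[None, :] + lam_b[:, None], lam_b[:, None])
            mean_b = np.where(
                ind == 1,
                ((y[None, :] - theta) * prec_y[None, :] + (lam_b * mu_b)[:, None]) / prec_b,
                mu_b[:, None],
            )
            beta = mean_b + rng.standard_normal((C, N)) / np.sqrt(prec_b)

            prec_mu = N * lam_t + prior_prec_mu
            mean_mu = lam_t * theta.sum(axis=1) / prec_mu
            mu_t = mean_mu + rng.standard_normal(C) / np.sqrt(prec_mu)
            ss = ((theta - mu_t[:, None]) ** 2).sum(axis=1)
            lam_t, aux_t = _update_scale(rng, ss, N, aux_t, priors.s_theta, priors.df_theta)

            # bias-location and -scale learn from the biased studies only
            nb = ind.sum(axis=1)
            sum_biased = (ind * beta).sum(axis=1)
            sd_mu_b = 1.0 / np.sqrt(np.maximum(nb, 1) * lam_b)
            mean_mu_b = sum_biased / np.maximum(nb, 1)
            prop = _trunc_normal(rng, mean_mu_b, sd_mu_b, priors.b_lower, priors.b_upper)
            flat = rng.uniform(priors.b_lower, priors.b_upper, size=C)
            mu_b = np.where(nb > 0, prop, flat)
            ss_b = (ind * (beta - mu_b[:, None]) ** 2).sum(axis=1)
            lam_b, aux_b = _update_scale(rng, ss_b, nb, aux_b, priors.s_beta, priors.df_beta)

            if pi_b_fixed is None:
                pi_b = rng.beta(priors.a0 + nb, priors.a1 + N - nb)

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                tau = 1.0 / np.sqrt(lam_t)
                store["mu_theta"][:, keep] = mu_t
                store["tau_theta"][:, keep] = tau
                store["mu_beta"][:, keep] = mu_b
                store["tau_beta"][:, keep] = 1.0 / np.sqrt(lam_b)
                store["pi_b"][:, keep] = pi_b
                store["theta"][:, keep] = theta
                store["theta_b"][:, keep] = theta + ind * beta
                store["beta"][:, keep] = beta
                store["indicator"][:, keep] = ind
                store["theta_new"][:, keep] = mu_t + tau * rng.standard_normal(C)
                keep += 1

    samples = _make_samples(
        store, "bc_parametric", data, priors, mcmc,
        {"pi_b_fixed": pi_b_fixed, "indicators_clamped": indicators_fixed is not None},
    )
    if mcmc.kept > 10:
        _check_convergence(samples, ["mu_theta", "tau_theta"])
    return samples


# ----------------------------------------------------------------------
# model 3: BC-BNP (truncated Dirichlet-process bias distribution)
# ----------------------------------------------------------------------

def fit_bc_bnp(
    data: MetaDataset,
    priors: HyperPriorConfig | None = None,
    mcmc: McmcConfig | None = None,
    *,
    pi_b_fixed: float | None = None,
) -> PosteriorSamples:
    """Fit the bias-corrected Bayesian nonparametric model.

    The bias distribution is a DP with ``N(mu_beta, tau_beta^2)`` base
    measure and concentration ``alpha ~ Uniform(alpha_min, alpha_max)``,
    truncated at K stick-breaking atoms.  ``priors.alpha_max`` and
    ``priors.K`` are resolved from the dataset size when unset.  Cluster
    labels use the published convention: 1 is the unbiased cluster, labels
    2..K+1 index the bias atoms.
    """
    priors = (priors or HyperPriorConfig()).resolve(len(data))
    mcmc = mcmc or McmcConfig()
    if priors.K < 2:
        raise ValueError("DP truncation level K must be >= 2")
    y, se, mu0, sd0, rng = _init_common(data, mcmc)
    C, N, T, K = mcmc.chains, len(data), mcmc.kept, priors.K
    prec_y = 1.0 / se**2
    amin, amax = priors.alpha_min, priors.alpha_max

    mu_t = np.full(C, mu0)
    lam_t = np.full(C, 1.0 / sd0**2)
    aux_t = np.full(C, priors.s_theta**2)
    lam_b = np.full(C, 1.0 / sd0**2)
    aux_b = np.full(C, priors.s_beta**2)
    out = _initial_outliers(y)
    mu_b = np.full(
        C,
        float(np.clip(np.mean(y[out]) - mu0 if out.any() else 0.0, priors.b_lower, priors.b_upper)),
    )
    pi_b = np.full(C, pi_b_fixed if pi_b_fixed is not None else priors.a0 / (priors.a0 + priors.a1))
    alpha = np.full(C, 0.5 * (amin + amax))
    atoms = rng.normal(mu_b[:, None], 1.0 / np.sqrt(lam_b)[:, None], size=(C, K))
    # labels: 0 = unbiased, 1..K = bias atoms (stored 1-based later)
    labels = np.where(out[None, :], rng.integers(1, K + 1, size=(C, N)), 0)
    theta = np.tile(y, (C, 1))
    w = np.full((C, K), 1.0 / K)

    store = {
        "mu_theta": np.empty((C, T)),
        "tau_theta": np.empty((C, T)),
        "mu_beta": np.empty((C, T)),
        "tau_beta": np.empty((C, T)),
        "pi_b": np.empty((C, T)),
        "alpha": np.empty((C, T)),
        "theta": np.empty((C, T, N)),
        "theta_b": np.empty((C, T, N)),
        "beta": np.empty((C, T, N)),
        "indicator": np.empty((C, T, N), dtype=np.int8),
        "label": np.empty((C, T, N), dtype=np.int16),
        "weights": np.empty((C, T, K)),
        "atoms": np.empty((C, T, K)),
        "theta_new": np.empty((C, T)),
    }
    keep = 0
    prior_prec_mu = 1.0 / priors.sigma_mu**2
    chain_idx = np.arange(C)[:, None]
    flat_offset = (np.arange(C) * (K + 1))[:, None]
    bcast_prec = np.broadcast_to(prec_y, (C, N)).ravel()

    with np.errstate(divide="ignore"):
        for it in range(mcmc.iterations):
            # (I_i, L_i) jointly: one categorical over {unbiased} + K atoms
            # with prior masses (1 - pi_B) and pi_B * w_k, given theta_i
            logp = np.empty((C, N, K + 1))
            r0 = y[None, :] - theta
            logp[:, :, 0] = np.log1p(-pi_b)[:, None] - 0.5 * r0**2 * prec_y[None, :]
            rk = r0[:, :, None] - atoms[:, None, :]  # (C, N, K)
            logp[:, :, 1:] = (
                np.log(pi_b)[:, None, None]
                + np.log(np.maximum(w, 1e-300))[:, None, :]
                - 0.5 * rk**2 * prec_y[None, :, None]
            )
            labels = _categorical_rows(rng, logp)
            ind = (labels > 0).astype(np.int8)

            # theta_i | labels
            atoms_pad = np.concatenate([np.zeros((C, 1)), atoms], axis=1)
            beta_sel = np.take_along_axis(atoms_pad, labels, axis=1)
            prec = prec_y[None, :] + lam_t[:, None]
            mean = ((y[None, :] - ind * beta_sel) * prec_y[None, :] + (lam_t * mu_t)[:, None]) / prec
            theta = mean + rng.standard_normal((C, N)) / np.sqrt(prec)

            # atoms: conjugate from member studies' residuals y_i - theta_i
            flat = (flat_offset + labels).ravel()
            resid_w = ((y[None, :] - theta) * prec_y[None, :]).ravel()
            counts = np.bincount(flat, minlength=C * (K + 1)).reshape(C, K + 1)
            sum_prec = np.bincount(flat, weights=bcast_prec, minlength=C * (K + 1)).reshape(C, K + 1)
            sum_r = np.bincount(flat, weights=resid_w, minlength=C * (K + 1)).reshape(C, K + 1)
            post_prec = lam_b[:, None] + sum_prec[:, 1:]
            post_mean = ((lam_b * mu_b)[:, None] + sum_r[:, 1:]) / post_prec
            atoms = post_mean + rng.standard_normal((C, K)) / np.sqrt(post_prec)

            # stick fractions and weights
            n_k = counts[:, 1:].astype(float)  # (C, K)
            tail = np.cumsum(n_k[:, ::-1], axis=1)[:, ::-1] - n_k  # studies past atom k
            q = rng.beta(1.0 + n_k[:, : K - 1], alpha[:, None] + tail[:, : K - 1])
            q = np.clip(q, 1e-12, 1.0 - 1e-12)
            one_minus = np.cumprod(1.0 - q, axis=1)
            w[:, 0] = q[:, 0]
            w[:, 1 : K - 1] = q[:, 1:] * one_minus[:, : K - 2]
            w[:, K - 1] = 1.0 - w[:, : K - 1].sum(axis=1)
            np.clip(w, 0.0, None, out=w)

            # model-of-interest hyperparameters
            prec_mu = N * lam_t + prior_prec_mu
            mean_mu = lam_t * theta.sum(axis=1) / prec_mu
            mu_t = mean_mu + rng.standard_normal(C) / np.sqrt(prec_mu)
            ss = ((theta - mu_t[:, None]) ** 2).sum(axis=1)
            lam_t, aux_t = _update_scale(rng, ss, N, aux_t, priors.s_theta, priors.df_theta)

            # base-measure location/scale from the K atoms (blocked Gibbs)
            mu_b = _trunc_normal(
                rng, atoms.mean(axis=1), 1.0 / np.sqrt(K * lam_b), priors.b_lower, priors.b_upper
            )
            ss_b = ((atoms - mu_b[:, None]) ** 2).sum(axis=1)
            lam_b, aux_b = _update_scale(rng, ss_b, K, aux_b, priors.s_beta, priors.df_beta)

            nb = ind.sum(axis=1)
            if pi_b_fixed is None:
                pi_b = rng.beta(priors.a0 + nb, priors.a1 + N - nb)

            # concentration: truncated Gamma(K, -sum log(1 - q_k))
            rate = -np.log1p(-q).sum(axis=1)
            alpha = _trunc_gamma(rng, float(K), rate, amin, amax)

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                tau = 1.0 / np.sqrt(lam_t)
                store["mu_theta"][:, keep] = mu_t
                store["tau_theta"][:, keep] = tau
                store["mu_beta"][:, keep] = mu_b
                store["tau_beta"][:, keep] = 1.0 / np.sqrt(lam_b)
                store["pi_b"][:, keep] = pi_b
                store["alpha"][:, keep] = alpha
                store["theta"][:, keep] = theta
                store["theta_b"][:, keep] = theta + ind * beta_sel
                store["beta"][:, keep] = ind * beta_sel
                store["indicator"][:, keep] = ind
                store["label"][:, keep] = labels + 1  # published convention
                store["weights"][:, keep] = w
                store["atoms"][:, keep] = atoms
                store["theta_new"][:, keep] = mu_t + tau * rng.standard_normal(C)
                keep += 1

    samples = _make_samples(store, "bc_bnp", data, priors, mcmc, {"pi_b_fixed": pi_b_fixed})
    if mcmc.kept > 10:
        _check_convergence(samples, ["mu_theta", "tau_theta"] + ([] if pi_b_fixed is not None else ["pi_b"]))
    return samples
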