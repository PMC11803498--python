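"""Synthetic meta-analyses with planted internal-validity bias.

Studies are generated from a normal-normal random effects model on the
log-odds-ratio scale: ``theta_i ~ N(mu, tau^2)``, ``y_i ~ N(theta_i,
sigma^2 / n_i)`` with ``SE_i = sigma / sqrt(n_i)`` and study sizes ``n_i``
resampled from a pool of realistic sizes.  A chosen subset of studies is
then shifted by a deterministic, level-specific amount — *mild*, *large* or
*extreme* — placed at outlier fences of the marginal distribution of ``y``:
``Q3 + {1.5, 2.25, 3.0} * IQR``, where the quartiles are those of
``N(mu, tau^2 + sigma^2 / n_bar)`` at the realized mean sample size.

Defaults follow the study conditions used throughout this package's
evaluation: pooled log OR ``mu = 1``, heterogeneity ``tau = 0.5`` (fairly
high on the log-OR scale), within-study SD ``sigma = 4.95`` (the median
implied by the bundled case-study data), and sample sizes resampled from
the 18 COVID-study totals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data import MetaDataset, Scale, StudyRecord, covid_fixture
from .mcmc import (
    McmcConfig,
    PosteriorSamples,
    fit_bc_bnp,
    fit_bc_parametric,
    fit_random_effects,
)
from .priors import HyperPriorConfig

__all__ = [
    "BiasLevel",
    "ScenarioConfig",
    "SimulatedMeta",
    "bias_levels",
    "simulate_scenario",
    "oracle_subset",
    "run_model_comparison",
    "scenario_grid",
    "covid_size_pool",
    "surrogate_size_pool",
]


class BiasLevel(str, enum.Enum):
    NONE = "none"
    MILD = "mild"
    LARGE = "large"
    EXTREME = "extreme"


def covid_size_pool() -> tuple[int, ...]:
    """Study sample sizes of the bundled 18-study COVID meta-analysis."""
    return tuple(int(s.n) for s in covid_fixture())


def surrogate_size_pool(n: int = 30, seed: int = 20_24) -> tuple[int, ...]:
    """A packaged surrogate pool of study sizes, log-uniform on [40, 1200].

    Stands in for the external 31-trial size pool used in larger scenarios;
    the range matches the bundled COVID sizes.
    """
    rng = np.random.default_rng(seed)
    return tuple(int(round(x)) for x in np.exp(rng.uniform(np.log(40), np.log(1200), n)))


#: Scenario grid: (N, percent biased) -> (mild, large, extreme) counts.
SCENARIO_GRID: dict[tuple[int, int], tuple[int, int, int]] = {
    (20, 0): (0, 0, 0),
    (20, 10): (0, 1, 1),
    (20, 30): (2, 2, 2),
    (20, 50): (3, 3, 4),
    (30, 0): (0, 0, 0),
    (30, 10): (1, 1, 1),
    (30, 30): (3, 3, 3),
    (30, 50): (5, 5, 5),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario.

    ``n_mild + n_large + n_extreme`` studies receive planted bias; the rest
    are clean.  ``size_pool`` is resampled with replacement.
    """

    n_studies: int = 20
    n_mild: int = 0
    n_large: int = 0
    n_extreme: int = 0
    mu_theta_true: float = 1.0
    tau_theta_true: float = 0.5
    sigma_within: float = 4.95
    size_pool: tuple[int, ...] = field(default_factory=covid_size_pool)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "size_pool", tuple(int(n) for n in self.size_pool))
        if self.n_studies < 2:
            raise ValueError("n_studies must be >= 2")
        for name in ("n_mild", "n_large", "n_extreme"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_biased > self.n_studies:
            raise ValueError("more planted biases than studies")
        if not (self.tau_theta_true > 0 and self.sigma_within > 0):
            raise ValueError("tau_theta_true and sigma_within must be > 0")
        if not self.size_pool or min(self.size_pool) < 2:
            raise ValueError("size_pool must be nonempty with all sizes >= 2")

    @property
    def n_biased(self) -> int:
        return self.n_mild + self.n_large + self.n_extreme

    @classmethod
    def from_grid(cls, n_studies: int, pct_bias: int, seed: int = 0, **kw) -> "ScenarioConfig":
        """Scenario from the standard (N, % biased) grid."""
        try:
            mild, large, extreme = SCENARIO_GRID[(n_studies, pct_bias)]
        except KeyError:
            raise KeyError(
                f"no grid entry for N={n_studies}, {pct_bias}% bias; "
                f"available: {sorted(SCENARIO_GRID)}"
            ) from None
        if n_studies == 30 and "size_pool" not in kw:
            kw["size_pool"] = surrogate_size_pool()
        return cls(
            n_studies=n_studies, n_mild=mild, n_large=large, n_extreme=extreme,
            seed=seed, **kw,
        )


@dataclass(frozen=True)
class SimulatedMeta:
    """A synthetic meta-analysis with its ground truth."""

    data: MetaDataset
    true_theta: np.ndarray
    bias_level: tuple[BiasLevel, ...]
    bias_shift: np.ndarray
    config: ScenarioConfig

    def __post_init__(self) -> None:
        lv = np.array([b == BiasLevel.NONE for b in self.bias_level])
        if not np.all((np.asarray(self.bias_shift) == 0) == lv):
            raise ValueError("bias_shift must be 0 exactly where bias_level is none")

    @property
    def biased_mask(self) -> np.ndarray:
        return np.array([b != BiasLevel.NONE for b in self.bias_level])


def bias_levels(
    mu: float, tau: float, sigma: float, n_bar: float
) -> tuple[float, float, float]:
    """Mild/large/extreme bias shifts: Q3 + {1.5, 2.25, 3.0} * IQR.

    Quartiles are those of the marginal effect distribution
    ``N(mu, tau^2 + sigma^2 / n_bar)``.
    """
    if not (tau > 0 and sigma > 0 and n_bar >= 1):
        raise ValueError("need tau > 0, sigma > 0, n_bar >= 1")
    sd = np.sqrt(tau**2 + sigma**2 / n_bar)
    z75 = stats.norm.ppf(0.75)
    q3 = mu + z75 * sd
    iqr = 2.0 * z75 * sd
    return (q3 + 1.50 * iqr, q3 + 2.25 * iqr, q3 + 3.00 * iqr)


def simulate_scenario(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> SimulatedMeta:
    """Generate one synthetic meta-analysis with planted biases.

    Biased studies are picked by simple random sampling without
    replacement; each receives the deterministic shift of its level,
    computed at the realized mean sample size of the replicate.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    c = config
    n = rng.choice(np.asarray(c.size_pool), size=c.n_studies, replace=True)
    se = c.sigma_within / np.sqrt(n)
    theta = rng.normal(c.mu_theta_true, c.tau_theta_true, c.n_studies)
    y = rng.normal(theta, se)

    levels = [BiasLevel.NONE] * c.n_studies
    shift = np.zeros(c.n_studies)
    if c.n_biased:
        chosen = rng.choice(c.n_studies, size=c.n_biased, replace=False)
        mu_m, mu_l, mu_e = bias_levels(
            c.mu_theta_true, c.tau_theta_true, c.sigma_within, float(np.mean(n))
        )
        per_level = (
            [(BiasLevel.MILD, mu_m)] * c.n_mild
            + [(BiasLevel.LARGE, mu_l)] * c.n_large
            + [(BiasLevel.EXTREME, mu_e)] * c.n_extreme
        )
        for idx, (lv, mu_b) in zip(chosen, per_level):
            levels[idx] = lv
            shift[idx] = mu_b
    y = y + shift

    studies = tuple(
        StudyRecord(f"study-{i + 1:02d}", float(y[i]), float(se[i]), n=int(n[i]))
        for i in range(c.n_studies)
    )
    return SimulatedMeta(
        data=MetaDataset(studies, Scale.LOG_OR),
        true_theta=theta,
        bias_level=tuple(levels),
        bias_shift=shift,
        config=c,
    )


def oracle_subset(sim: SimulatedMeta) -> MetaDataset:
    """The unbiased studies only — the benchmark an oracle analyst would use."""
    keep = [i for i, b in enumerate(sim.bias_level) if b == BiasLevel.NONE]
    if len(keep) < 2:
        raise ValueError("fewer than 2 unbiased studies; oracle subset undefined")
    return sim.data.subset(keep)


MODELS = ("re", "oracle", "bc_parametric", "bc_bnp")


def run_model_comparison(
    sim: SimulatedMeta,
    mcmc: McmcConfig | None = None,
    priors: HyperPriorConfig | None = None,
) -> dict:
    """Fit all four comparators to one simulated meta-analysis.

    Returns a dict with per-model posterior summaries of ``mu_theta`` and
    ``tau_theta``, per-study bias probabilities for the two bias-corrected
    models, and the fitted :class:`PosteriorSamples` objects.
    """
    mcmc = mcmc or McmcConfig.fast()
    priors = priors or HyperPriorConfig()
    fits: dict[str, PosteriorSamples] = {
        "re": fit_random_effects(sim.data, priors, mcmc),
        "oracle": fit_random_effects(oracle_subset(sim), priors, mcmc),
        "bc_parametric": fit_bc_parametric(sim.data, priors, mcmc),
        "bc_bnp": fit_bc_bnp(sim.data, priors, mcmc),
    }
    out: dict = {"fits": fits, "summary": {}, "prob_bias": {}}
    for tag, s in fits.items():
        for par in ("mu_theta", "tau_theta"):
            d = s.flat(par)
            out["summary"][(tag, par)] = {
                "mean": float(d.mean()),
                "sd": float(d.std(ddof=1)),
                "q2.5": float(np.quantile(d, 0.025)),
                "q97.5": float(np.quantile(d, 0.975)),
            }
        if tag in ("bc_parametric", "bc_bnp"):
            out["prob_bias"][tag] = s.flat("indicator").mean(axis=0)
    return out


def scenario_grid(
    n_studies: Sequence[int] = (20, 30),
    pct_bias: Sequence[int] = (0, 10, 30, 50),
    seed: int = 0,
) -> list[ScenarioConfig]:
    """All grid scenarios, each with a seed derived from ``seed``."""
    ss = np.random.SeedSequence(seed).spawn(len(n_studies) * len(pct_bias))
    out, i = [], 0
    for n in n_studies:
        for pct in pct_bias:
            out.append(
                ScenarioConfig.from_grid(n, pct, seed=int(ss[i].generate_state(1)[0] % 2**31))
            )
            i += 1
    return out
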