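"""Posterior reporting: summaries, bias probabilities, coclustering,
occupied-cluster counts, the bias-correction diagnostic, and forest-plot
data.

All intervals are equal-tailed 95% posterior intervals (2.5% / 97.5%
quantiles).  Transformed summaries (e.g. the pooled odds ratio
``exp(mu_theta)``) are always computed by transforming draw-wise and then
summarizing, never the other way around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .mcmc import PosteriorSamples, split_rhat

__all__ = [
    "CoclusterMatrix",
    "DeltaDiagnostic",
    "summarize",
    "prob_bias",
    "cocluster",
    "cluster_heatmap_order",
    "delta_diagnostic",
    "occupied_clusters",
    "forest_data",
]

_BC_MODELS = ("bc_parametric", "bc_bnp")


def _require_bc(samples: PosteriorSamples, what: str) -> None:
    if samples.model_tag not in _BC_MODELS:
        raise ValueError(
            f"{what} requires a bias-correction model fit, got {samples.model_tag!r}"
        )


def summarize(
    samples: PosteriorSamples,
    parameters: list[str] | None = None,
    exp_transform: bool = False,
) -> pd.DataFrame:
    """Posterior summary table: mean, SD, median, 95% interval, R-hat, ESS.

    Scalar parameters get one row; per-study/per-atom parameters one row
    per component, suffixed ``[i]``.  With ``exp_transform`` every draw is
    exponentiated before summarizing (log-OR models report odds ratios).
    """
    if parameters is None:
        parameters = [p for p in samples.draws if samples.array(p).ndim == 2]
    rows = []
    for name in parameters:
        arr = samples.array(name).astype(float)
        if exp_transform:
            arr = np.exp(arr)
        comps = [(name, arr)] if arr.ndim == 2 else [
            (f"{name}[{i + 1}]", arr[:, :, i]) for i in range(arr.shape[2])
        ]
        for label, a in comps:
            flat = a.reshape(-1)
            const = np.all(flat == flat[0])
            rows.append(
                {
                    "parameter": label,
                    "mean": flat.mean(),
                    "sd": 0.0 if const else flat.std(ddof=1),
                    "median": float(np.median(flat)),
                    "q2.5": float(np.quantile(flat, 0.025)),
                    "q97.5": float(np.quantile(flat, 0.975)),
                    "rhat": 1.0 if const else split_rhat(a),
                    "ess": float(len(flat)) if const else _ess(a),
                }
            )
    return pd.DataFrame(rows).set_index("parameter")


def _ess(chains: np.ndarray) -> float:
    import arviz as az

    with np.errstate(all="ignore"):
        return float(az.ess(chains))


def prob_bias(samples: PosteriorSamples) -> pd.Series:
    """Posterior probability that each study is biased, P(I_i = 1 | data)."""
    _require_bc(samples, "prob_bias")
    p = samples.flat("indicator").mean(axis=0)
    return pd.Series(p, index=samples.study_ids, name="prob_bias")


@dataclass(frozen=True)
class CoclusterMatrix:
    """Posterior pairwise same-cluster probabilities and dissimilarity."""

    s_hat: np.ndarray
    study_ids: tuple[str, ...]
    n_draws: int

    def __post_init__(self) -> None:
        s = np.asarray(self.s_hat)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("s_hat must be square")
        if not np.allclose(s, s.T) or not np.allclose(np.diag(s), 1.0):
            raise ValueError("s_hat must be symmetric with unit diagonal")
        if s.min() < 0 or s.max() > 1 + 1e-12:
            raise ValueError("s_hat entries must lie in [0, 1]")

    @property
    def d_hat(self) -> np.ndarray:
        return 1.0 - self.s_hat

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.s_hat, index=self.study_ids, columns=self.study_ids)


def cocluster(samples: PosteriorSamples) -> CoclusterMatrix:
    """Same-cluster probability matrix from the label draws.

    Entry (i, j) is the fraction of retained draws in which studies i and j
    carry the same cluster label (label 1 being the unbiased cluster);
    invariant under relabeling of the bias atoms because only label
    equality is compared.
    """
    if "label" not in samples.draws:
        raise ValueError(
            f"cocluster requires label draws; model {samples.model_tag!r} has none"
        )
    lab = samples.flat("label")  # (T, N)
    same = lab[:, :, None] == lab[:, None, :]
    s_hat = same.mean(axis=0)
    np.fill_diagonal(s_hat, 1.0)
    return CoclusterMatrix(s_hat, tuple(samples.study_ids), lab.shape[0])


def cluster_heatmap_order(matrix: CoclusterMatrix):
    """Complete-linkage clustering of the dissimilarity matrix.

    Returns ``(order, linkage)``: the leaf ordering (a permutation of row
    indices) and the scipy linkage matrix describing the merge tree, for
    heatmap rendering.  Equal distances are resolved toward lower study
    indices by scipy's stable ordering of the condensed distance vector.
    """
    d = matrix.d_hat.copy()
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    link = hierarchy.linkage(condensed, method="complete")
    order = list(hierarchy.leaves_list(link))
    return order, link


@dataclass(frozen=True)
class DeltaDiagnostic:
    """The bias-correction-needed diagnostic.

    ``delta = mu_beta - mu_theta`` draw-wise; correction is deemed
    unnecessary when the 95% interval of delta overlaps the posterior mean
    of ``2 * tau_theta``.
    """

    delta_draws: np.ndarray
    pi_b_draws: np.ndarray
    delta_interval: tuple[float, float]
    two_tau_mean: float

    @property
    def correction_needed(self) -> bool:
        lo, hi = self.delta_interval
        return not (lo <= self.two_tau_mean <= hi)


def delta_diagnostic(samples: PosteriorSamples) -> DeltaDiagnostic:
    """Compute the delta-vs-pi_B diagnostic from a bias-correction fit."""
    _require_bc(samples, "delta_diagnostic")
    delta = samples.flat("mu_beta") - samples.flat("mu_theta")
    lo, hi = np.quantile(delta, [0.025, 0.975])
    return DeltaDiagnostic(
        delta_draws=delta,
        pi_b_draws=samples.flat("pi_b"),
        delta_interval=(float(lo), float(hi)),
        two_tau_mean=float(2.0 * samples.flat("tau_theta").mean()),
    )


def occupied_clusters(samples: PosteriorSamples):
    """Number of occupied bias clusters per draw, with a summary.

    Per retained draw this counts the distinct bias-atom labels among
    studies currently flagged biased (0 when none is).  Returns
    ``(counts, summary_dict)`` with the posterior median and equal-tailed
    95% interval.
    """
    if "label" not in samples.draws:
        raise ValueError("occupied_clusters requires label draws (BC-BNP fit)")
    lab = samples.flat("label")
    ind = samples.flat("indicator")
    masked = np.where(ind == 1, lab, -1)
    masked.sort(axis=1)
    distinct = (np.diff(masked, axis=1) != 0).sum(axis=1) + 1
    counts = np.where((masked == -1).all(axis=1), 0, distinct - (masked[:, 0] == -1))
    lo, hi = np.quantile(counts, [0.025, 0.975])
    summary = {
        "median": float(np.median(counts)),
        "q2.5": float(lo),
        "q97.5": float(hi),
    }
    return counts, summary


def forest_data(samples: PosteriorSamples) -> pd.DataFrame:
    """Per-study paired summaries of the biased and bias-corrected effects.

    For each study: median and 95% interval of the biased effect
    ``theta_b`` and of the bias-corrected effect ``theta``, plus
    P(I_i = 1 | data) — the rows of a two-line-per-study forest plot.
    """
    _require_bc(samples, "forest_data")
    theta = samples.flat("theta")
    theta_b = samples.flat("theta_b")
    rows = []
    p = prob_bias(samples)
    for i, sid in enumerate(samples.study_ids):
        rows.append(
            {
                "study_id": sid,
                "theta_b_median": float(np.median(theta_b[:, i])),
                "theta_b_q2.5": float(np.quantile(theta_b[:, i], 0.025)),
                "theta_b_q97.5": float(np.quantile(theta_b[:, i], 0.975)),
                "theta_median": float(np.median(theta[:, i])),
                "theta_q2.5": float(np.quantile(theta[:, i], 0.025)),
                "theta_q97.5": float(np.quantile(theta[:, i], 0.975)),
                "prob_bias": float(p.iloc[i]),
            }
        )
    return pd.DataFrame(rows).set_index("study_id")
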