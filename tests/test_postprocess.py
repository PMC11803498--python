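"""Posterior reporting: summaries, coclustering, occupied-cluster counts,
and the bias-correction diagnostic."""

import numpy as np
import pandas as pd
import pytest

from bcmeta import (
    CoclusterMatrix,
    PosteriorSamples,
    cluster_heatmap_order,
    cocluster,
    delta_diagnostic,
    forest_data,
    occupied_clusters,
    prob_bias,
    summarize,
)


def _samples(draws, model_tag="bc_bnp", ids=None):
    n = next(a.shape[2] for a in draws.values() if a.ndim == 3)
    ids = ids or [f"s{i}" for i in range(n)]
    return PosteriorSamples(draws, model_tag, ids, "test", {})


@pytest.fixture
def label_fixture(rng):
    """5 studies x 100 draws of labels/indicators with known structure."""
    lab = rng.integers(1, 5, size=(2, 50, 5)).astype(np.int16)
    ind = (lab > 1).astype(np.int8)
    return _samples({"label": lab, "indicator": ind})


class TestSummarize:
    def test_quantiles_match_sort_based_oracle(self, rng):
        draws = rng.gamma(2.0, 1.5, size=(4, 250))
        s = PosteriorSamples({"x": draws}, "re", [], "t", {})
        row = summarize(s, ["x"]).loc["x"]
        flat = np.sort(draws.ravel())
        # linear-interpolation order statistic, same convention as the
        # implementation is expected to follow
        def q(p):
            h = p * (flat.size - 1)
            lo = int(np.floor(h))
            return flat[lo] + (h - lo) * (flat[min(lo + 1, flat.size - 1)] - flat[lo])

        assert row["q2.5"] == pytest.approx(q(0.025), rel=1e-12)
        assert row["q97.5"] == pytest.approx(q(0.975), rel=1e-12)
        assert row["median"] == pytest.approx(q(0.5), rel=1e-12)
        assert row["mean"] == pytest.approx(flat.mean(), rel=1e-12)

    def test_constant_draws_collapse(self):
        s = PosteriorSamples({"c": np.full((2, 40), 3.25)}, "re", [], "t", {})
        row = summarize(s, ["c"]).loc["c"]
        assert row["sd"] == 0.0
        assert row["q2.5"] == row["q97.5"] == 3.25
        assert row["rhat"] == 1.0

    def test_exp_transform_is_drawwise_not_summary_then_exp(self, rng):
        draws = rng.normal(0.0, 1.5, size=(2, 500))  # strongly skewed after exp
        s = PosteriorSamples({"x": draws}, "re", [], "t", {})
        row = summarize(s, ["x"], exp_transform=True).loc["x"]
        assert row["mean"] == pytest.approx(np.exp(draws).mean(), rel=1e-12)
        assert row["mean"] > np.exp(draws.mean()) * 1.5  # Jensen gap is material

    def test_unknown_parameter_raises(self, label_fixture):
        with pytest.raises(KeyError, match="nope"):
            summarize(label_fixture, ["nope"])


class TestProbBias:
    def test_equals_counting_oracle(self, label_fixture):
        p = prob_bias(label_fixture)
        ind = label_fixture.flat("indicator")
        for i, sid in enumerate(label_fixture.study_ids):
            count = sum(int(ind[t, i]) for t in range(ind.shape[0]))
            assert p[sid] == pytest.approx(count / ind.shape[0])

    def test_all_zero_draws_give_zero(self):
        s = _samples(
            {"indicator": np.zeros((2, 30, 4), dtype=np.int8),
             "label": np.ones((2, 30, 4), dtype=np.int16)}
        )
        assert (prob_bias(s) == 0).all()

    def test_random_effects_fit_unsupported(self):
        s = PosteriorSamples({"mu_theta": np.zeros((2, 10))}, "re", ["a"], "t", {})
        with pytest.raises(ValueError, match="bias-correction"):
            prob_bias(s)


class TestCocluster:
    def test_matches_brute_force_double_loop(self, label_fixture):
        mat = cocluster(label_fixture)
        lab = label_fixture.flat("label")
        t, n = lab.shape
        brute = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                brute[a, b] = sum(lab[d, a] == lab[d, b] for d in range(t)) / t
        np.fill_diagonal(brute, 1.0)
        np.testing.assert_allclose(mat.s_hat, brute, atol=1e-12)
        np.testing.assert_allclose(mat.d_hat, 1 - brute, atol=1e-12)

    def test_single_draw_all_equal_labels(self):
        s = _samples(
            {"label": np.full((1, 1, 6), 3, dtype=np.int16),
             "indicator": np.ones((1, 1, 6), dtype=np.int8)}
        )
        assert (cocluster(s).s_hat == 1.0).all()

    def test_never_coclustered_pair_has_zero_entry(self):
        lab = np.ones((1, 20, 2), dtype=np.int16)
        lab[:, :, 1] = 2
        s = _samples({"label": lab, "indicator": (lab > 1).astype(np.int8)})
        assert cocluster(s).s_hat[0, 1] == 0.0

    def test_invariant_under_atom_relabeling(self, label_fixture):
        base = cocluster(label_fixture).s_hat
        lab = label_fixture.array("label").copy()
        swapped = lab.copy()
        swapped[lab == 2], swapped[lab == 3] = 3, 2
        s2 = _samples({"label": swapped, "indicator": (swapped > 1).astype(np.int8)})
        np.testing.assert_allclose(cocluster(s2).s_hat, base, atol=1e-12)

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            CoclusterMatrix(np.array([[1.0, 0.2], [0.4, 1.0]]), ("a", "b"), 10)


class TestClusterHeatmapOrder:
    def test_block_diagonal_blocks_stay_contiguous(self):
        s = np.eye(6)
        s[:3, :3] = 0.9
        s[3:, 3:] = 0.9
        np.fill_diagonal(s, 1.0)
        mat = CoclusterMatrix(s, tuple("abcdef"), 100)
        order, _ = cluster_heatmap_order(mat)
        assert {frozenset(order[:3]), frozenset(order[3:])} == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5})
        }

    def test_three_leaf_complete_linkage_hand_worked(self):
        # d(a,b)=0.1, d(a,c)=0.9, d(b,c)=0.6: (a,b) merge first at 0.1,
        # then c joins at max(0.9, 0.6) = 0.9
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.6], [0.9, 0.6, 0]], float)
        mat = CoclusterMatrix(1 - d, ("a", "b", "c"), 10)
        order, link = cluster_heatmap_order(mat)
        assert link[0, 2] == pytest.approx(0.1)
        assert sorted(link[0, :2]) == [0, 1]
        assert link[1, 2] == pytest.approx(0.9)

    def test_order_is_permutation_of_studies(self, label_fixture):
        order, _ = cluster_heatmap_order(cocluster(label_fixture))
        assert sorted(order) == list(range(5))


class TestOccupiedClusters:
    def test_matches_brute_force_distinct_count(self, label_fixture):
        counts, summary = occupied_clusters(label_fixture)
        lab = label_fixture.flat("label")
        ind = label_fixture.flat("indicator")
        brute = np.array(
            [len({int(l) for l, i in zip(row, irow) if i == 1}) for row, irow in zip(lab, ind)]
        )
        np.testing.assert_array_equal(counts, brute)
        assert summary["median"] == np.median(brute)

    def test_zero_when_no_study_is_biased(self):
        s = _samples(
            {"label": np.ones((1, 8, 3), dtype=np.int16),
             "indicator": np.zeros((1, 8, 3), dtype=np.int8)}
        )
        counts, summary = occupied_clusters(s)
        assert (counts == 0).all()
        assert summary["median"] == 0.0


class TestDeltaDiagnostic:
    def test_decision_is_pure_function_of_draws(self, bnp_fit):
        d1 = delta_diagnostic(bnp_fit)
        d2 = delta_diagnostic(bnp_fit)
        assert d1.delta_interval == d2.delta_interval
        assert d1.correction_needed == d2.correction_needed
        np.testing.assert_array_equal(d1.delta_draws, d2.delta_draws)

    def test_boundary_case_constant_delta_at_two_tau(self):
        t = 200
        tau = np.full((1, t), 0.4)
        mu_t = np.full((1, t), 1.0)
        mu_b = mu_t + 2 * tau
        s = PosteriorSamples(
            {"mu_theta": mu_t, "mu_beta": mu_b, "tau_theta": tau,
             "pi_b": np.full((1, t), 0.5)},
            "bc_parametric", ["a"], "t", {},
        )
        diag = delta_diagnostic(s)
        assert diag.delta_interval[0] == pytest.approx(diag.delta_interval[1])
        assert diag.two_tau_mean == pytest.approx(0.8)
        assert not diag.correction_needed

    def test_clear_separation_flags_correction(self):
        t = 500
        rngl = np.random.default_rng(1)
        s = PosteriorSamples(
            {"mu_theta": rngl.normal(0, 0.05, (1, t)),
             "mu_beta": rngl.normal(5.0, 0.05, (1, t)),
             "tau_theta": np.abs(rngl.normal(0.3, 0.02, (1, t))),
             "pi_b": rngl.beta(8, 2, (1, t))},
            "bc_bnp", ["a"], "t", {},
        )
        assert delta_diagnostic(s).correction_needed


class TestForestData:
    def test_shapes_and_probability_column(self, bnp_fit):
        fd = forest_data(bnp_fit)
        assert list(fd.index) == bnp_fit.study_ids
        assert ((fd["prob_bias"] >= 0) & (fd["prob_bias"] <= 1)).all()
        assert (fd["theta_q2.5"] <= fd["theta_median"]).all()
        assert (fd["theta_median"] <= fd["theta_q97.5"]).all()

    def test_mc_stability_of_cocluster_matrix_across_chain_halves(self):
        # needs a well-identified posterior: one planted outlier, the rest
        # exchangeable, so the label structure is stable along a long chain
        import numpy as _np

        from bcmeta import McmcConfig, MetaDataset, StudyRecord, fit_bc_bnp

        gen = _np.random.default_rng(3)
        y = gen.normal(1.0, 0.4, 12)
        y[4] += 6.0
        data = MetaDataset(
            tuple(StudyRecord(f"s{i}", float(v), 0.3) for i, v in enumerate(y))
        )
        fit = fit_bc_bnp(
            data, mcmc=McmcConfig(chains=4, iterations=20_000, burn_in=4_000, seed=1234)
        )
        lab = fit.array("label")
        half = lab.shape[1] // 2
        def s_hat(a):
            flat = a.reshape(-1, a.shape[2])
            same = flat[:, :, None] == flat[:, None, :]
            return same.mean(axis=0)
        s1, s2 = s_hat(lab[:, :half]), s_hat(lab[:, half:])
        assert np.abs(s1 - s2).max() < 0.05
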