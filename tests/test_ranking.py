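import math

import numpy as np
import pytest

from dacrank import (
    ExpertBelief,
    ModelSpec,
    ObservationSet,
    RankingConfig,
    ValidationError,
    classify_agreement,
    dac2,
    dac_scores,
    dac_vector,
    fit_posterior,
    full_report,
    kl_normal_normal,
    log_marginal_likelihood,
    normal,
    pairwise_table,
    rank_experts,
    worked_example,
)


class TestDacScores:
    def test_worked_example_ratio(self):
        """Reference N(0,1), expert N(0.5,1), benchmark N(0,900): DAC = 0.125/2.902."""
        ex = worked_example()
        kl_d, kl_J, dac = dac_scores(
            ex["reference_posterior"], [ex["expert_prior"]], ex["benchmark"]
        )
        assert round(kl_d[0], 3) == 0.125
        assert round(kl_J, 3) == 2.902
        assert round(dac[0], 3) == 0.043
        assert classify_agreement(dac[0]) == "agreement"

    def test_expert_equal_to_benchmark_scores_one(self):
        bench = normal(0, 30)
        _, _, dac = dac_scores(normal(0, 1), [bench], bench)
        assert dac[0] == pytest.approx(1.0, abs=1e-12)

    def test_expert_equal_to_posterior_scores_zero(self):
        _, _, dac = dac_scores(normal(0, 1), [normal(0, 1)], normal(0, 30))
        assert dac[0] == 0.0

    def test_benchmark_equal_to_posterior_is_degenerate(self):
        ref = normal(0, 1)
        with pytest.raises(ValidationError):
            dac_scores(ref, [normal(0.5, 1)], ref)


class TestClassify:
    @pytest.mark.parametrize(
        "score, label",
        [(0.043, "agreement"), (2.26, "disagreement"), (1.0, "agreement"), (0.0, "agreement")],
    )
    def test_strict_threshold_at_one(self, score, label):
        assert classify_agreement(score) == label

    def test_negative_score_rejected(self):
        with pytest.raises(ValidationError):
            classify_agreement(-0.1)


class TestRankExperts:
    def test_published_dac_ranking(self):
        assert list(rank_experts([0.56, 1.12, 2.26, 0.07], "ascending")) == [2, 3, 4, 1]

    def test_published_evidence_ranking(self):
        log_m = np.log([5.57e-68, 6.82e-68, 2.19e-69, 1.72e-67])
        assert list(rank_experts(log_m, "descending")) == [3, 2, 4, 1]

    def test_ties_broken_by_input_order(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="dacrank.ranking"):
            ranks = rank_experts([1.0, 1.0, 1.0, 1.0], "ascending")
        assert list(ranks) == [1, 2, 3, 4]
        assert any("tie" in r.message for r in caplog.records)

    def test_infinite_score_ranks_last(self):
        assert list(rank_experts([0.5, math.inf, 1.2], "ascending")) == [1, 3, 2]


class TestPairwise:
    def test_published_entries(self):
        kl = [1.43, 2.86, 5.76, 0.19]
        log_m = np.log([5.57e-68, 6.82e-68, 2.19e-69, 1.72e-67])
        pt = pairwise_table(kl, log_m)
        assert pt.kl_ratio.iloc[1, 0] == pytest.approx(2.00, abs=5e-3)
        assert round(pt.bf.iloc[1, 0], 2) == 1.22
        np.testing.assert_array_equal(np.diag(pt.kl_ratio), 1.0)
        np.testing.assert_array_equal(np.diag(pt.bf), 1.0)

    def test_reciprocal_symmetry(self, rng):
        kl = rng.uniform(0.1, 5.0, size=4)
        log_m = rng.uniform(-160, -150, size=4)
        pt = pairwise_table(kl, log_m)
        np.testing.assert_allclose(pt.kl_ratio.values * pt.kl_ratio.values.T, 1.0, rtol=1e-12)
        np.testing.assert_allclose(pt.bf.values * pt.bf.values.T, 1.0, rtol=1e-12)

    def test_rejects_nonpositive_kl(self):
        with pytest.raises(ValidationError):
            pairwise_table([0.0, 1.0], [-1.0, -2.0])


class TestDac2:
    def test_reduces_to_bf_when_posteriors_agree(self):
        assert dac2(math.log(0.21), 0.0) == pytest.approx(0.21)

    def test_identity_expert_scores_one(self):
        assert dac2(0.0, 0.0) == pytest.approx(1.0)

    def test_conjugate_oracle_single_observation(self):
        """n=1, sigma=1, y=0, benchmark N(0,100), expert N(1,1): both factors
        have closed forms, and the pipeline must reproduce their product."""
        data = ObservationSet.from_values([0.0])
        model = ModelSpec(sigma_mode="fixed", sigma=1.0)
        bench, expert = normal(0, 10), normal(1, 1)

        log_bf = (
            log_marginal_likelihood(data, bench, model).log_m
            - log_marginal_likelihood(data, expert, model).log_m
        )
        ref_post = fit_posterior(data, bench, model)
        exp_post = fit_posterior(data, expert, model)
        kl_posts = kl_normal_normal(ref_post.density, exp_post.density).value
        value = dac2(log_bf, kl_posts)

        # independent closed forms: m(y) = N(0; mu0, 1 + tau^2), conjugate
        # posteriors N(mu0 tau^2-weighted, .) and the normal-normal KL
        from scipy import stats

        m_bench = stats.norm.logpdf(0.0, 0.0, math.sqrt(1 + 100))
        m_exp = stats.norm.logpdf(0.0, 1.0, math.sqrt(2))
        s_bench = math.sqrt(1 / (1 + 1 / 100))
        s_exp = math.sqrt(0.5)
        mu_exp = 0.5
        kl_cf = (
            math.log(s_exp / s_bench)
            + (s_bench**2 + (0.0 - mu_exp) ** 2) / (2 * s_exp**2)
            - 0.5
        )
        assert value == pytest.approx(math.exp(m_bench - m_exp + kl_cf), rel=1e-6)


class TestReports:
    def test_dac_vector_reconstruction(self, std_normal_data, panel, wide_uniform, plugin_model):
        rep = dac_vector(RankingConfig(panel, wide_uniform, plugin_model, std_normal_data))
        np.testing.assert_allclose(rep.dac * rep.kl_J, rep.kl, rtol=1e-10)
        assert sorted(rep.dac_rank) == [1, 2, 3, 4]
        assert rep.agreement_dac == [classify_agreement(v) for v in rep.dac]

    def test_ranking_invariant_across_uninformative_benchmarks(
        self, std_normal_data, panel, plugin_model, wide_uniform, wide_normal
    ):
        rep_u = dac_vector(RankingConfig(panel, wide_uniform, plugin_model, std_normal_data))
        rep_n = dac_vector(RankingConfig(panel, wide_normal, plugin_model, std_normal_data))
        np.testing.assert_array_equal(rep_u.dac_rank, rep_n.dac_rank)
        np.testing.assert_allclose(rep_u.kl, rep_n.kl, atol=1e-2)

    def test_full_report_fields_consistent(self, std_normal_data, panel, wide_uniform, plugin_model):
        rep = full_report(RankingConfig(panel, wide_uniform, plugin_model, std_normal_data))
        np.testing.assert_allclose(
            rep.bf_Jd, np.exp(rep.log_m_J - rep.log_m), rtol=1e-12
        )
        assert sorted(rep.bf_rank) == [1, 2, 3, 4]
        # DAC2 >= BF (the posterior-KL factor is >= 1)
        assert np.all(rep.dac2 >= rep.bf_Jd * (1 - 1e-12))
        frame = rep.to_frame()
        assert list(frame["expert_id"]) == [e.expert_id for e in panel]

    def test_overconfidence_blows_up_kl_but_not_bf(self, plugin_model):
        """Two experts equally off in location; the narrower one loses far
        more information, while evidence stays bounded."""
        from dacrank import generate_dataset

        data = generate_dataset(n=104, mu=2.2, sigma=0.9, seed=21)
        post = fit_posterior(data, normal(0, 100), plugin_model)
        offset = post.mu1 + 0.4
        kl_wide = kl_normal_normal(post.density, normal(offset, 0.09)).value
        kl_tight = kl_normal_normal(post.density, normal(offset, 0.01)).value
        assert kl_tight > 10 * kl_wide
        lm_wide = log_marginal_likelihood(data, normal(offset, 0.09), plugin_model).log_m
        lm_tight = log_marginal_likelihood(data, normal(offset, 0.01), plugin_model).log_m
        assert np.isfinite(lm_tight) and abs(lm_tight - lm_wide) < 20

    def test_benchmark_free_mode_ranks_on_raw_kl(self, std_normal_data, panel, plugin_model):
        rep = full_report(RankingConfig(panel, None, plugin_model, std_normal_data))
        assert rep.dac is None and rep.bf_Jd is None
        assert sorted(rep.dac_rank) == [1, 2, 3, 4]
        assert rep.log_m is not None
        cols = rep.to_frame().columns
        assert "dac" not in cols

    def test_empty_panel_rejected(self, std_normal_data, plugin_model, wide_uniform):
        with pytest.raises(ValidationError):
            RankingConfig([], wide_uniform, plugin_model, std_normal_data)
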