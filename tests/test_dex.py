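"""Donor-blocked model: reductions to OLS, eBayes recovery, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pd1rev import dex, normcore, simdata
from .oracles import bh_stepup, ols_t_test


class TestBuildDesign:
    def test_fixed_blocking_rank(self):
        design = simdata.make_design(3, groups=("NI",), conditions=simdata.CONDITIONS[:3])
        x, blocks = dex.build_design(design, blocking="fixed")
        # 3 condition coefficients + (3 - 1) donor indicators
        assert np.linalg.matrix_rank(np.asarray(x, float)) == 3 + 2
        assert blocks is None

    def test_random_blocking_returns_donor_labels(self, design_one_group):
        x, blocks = dex.build_design(design_one_group, blocking="random")
        expected = design_one_group.set_index("sample_id")["donor_id"]
        assert (blocks == expected.reindex(blocks.index)).all()

    def test_five_condition_single_group_estimable(self, design_one_group):
        x, _ = dex.build_design(design_one_group)
        assert np.linalg.matrix_rank(np.asarray(x, float)) == 5

    def test_singleton_condition_rejected(self, design_one_group):
        crippled = design_one_group[
            ~((design_one_group["condition"] == "TNF")
              & (design_one_group["donor_id"] != "NI_donor1"))
        ]
        with pytest.raises(ValueError, match="single sample"):
            dex.build_design(crippled)


class TestConsensusCorrelation:
    def test_recovers_planted_correlation(self, design_one_group):
        x, blocks = dex.build_design(design_one_group)
        y = simdata.simulate_correlated_expression(2000, design_one_group, 0.5, seed=21)
        est = dex.consensus_correlation(y, x, blocks.loc[y.columns])
        assert est == pytest.approx(0.5, abs=0.1)

    def test_null_recovery(self, design_one_group):
        x, blocks = dex.build_design(design_one_group)
        y = simdata.simulate_correlated_expression(2000, design_one_group, 0.0, seed=22)
        est = dex.consensus_correlation(y, x, blocks.loc[y.columns])
        assert est == pytest.approx(0.0, abs=0.1)

    def test_always_clamped(self, design_one_group):
        x, blocks = dex.build_design(design_one_group)
        y = simdata.simulate_correlated_expression(50, design_one_group, 0.95, seed=23)
        est = dex.consensus_correlation(y, x, blocks.loc[y.columns])
        assert -0.99 <= est <= 0.99

    def test_singleton_blocks_rejected(self, design_one_group):
        x, _ = dex.build_design(design_one_group)
        y = simdata.simulate_correlated_expression(20, design_one_group, 0.2, seed=1)
        singles = pd.Series(np.arange(len(y.columns)), index=y.columns)
        with pytest.raises(ValueError, match="blocks"):
            dex.consensus_correlation(y, x, singles)


class TestFitGls:
    def test_reduces_to_ols_at_rho_zero_unit_weights(self, design_one_group):
        rng = np.random.default_rng(5)
        x, blocks = dex.build_design(design_one_group)
        y = pd.DataFrame(
            rng.normal(5, 1, (50, len(design_one_group))),
            columns=design_one_group["sample_id"].to_numpy(),
        )
        fit = dex.fit_gls(y, None, x, blocks=blocks, rho=0.0)
        c = dex.condition_contrast_vector(fit.coef_names, "TNF", "control")
        oracle = ols_t_test(y.to_numpy(), np.asarray(x, float), c)
        est = fit.coefficients.to_numpy() @ c
        assert np.allclose(est, oracle[:, 0], atol=1e-10)
        eb = dex.EBayesState(d0=0.0, s0_sq=1.0, s2_post=fit.sigma2, df_resid=fit.df_resid)
        tab = dex.contrast_test(fit, eb, c)
        assert np.allclose(tab["t"], oracle[:, 1], atol=1e-10)
        assert np.allclose(tab["p"], oracle[:, 2], atol=1e-10)

    def test_blocking_shrinks_within_block_contrast_se(self):
        """Under high intra-donor correlation, paired contrasts gain precision."""
        design = simdata.make_design(2, groups=("NI",), conditions=("control", "TNF"))
        rng = np.random.default_rng(0)
        y = pd.DataFrame(
            rng.normal(0, 1, (30, 4)), columns=design["sample_id"].to_numpy()
        )
        x, blocks = dex.build_design(design)
        c = dex.condition_contrast_vector(list(x.columns), "TNF", "control")
        se = {}
        for rho in (0.0, 0.9):
            fit = dex.fit_gls(y, None, x, blocks=blocks, rho=rho)
            var_u = np.einsum("j,gjk,k->g", c, fit.cov_unscaled, c)
            se[rho] = np.sqrt(var_u).mean()
        assert se[0.9] < se[0.0]

    def test_noiseless_limit_recovers_planted_coefficient(self, design_one_group):
        x, blocks = dex.build_design(design_one_group)
        eff = {"TNF": np.full(30, 1.0), "TNF_sPD1": np.full(30, 1.0)}
        y = simdata.simulate_correlated_expression(
            30, design_one_group, 0.0, seed=3, total_sd=1e-6, condition_effects=eff
        )
        fit = dex.fit_gls(y, None, x, blocks=blocks, rho=0.0)
        c = dex.condition_contrast_vector(fit.coef_names, "TNF", "control")
        assert np.allclose(fit.coefficients.to_numpy() @ c, 1.0, atol=1e-4)

    def test_rank_deficient_design_rejected(self, design_one_group):
        x, blocks = dex.build_design(design_one_group)
        x2 = x.copy()
        x2["dup"] = x2.iloc[:, 1]
        y = pd.DataFrame(np.ones((12, len(x2))), columns=x2.index)
        with pytest.raises(ValueError, match="aliased"):
            dex.fit_gls(y, None, x2, blocks=blocks, rho=0.0)


class TestEbayes:
    def test_identical_variances_fully_shrunk(self):
        s2 = np.full(100, 2.5)
        eb = dex.ebayes_moderate(s2, d_g=4.0)
        assert np.allclose(eb.s2_post, 2.5, rtol=1e-3)

    def test_recovers_planted_prior(self):
        rng = np.random.default_rng(11)
        d0, s0_sq, d_g = 4.0, 2.0, 10.0
        true_var = d0 * s0_sq / stats.chi2.rvs(d0, size=5000, random_state=rng)
        s2 = true_var * stats.chi2.rvs(d_g, size=5000, random_state=rng) / d_g
        eb = dex.ebayes_moderate(s2, d_g=d_g)
        assert eb.d0 == pytest.approx(d0, abs=1.0)
        assert eb.s0_sq == pytest.approx(s0_sq, rel=0.1)

    def test_posterior_between_prior_and_sample(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(5, 500) / 5
        eb = dex.ebayes_moderate(s2, d_g=5.0)
        lo = np.minimum(eb.s0_sq, s2)
        hi = np.maximum(eb.s0_sq, s2)
        assert ((eb.s2_post >= lo - 1e-12) & (eb.s2_post <= hi + 1e-12)).all()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="10 genes"):
            dex.ebayes_moderate(np.ones(5), d_g=3.0)


class TestBhAdjust:
    def test_matches_textbook_stepup(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert np.allclose(dex.bh_adjust(p), bh_stepup(p))
        assert np.allclose(dex.bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_constant_and_singleton(self):
        assert np.allclose(dex.bh_adjust([0.03] * 7), 0.03)
        assert dex.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            p = rng.uniform(size=37)
            assert np.allclose(dex.bh_adjust(p), bh_stepup(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dex.bh_adjust([0.5, 1.5])


class TestContrastTest:
    def test_zero_contrast_rejected(self, design_one_group):
        rng = np.random.default_rng(1)
        x, blocks = dex.build_design(design_one_group)
        y = pd.DataFrame(rng.normal(size=(20, 15)), columns=design_one_group["sample_id"])
        fit = dex.fit_gls(y, None, x, blocks=blocks, rho=0.0)
        eb = dex.ebayes_moderate(fit.sigma2, fit.df_resid)
        with pytest.raises(ValueError, match="nonzero"):
            dex.contrast_test(fit, eb, np.zeros(len(fit.coef_names)))

    def test_pvalues_uniform_under_null(self, design_one_group):
        """KS check of raw p against uniform over pooled null simulations."""
        pooled = []
        for run in range(5):
            truth = simdata.make_truth(
                design_one_group, n_genes=2000, seed=900 + run, frac_tnf_de=0.0,
                n_responsive=0, sigma_donor=0.0, mean_library_size=1e6,
            )
            counts = simdata.simulate_bulk_counts(truth, design_one_group)
            res = dex.run_group_analysis(counts, design_one_group, group="NI")
            pooled.append(res.tables["TNF_vs_control"]["p"].to_numpy())
        pooled = np.concatenate(pooled)
        ks = stats.kstest(pooled, "uniform").statistic
        assert ks < 0.02

    def test_power_at_large_planted_effect(self, design_one_group):
        """A gene with log2FC 2 ranks in the top 1% by p almost always."""
        hits = 0
        n_sims = 40
        for run in range(n_sims):
            truth = simdata.make_truth(
                design_one_group, n_genes=500, seed=700 + run, frac_tnf_de=0.0,
                n_responsive=0, mean_library_size=5e5,
            )
            gi = 0
            truth.tnf_log2fc.iloc[gi, 0] = 2.0
            counts = simdata.simulate_bulk_counts(truth, design_one_group)
            res = dex.run_group_analysis(counts, design_one_group, group="NI")
            tab = res.tables["TNF_vs_control"]
            gene = truth.gene_ids[gi]
            if gene in tab.index:
                rank = (tab["p"] < tab.loc[gene, "p"]).sum()
                if rank < 0.01 * len(tab):
                    hits += 1
        assert hits >= int(0.95 * n_sims)

    def test_deg_count_monotone_in_effect_size(self, design_one_group):
        degs = []
        for scale in (0.5, 1.0, 2.0):
            truth = simdata.make_truth(
                design_one_group, n_genes=1000, seed=77, frac_tnf_de=0.2,
                tnf_lfc_scale=scale, n_responsive=0, mean_library_size=5e5,
            )
            counts = simdata.simulate_bulk_counts(truth, design_one_group)
            res = dex.run_group_analysis(counts, design_one_group, group="NI")
            degs.append(int((res.tables["TNF_vs_control"]["p_adj"] <= 0.05).sum()))
        assert degs[0] < degs[1] < degs[2]

    def test_log2fc_unbiased_at_planted_effect(self, design_one_group):
        biases = []
        for run in range(3):
            truth = simdata.make_truth(
                design_one_group, n_genes=2000, seed=870 + run, frac_tnf_de=0.1,
                tnf_lfc_scale=1.0, n_responsive=0, mean_library_size=1e6,
            )
            counts = simdata.simulate_bulk_counts(truth, design_one_group)
            res = dex.run_group_analysis(counts, design_one_group, group="NI")
            tab = res.tables["TNF_vs_control"]
            planted = truth.tnf_log2fc["NI"].reindex(tab.index)
            up = (planted == 1.0).to_numpy()
            biases.append(float((tab["log2fc"].to_numpy()[up] - 1.0).mean()))
        assert abs(np.mean(biases)) < 0.05


def test_donor_blocked_lm_estimator(signal_counts, design_two_groups):
    ni = design_two_groups[design_two_groups["disease_group"] == "NI"].reset_index(drop=True)
    counts = signal_counts[ni["sample_id"]]
    norm = normcore.normalize(counts, design=dex.build_design(ni)[0])
    est = dex.DonorBlockedLM().fit(norm.log2_cpm.T, ni, weights=norm.weights.T)
    assert hasattr(est, "coef_") and -0.99 <= est.consensus_rho_ <= 0.99
    tab = est.contrast(
        dex.condition_contrast_vector(est.fit_.coef_names, "TNF", "control"),
        name="TNF_vs_control",
    )
    assert {"log2fc", "t", "p", "p_adj"} <= set(tab.columns)
    assert ((tab["p_adj"] >= tab["p"] - 1e-12)).all()
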