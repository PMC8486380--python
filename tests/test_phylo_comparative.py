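"""Covariance construction, contrasts, ancestral states, and model fits."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_mixed_model_data
from lewontin import phylo_comparative as pc
from lewontin import synthetic_data as sd
from lewontin.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidTreeError,
)

FAST = pc.SamplerConfig(n_walkers=16, n_burn=400, n_steps=600, ess_min=200.0,
                        rhat_max=1.05)


class TestPhyloCovariance:
    def test_star_tree_is_identity(self):
        star = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
        cov = pc.phylo_covariance(star)
        assert np.allclose(cov.matrix, np.eye(4))

    def test_three_tip_by_hand(self, three_tip_tree):
        cov = pc.phylo_covariance(three_tip_tree)
        assert cov.labels == ["A", "B", "C"]
        expected = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        assert np.allclose(cov.matrix, expected)
        assert cov.height == pytest.approx(2.0)

    def test_simulated_tree_is_psd_and_symmetric(self, medium_tree):
        cov = pc.phylo_covariance(medium_tree)
        assert np.max(np.abs(cov.matrix - cov.matrix.T)) == 0.0
        np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(len(cov.labels)))
        assert np.allclose(np.diag(cov.matrix), 1.0)
        assert cov.matrix.min() >= 0.0

    def test_non_ultrametric_rejected_and_repairable(self):
        tree = dendropy.Tree.get(data="((A:1,B:0.5):1,C:2);", schema="newick")
        with pytest.raises(InvalidTreeError):
            pc.phylo_covariance(tree)
        with pytest.raises(InvalidTreeError):
            pc.repair_ultrametric(tree, tol=1e-3)  # deviation way beyond tolerance
        slightly_off = dendropy.Tree.get(
            data="((A:1.0005,B:1):1,C:2);", schema="newick"
        )
        repaired = pc.repair_ultrametric(slightly_off, tol=1e-3)
        pc.phylo_covariance(repaired)  # no longer raises

    def test_subtree_pruning_preserves_covariance_ratios(self, medium_tree):
        cov = pc.phylo_covariance(medium_tree)
        keep = cov.labels[:20]
        sub = medium_tree.extract_tree_with_taxa_labels(keep)
        sub_cov = pc.phylo_covariance(sub)
        idx = [cov.labels.index(s) for s in sub_cov.labels]
        big = cov.matrix[np.ix_(idx, idx)]
        ratio = sub_cov.matrix[big > 0] / big[big > 0]
        assert np.allclose(ratio, ratio[0])


class TestPic:
    def test_equal_branch_cherry(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        out = pc.pic(tree, {"A": 3.0, "B": 1.0}).table
        assert out["contrast"].iloc[0] == pytest.approx(2.0 / np.sqrt(2.0))

    def test_unequal_branch_cherry(self):
        tree = dendropy.Tree.get(data="(A:1,B:3);", schema="newick")
        out = pc.pic(tree, {"A": 5.0, "B": 1.0}).table
        assert out["contrast"].iloc[0] == pytest.approx(2.0)

    def test_contrast_count_and_ages(self, medium_tree):
        trait, _ = sd.simulate_bm(medium_tree, 1.0, seed=1)
        out = pc.pic(medium_tree, trait).table
        assert len(out) == 49  # n - 1
        assert (out["age"] >= 0).all()

    def test_contrast_variance_estimates_bm_rate(self):
        msq = []
        for rep in range(20):
            tree = sd.simulate_tree(100, 0.1, seed=rep)
            trait, _ = sd.simulate_bm(tree, 2.0, seed=1000 + rep)
            msq.append(np.mean(pc.pic(tree, trait).table["contrast"] ** 2))
        assert np.mean(msq) == pytest.approx(2.0, rel=0.15)

    def test_missing_tip_value_rejected(self, medium_tree):
        with pytest.raises(InvalidArgumentError):
            pc.pic(medium_tree, {"s0001": 1.0})


class TestBmLikelihoodOracle:
    def test_pruning_equals_dense_mvn_on_small_trees(self):
        """Contrast-recursion likelihood == dense MVN likelihood, <=6 tips."""
        for n in (2, 3, 4, 5, 6):
            for rep in range(4):
                tree = sd.simulate_tree(n, 0.4, seed=37 * n + rep)
                trait, _ = sd.simulate_bm(tree, 1.7, root_value=0.3, seed=rep)
                for sigma2, root in ((1.7, 0.3), (0.5, -1.0)):
                    a = pc.bm_loglik_pruning(tree, trait, sigma2, root)
                    b = pc.bm_loglik_dense(tree, trait, sigma2, root)
                    assert a == pytest.approx(b, abs=1e-8)


class TestAncestralStates:
    def test_cherry_symmetry(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        out = pc.ancestral_states(tree, {"A": 3.0, "B": 1.0})
        assert list(out.values())[0] == pytest.approx(2.0)

    def test_three_tip_against_dense_gls_oracle(self, three_tip_tree):
        trait = {"A": 2.0, "B": 4.0, "C": 9.0}
        out = pc.ancestral_states(three_tip_tree, trait)
        # oracle: explicit GLS solve on the time-scaled covariance
        C = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        y = np.array([2.0, 4.0, 9.0])
        Cinv = np.linalg.inv(C)
        ones = np.ones(3)
        mu = ones @ Cinv @ y / (ones @ Cinv @ ones)
        c_ab = np.array([1.0, 1.0, 0.0])  # shared path of the AB node with tips
        expected_ab = mu + c_ab @ Cinv @ (y - mu)
        values = sorted(out.values())
        assert values == pytest.approx(sorted([mu, expected_ab]), abs=1e-8)

    def test_constant_trait_constant_states(self, medium_tree):
        trait = {lab: 5.5 for lab in (lf.taxon.label for lf in medium_tree.leaf_node_iter())}
        out = pc.ancestral_states(medium_tree, trait)
        assert np.allclose(list(out.values()), 5.5)


class TestNodeHeightTest:
    def test_constant_contrasts_give_flat_slope(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        res = pc.node_height_test(tree, {"A": 0.0, "B": 0.0, "C": 0.0, "D": 0.0})
        assert res.slope == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_too_few_tips_rejected(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        with pytest.raises(InsufficientDataError):
            pc.node_height_test(tree, {"A": 1.0, "B": 2.0})

    def test_recent_rate_shift_detected(self):
        tree = sd.simulate_tree(100, 0.1, seed=301)
        h = pc.tree_height(tree)
        trait = sd.simulate_bm_epoch(tree, 1.0, h / 3, 10.0, seed=401)
        res = pc.node_height_test(tree, trait)
        assert res.slope < 0
        assert res.p_value < 0.05

    def test_permutation_mode_agrees_on_signal(self):
        tree = sd.simulate_tree(80, 0.1, seed=305)
        h = pc.tree_height(tree)
        trait = sd.simulate_bm_epoch(tree, 1.0, h / 3, 10.0, seed=405)
        wald = pc.node_height_test(tree, trait, method="huber")
        perm = pc.node_height_test(tree, trait, method="permutation", n_perm=199, seed=1)
        assert perm.slope == wald.slope
        assert (perm.p_value < 0.05) == (wald.p_value < 0.05)


class TestOlsDiversityNc:
    def test_exact_line(self):
        nc = np.logspace(4, 14, 30)
        pi = 10 ** (-3 + 0.0531 * np.log10(nc))
        fit = pc.ols_diversity_nc(pi, nc, n_boot=100, seed=0)
        assert fit.slope == pytest.approx(0.0531, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.percent_per_decade == pytest.approx(13.0, abs=0.05)

    def test_zero_slope(self):
        nc = np.logspace(4, 14, 30)
        pi = np.full(30, 0.01)
        fit = pc.ols_diversity_nc(pi, nc, n_boot=100, seed=0)
        assert fit.percent_per_decade == pytest.approx(0.0, abs=1e-9)

    def test_bootstrap_ci_covers_generating_slope(self):
        rng = np.random.default_rng(11)
        log_nc = rng.uniform(4, 14, 172)
        log_pi = -3 + 0.0531 * log_nc + rng.normal(0, 0.4, 172)
        fit = pc.ols_diversity_nc(10.0**log_pi, 10.0**log_nc, n_boot=500, seed=11)
        assert fit.slope_ci[0] <= 0.0531 <= fit.slope_ci[1]


class TestFitPhyloMM:
    def test_recovers_slope_and_lambda(self, medium_tree):
        y, x, cov = make_mixed_model_data(medium_tree, 0.053, 0.67, 0.31, seed=5)
        fit = pc.fit_phylo_mm(y, x, cov, config=FAST, seed=5)
        lo, hi = fit.credible_interval("beta", 0.95)
        assert lo <= 0.053 <= hi
        assert 0 <= fit.summary.loc["lambda", "mean"] <= 1

    def test_lambda_identity_drawwise(self, medium_tree):
        y, x, cov = make_mixed_model_data(medium_tree, 0.053, 0.5, 0.31, seed=6)
        fit = pc.fit_phylo_mm(y, x, cov, config=FAST, seed=6)
        lam = fit.draws["sigma_p2"] / (fit.draws["sigma_p2"] + fit.draws["sigma_r2"])
        assert np.allclose(lam, fit.draws["lambda"])
        assert ((fit.draws["lambda"] >= 0) & (fit.draws["lambda"] <= 1)).all()

    def test_deterministic_given_seed(self, medium_tree):
        y, x, cov = make_mixed_model_data(medium_tree, 0.053, 0.5, 0.31, seed=7)
        a = pc.fit_phylo_mm(y, x, cov, config=FAST, seed=3)
        b = pc.fit_phylo_mm(y, x, cov, config=FAST, seed=3)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_identity_covariance_flagged(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        x = rng.normal(size=20)
        fit = pc.fit_phylo_mm(y, x, np.eye(20), config=FAST, seed=0)
        assert "unidentifiable-lambda" in fit.flags

    def test_collinear_regression_degenerate(self, medium_tree):
        y, _, cov = make_mixed_model_data(medium_tree, 0.0, 0.3, 0.31, seed=8)
        fit = pc.fit_phylo_mm(y, y, cov, config=FAST, seed=8)
        assert fit.summary.loc["beta", "mean"] == pytest.approx(1.0, abs=0.01)
        assert fit.summary.loc["sigma_r2", "mean"] < 0.01
        assert "degenerate-residual" in fit.flags

    def test_missing_values_rejected(self, medium_tree):
        y, x, cov = make_mixed_model_data(medium_tree, 0.0, 0.3, 0.31, seed=9)
        y[0] = np.nan
        with pytest.raises(InvalidArgumentError):
            pc.fit_phylo_mm(y, x, cov, config=FAST)


class TestFitPhyloMMSubset:
    def test_subset_too_small_rejected(self, small_dataset):
        tiny = small_dataset.taxa.copy()
        tiny.loc[:, "phylum"] = "other"
        tiny.loc[tiny.index[:5], "phylum"] = "rare"
        with pytest.raises(InsufficientDataError):
            pc.fit_phylo_mm_subset(tiny, small_dataset.tree, "rare", config=FAST)

    def test_full_subset_matches_direct_fit(self, small_dataset):
        fit = pc.fit_phylo_mm_subset(
            small_dataset.taxa, small_dataset.tree, phylum=None, config=FAST, seed=2
        )
        assert fit.n_obs == len(small_dataset.taxa)
        assert "beta" in fit.summary.index

    def test_constant_predictor_falls_back_to_reduced(self, small_dataset):
        taxa = small_dataset.taxa.copy()
        taxa["N_c"] = 1e6  # degenerate design
        fit = pc.fit_phylo_mm_subset(taxa, small_dataset.tree, None, config=FAST, seed=2)
        assert "reduced" in fit.flags or "degenerate-design" in fit.flags


class TestFitMapLength:
    def test_social_taxa_excluded(self, medium_tree):
        ds = sd.simulate_dataset(sd.SimConfig(n_taxa=50, seed=31, n_social=6))
        fit, meta = pc.fit_map_length_model(ds.taxa, ds.tree, config=FAST, seed=4)
        assert meta["n_social_excluded"] == 6
        assert set(meta["social_excluded"]) == set(
            ds.taxa.loc[ds.taxa["social"], "species"]
        )
        assert meta["n_fit"] == 44

    def test_slope_recovered(self):
        cfg = sd.SimConfig(n_taxa=130, seed=33, map_slope=-0.12)
        ds = sd.simulate_dataset(cfg)
        fit, _ = pc.fit_map_length_model(ds.taxa, ds.tree, config=FAST, seed=5)
        lo, hi = fit.credible_interval("beta", 0.90)
        assert lo <= -0.12 <= hi

    def test_constant_map_length_zero_slope(self, small_dataset):
        taxa = small_dataset.taxa.copy()
        rng = np.random.default_rng(0)
        taxa["map_length_M"] = 2.0 * (1 + 1e-9 * rng.random(len(taxa)))
        fit, _ = pc.fit_map_length_model(taxa, small_dataset.tree, config=FAST, seed=6)
        assert abs(fit.summary.loc["beta", "mean"]) < 1e-6

    def test_lognormal_prediction_correction(self, small_dataset):
        fit, meta = pc.fit_map_length_model(
            small_dataset.taxa, small_dataset.tree, config=FAST, seed=7
        )
        # half-variance correction makes E[L] exceed the median prediction
        a = fit.summary.loc["alpha", "mean"]
        b = fit.summary.loc["beta", "mean"]
        assert meta["predict"](8.0) > 10 ** (a + b * 8.0)
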