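"""Kmult calibration and sentinels; PGLS sequential ANOVA with RRPP."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phylomorph as pm
from phylomorph.signal import _k_statistic, compare_hypotheses_pgls, kmult, pgls_anova
from phylomorph.synthetic import fixture_strategy_posterior


def star_tree(n, length=1.0):
    tips = ",".join(f"t{i}:{length}" for i in range(1, n + 1))
    return pm.PhyloTree.from_newick(f"({tips});")


def _bm_draw(tree, m, seed, rate=1.0):
    return pm.simulate_from_model(
        {"model": "BM", "rates": {"all": rate * np.eye(m)},
         "root_state": np.zeros(m)},
        tree, seed=seed,
    )[0]


class TestKmult:
    def test_calibrated_to_one_under_brownian_motion(self, fixture_data):
        _, tree, _ = fixture_data
        ks = [
            _k_statistic(_bm_draw(tree, 3, 1000 + s), tree.vcv().matrix)
            for s in range(80)
        ]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_star_tree_formula_reduces_to_identity_covariance(self, rng):
        tree = star_tree(10)
        Y = rng.normal(size=(10, 4))
        assert _k_statistic(Y, tree.vcv().matrix) == pytest.approx(
            _k_statistic(Y, np.eye(10))
        )

    def test_permutation_p_uniform_under_null(self, fixture_data):
        # iid data carry no signal: permutation p-values should be uniform
        _, tree, _ = fixture_data
        rng = np.random.default_rng(7)
        pvals = []
        for s in range(300):
            Y = rng.normal(size=(tree.n_tips, 2))
            pvals.append(kmult(Y, tree, n_perm=60, seed=s).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_lambda_zero_sentinel_on_signal_free_data(self, fixture_data):
        _, tree, _ = fixture_data
        rng = np.random.default_rng(0)  # frozen instance with ML λ̂ at the 0 boundary
        res = kmult(rng.normal(size=(tree.n_tips, 4)), tree, n_perm=99,
                    seed=0, optimize_lambda=True)
        assert res.scaling_lambda == 0.0
        assert np.isnan(res.kmult) and np.isnan(res.p_value)
        assert np.isnan(res.z) and np.isnan(res.loglik_lambda)

    def test_lambda_stays_high_under_brownian_motion(self, fixture_data):
        _, tree, _ = fixture_data
        res = kmult(_bm_draw(tree, 3, 5), tree, n_perm=99, seed=0,
                    optimize_lambda=True)
        assert res.scaling_lambda > 0.5
        assert res.kmult > 0

    def test_bit_reproducible_given_seed(self, fixture_data, fixture_scores):
        _, tree, _ = fixture_data
        a = kmult(fixture_scores, tree, n_perm=199, seed=42)
        b = kmult(fixture_scores, tree, n_perm=199, seed=42)
        assert (a.kmult, a.p_value, a.z) == (b.kmult, b.p_value, b.z)


class TestPgls:
    @staticmethod
    def _inputs(tree, rng, effect=0.0):
        n = tree.n_tips
        Y = _bm_draw(tree, 3, int(rng.integers(2**31)))
        groups = {t: ("a" if i < n // 2 else "b") for i, t in enumerate(tree.tip_labels)}
        if effect:
            Y[[i for i, t in enumerate(tree.tip_labels) if groups[t] == "b"]] += effect
        sizes = pd.Series(
            np.exp(rng.normal(size=n)), index=tree.tip_labels
        )
        return pd.DataFrame(Y, index=tree.tip_labels), groups, sizes

    def test_r2_partition_sums_to_one(self, fixture_data, fixture_scores, fixture_shapes):
        _, tree, prior = fixture_data
        sizes = pd.Series(fixture_shapes.centroid_sizes, index=fixture_shapes.specimen_ids)
        tab = pgls_anova(fixture_scores, tree, prior, sizes, n_perm=99, seed=0)
        r2 = tab.table.set_index("term")["R2"]
        terms_plus_resid = r2.drop("Total").sum()
        assert terms_plus_resid == pytest.approx(1.0, abs=1e-10)

    def test_type_one_error_calibrated(self, fixture_data):
        # no group effect in the generating model: the strategy term should
        # reject at roughly the nominal 5% rate
        _, tree, _ = fixture_data
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 250
        for _ in range(n_sim):
            Y, groups, sizes = self._inputs(tree, rng)
            tab = pgls_anova(Y, tree, groups, sizes, n_perm=79,
                            seed=int(rng.integers(2**31)))
            rejections += tab.term("TPS")["p"] <= 0.05
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert 0.05 - 2.6 * se <= rate <= 0.05 + 2.6 * se

    def test_reduces_to_ordinary_anova_on_star_tree(self, rng):
        tree = star_tree(16)
        Y, groups, sizes = self._inputs(tree, rng, effect=0.5)
        tab = pgls_anova(Y, tree, groups, sizes, n_perm=9, seed=0)
        # oracle: direct OLS sequential sums of squares
        g = np.array([0.0 if groups[t] == "a" else 1.0 for t in tree.tip_labels])
        x = np.log(sizes.loc[tree.tip_labels].to_numpy())
        x = x - x.mean()
        Ym = Y.loc[tree.tip_labels].to_numpy()
        def rss(cols):
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, Ym, rcond=None)
            return float(((Ym - X @ beta) ** 2).sum())
        ones = np.ones(16)
        seq = [rss([ones]), rss([ones, g]), rss([ones, g, x]), rss([ones, g, x, g * x])]
        ss_terms = np.diff(seq) * -1
        df_res = 16 - 4
        f_expected = ss_terms / (seq[-1] / df_res)
        for k, term in enumerate(["TPS", "log(Csize)", "TPS:size"]):
            assert tab.term(term)["F"] == pytest.approx(f_expected[k], rel=1e-8)

    def test_rank_deficient_design_rejected(self, fixture_data):
        _, tree, prior = fixture_data
        sizes = pd.Series(1.0, index=tree.tip_labels)  # log → constant 0 column
        Y = pd.DataFrame(np.random.default_rng(0).normal(size=(17, 2)),
                         index=tree.tip_labels)
        with pytest.raises(ValueError, match="rank-deficient"):
            pgls_anova(Y, tree, prior, sizes, n_perm=9, seed=0)

    def test_permutations_bit_reproducible(self, fixture_data, fixture_scores, fixture_shapes):
        _, tree, prior = fixture_data
        sizes = pd.Series(fixture_shapes.centroid_sizes, index=fixture_shapes.specimen_ids)
        a = pgls_anova(fixture_scores, tree, prior, sizes, n_perm=199, seed=5)
        b = pgls_anova(fixture_scores, tree, prior, sizes, n_perm=199, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestCompareHypotheses:
    def test_identical_tables_give_zero_deltas(self, fixture_data, fixture_scores, fixture_shapes):
        _, tree, prior = fixture_data
        sizes = pd.Series(fixture_shapes.centroid_sizes, index=fixture_shapes.specimen_ids)
        cmp = compare_hypotheses_pgls(
            fixture_scores, tree, prior, prior, sizes, n_perm=99, seed=1
        )
        assert cmp["delta_z"] == 0.0
        assert cmp["delta_r2"] == 0.0

    def test_generating_hypothesis_wins_on_fixture(self, fixture_data, fixture_scores, fixture_shapes):
        # the fixture was generated with the posterior regime structure, so
        # the posterior labelling should explain more shape variance
        _, tree, prior = fixture_data
        sizes = pd.Series(fixture_shapes.centroid_sizes, index=fixture_shapes.specimen_ids)
        cmp = compare_hypotheses_pgls(
            fixture_scores, tree, prior, fixture_strategy_posterior(), sizes,
            n_perm=199, seed=2,
        )
        assert cmp["delta_r2"] > 0
        assert cmp["delta_z"] > 0
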