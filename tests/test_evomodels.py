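"""Evolutionary-model likelihood engine against independent dense-Gaussian
oracles, model nesting, AIC weights, simulation, SURFACE and adequacy."""
import numpy as np
import pytest
from scipy import integrate, stats

import phylomorph as pm
from phylomorph.evomodels import (
    ModelError,
    adequacy_bootstrap,
    aic_weights,
    fit_evo_model,
    loglik_evo_model,
    model_mean_cov,
    simulate_from_model,
    surface_forward,
)
from phylomorph.markov import paint_from_hypothesis
from phylomorph.tree import RegimePainting


# --------------------------------------------------------------- the oracle

def _root_path(tree, tip_label):
    """Independent path walk: ordered (t0, t1, regime?) pieces for one tip."""
    node = next(t for t in tree.tips if t.label == tip_label)
    chain = []
    while node.parent is not None:
        chain.append(node)
        node = node.parent
    chain.reverse()
    heights = tree.node_heights()
    return chain, heights


def _oracle_mean_cov(model, tree, params, painting=None):
    """Dense mean/covariance built by numeric quadrature along explicit
    root-to-tip paths — no shared code with the closed-form engine."""
    labels = tree.tip_labels
    n = len(labels)
    R = {k: np.atleast_2d(v) for k, v in params["rates"].items()}
    m = next(iter(R.values())).shape[0]
    heights = tree.node_heights()
    T = {lab: tree.tip_depths()[i] for i, lab in enumerate(labels)}

    def regime_at(tip_label, u):
        chain, _ = _root_path(tree, tip_label)
        for node in chain:
            h0 = heights[node.parent.index]
            t0 = h0
            for dur, reg in painting.segments[node.index]:
                if t0 <= u < t0 + dur:
                    return reg
                t0 += dur
        return painting.segments[chain[-1].index][-1][1]

    def shared_depth(a, b):
        if a == b:
            return T[a]
        ca, _ = _root_path(tree, a)
        cb, _ = _root_path(tree, b)
        shared = {n.index for n in ca} & {n.index for n in cb}
        if not shared:
            return 0.0
        # deepest shared edge's child node height bounds the common path
        h = 0.0
        for node in ca:
            if node.index in shared:
                h = max(h, heights[node.index])
        return h

    model = model.upper()
    V = np.zeros((n * m, n * m))
    mean = np.zeros(n * m)
    alpha = None
    if model in {"OU1", "OUM"}:
        alpha = np.asarray(params["alpha"], float) * np.ones(m)
    for i, a_lab in enumerate(labels):
        for j, b_lab in enumerate(labels):
            s = shared_depth(a_lab, b_lab)
            for a in range(m):
                for b in range(m):
                    if model == "BM":
                        V[i * m + a, j * m + b] = list(R.values())[0][a, b] * s
                    elif model == "EB":
                        rate = params["eb_rate"]
                        val, _ = integrate.quad(lambda u: np.exp(rate * u), 0, s)
                        V[i * m + a, j * m + b] = list(R.values())[0][a, b] * val
                    elif model == "BMM":
                        val = 0.0
                        for reg, Rk in R.items():
                            t_reg, _ = integrate.quad(
                                lambda u: 1.0 if regime_at(a_lab, u) == reg else 0.0,
                                0, s, limit=200,
                            )
                            val += Rk[a, b] * t_reg
                        V[i * m + a, j * m + b] = val
                    else:  # OU
                        Rm = list(R.values())[0]
                        val, _ = integrate.quad(
                            lambda u: np.exp(-alpha[a] * (T[a_lab] - u))
                            * np.exp(-alpha[b] * (T[b_lab] - u)),
                            0, s,
                        )
                        V[i * m + a, j * m + b] = Rm[a, b] * val
    for i, lab in enumerate(labels):
        if model in {"BM", "BMM", "EB"}:
            mean[i * m:(i + 1) * m] = np.asarray(params["root_state"], float)
        else:
            theta = params["theta"]
            root_theta = np.asarray(theta[painting.root_regime], float)
            for a in range(m):
                drift, _ = integrate.quad(
                    lambda u: alpha[a]
                    * np.exp(-alpha[a] * (T[lab] - u))
                    * np.asarray(theta[regime_at(lab, u)], float)[a],
                    0, T[lab], limit=200,
                )
                mean[i * m + a] = root_theta[a] * np.exp(-alpha[a] * T[lab]) + drift
    return mean, V


@pytest.fixture(scope="module")
def oracle_tree():
    # non-ultrametric 4-tip tree
    return pm.PhyloTree.from_newick("((A:1.2,B:0.7):0.8,(C:1.5,D:0.9):0.4);")


@pytest.fixture(scope="module")
def oracle_painting(oracle_tree):
    labels = {t: ("x" if t in {"C", "D"} else "y") for t in oracle_tree.tip_labels}
    return paint_from_hypothesis(oracle_tree, labels, derived_level="x")


@pytest.fixture(scope="module")
def oracle_params():
    R = np.array([[0.8, 0.3], [0.3, 1.4]])
    R2 = np.array([[2.0, -0.4], [-0.4, 0.9]])
    return {
        "BM": {"rates": {"all": R}, "root_state": np.array([0.5, -1.0])},
        "EB": {"rates": {"all": R}, "root_state": np.array([0.5, -1.0]), "eb_rate": -0.7},
        "BMM": {"rates": {"y": R, "x": R2}, "root_state": np.array([0.5, -1.0])},
        "OU1": {"rates": {"all": R}, "alpha": np.array([0.6, 1.1]),
                "theta": {"all": np.array([1.0, -0.5])}},
        "OUM": {"rates": {"all": R}, "alpha": np.array([0.6, 1.1]),
                "theta": {"y": np.array([1.0, -0.5]), "x": np.array([-2.0, 3.0])}},
    }


class TestLikelihoodEngine:
    @pytest.mark.parametrize("model", ["BM", "EB", "BMM", "OU1", "OUM"])
    def test_agrees_with_quadrature_oracle(self, model, oracle_tree, oracle_painting,
                                           oracle_params, rng):
        painting = oracle_painting if model in {"BMM", "OUM"} else (
            RegimePainting.uniform(oracle_tree, "all") if model == "OU1" else None
        )
        params = oracle_params[model]
        mean, V = model_mean_cov(model, oracle_tree, params, painting)
        mean_o, V_o = _oracle_mean_cov(model, oracle_tree, params, painting)
        np.testing.assert_allclose(mean, mean_o, atol=1e-8)
        np.testing.assert_allclose(V, V_o, atol=1e-8)
        Y = rng.normal(size=(4, 2))
        ll = loglik_evo_model(model, oracle_tree, Y, params, painting)
        ll_o = stats.multivariate_normal(mean_o, V_o, allow_singular=True).logpdf(
            Y.reshape(-1)
        )
        assert ll == pytest.approx(ll_o, abs=1e-6)

    def test_bm_two_tip_closed_form_mle(self):
        # two tips joined only at the root: C = diag(t1, t2); the GLS mean and
        # profiled rate have elementary closed forms
        tree = pm.PhyloTree.from_newick("(A:2.0,B:0.5);")
        y = np.array([[1.3], [-0.4]])
        t1, t2 = 2.0, 0.5
        w = np.array([1 / t1, 1 / t2])
        mu = (w @ y[:, 0]) / w.sum()
        s2 = ((y[:, 0] - mu) ** 2 @ w) / 2
        ll = -0.5 * (2 * np.log(2 * np.pi) + np.log(t1 * t2) + 2 * np.log(s2) + 2)
        fit = fit_evo_model("BM", tree, y)
        assert fit.root_state[0] == pytest.approx(mu, abs=1e-8)
        assert fit.rates["all"][0, 0] == pytest.approx(s2, abs=1e-8)
        assert fit.loglik == pytest.approx(ll, abs=1e-8)


class TestNesting:
    def test_bmm_with_equal_rates_equals_bm(self, oracle_tree, oracle_painting, rng):
        R = np.array([[1.1, 0.2], [0.2, 0.7]])
        Y = rng.normal(size=(4, 2))
        ll_bmm = loglik_evo_model(
            "BMM", oracle_tree, Y,
            {"rates": {"x": R, "y": R}, "root_state": np.zeros(2)}, oracle_painting,
        )
        ll_bm = loglik_evo_model(
            "BM", oracle_tree, Y, {"rates": {"all": R}, "root_state": np.zeros(2)}
        )
        assert ll_bmm == pytest.approx(ll_bm, abs=1e-6)

    def test_eb_zero_and_ou_small_alpha_reduce_to_bm(self, oracle_tree, rng):
        R = np.array([[1.1, 0.2], [0.2, 0.7]])
        Y = rng.normal(size=(4, 2))
        mu = np.array([0.3, -0.2])
        ll_bm = loglik_evo_model("BM", oracle_tree, Y,
                                 {"rates": {"all": R}, "root_state": mu})
        ll_eb = loglik_evo_model("EB", oracle_tree, Y,
                                 {"rates": {"all": R}, "root_state": mu, "eb_rate": 0.0})
        assert ll_eb == pytest.approx(ll_bm, abs=1e-10)
        ll_ou = loglik_evo_model(
            "OU1", oracle_tree, Y,
            {"rates": {"all": R}, "alpha": np.full(2, 1e-8), "theta": {"all": mu}},
            RegimePainting.uniform(oracle_tree, "all"),
        )
        assert ll_ou == pytest.approx(ll_bm, abs=1e-4)

    def test_fitted_nesting_inequalities(self, fixture_data, fixture_scores):
        _, tree, prior = fixture_data
        Y = fixture_scores.iloc[:, :2]
        paint = paint_from_hypothesis(tree, prior, derived_level="specialist")
        bm = fit_evo_model("BM", tree, Y)
        bmm = fit_evo_model("BMM", tree, Y, paint, seed=0)
        ou1 = fit_evo_model("OU1", tree, Y, alpha_structure="scalar")
        oum = fit_evo_model("OUM", tree, Y, paint, alpha_structure="scalar", seed=0)
        assert bmm.loglik >= bm.loglik - 1e-6
        assert oum.loglik >= ou1.loglik - 1e-6
        # BM is the α→0 boundary of OU; the α lower bound leaves a tiny gap
        assert ou1.loglik >= bm.loglik - 1e-3


class TestAicWeights:
    def _fits(self, fixture_data, fixture_scores, models=("BM", "EB")):
        _, tree, _ = fixture_data
        return [fit_evo_model(m, tree, fixture_scores.iloc[:, :2]) for m in models]

    def test_direct_formula_values(self, fixture_data, fixture_scores):
        fits = self._fits(fixture_data, fixture_scores)
        # force the printed-delta example: ΔAIC = (0, 2)
        fits[0].n_params = fits[0].n_params  # keep
        fits[1].loglik = fits[0].loglik + fits[1].n_params - fits[0].n_params - 1.0
        aic_weights(fits)
        w = np.exp(0) / (np.exp(0) + np.exp(-1))
        assert fits[0].aicw == pytest.approx(w, abs=1e-3)
        assert fits[1].aicw == pytest.approx(1 - w, abs=1e-3)
        assert fits[0].aicw + fits[1].aicw == pytest.approx(1.0)

    def test_equal_aic_gives_half_half(self, fixture_data, fixture_scores):
        fits = self._fits(fixture_data, fixture_scores)
        fits[1].loglik = fits[0].loglik + (fits[1].n_params - fits[0].n_params)
        aic_weights(fits)
        assert fits[0].aicw == pytest.approx(0.5, abs=1e-6)

    def test_mismatched_data_rejected(self, fixture_data, fixture_scores):
        _, tree, _ = fixture_data
        f1 = fit_evo_model("BM", tree, fixture_scores.iloc[:, :2])
        f2 = fit_evo_model("BM", tree, fixture_scores.iloc[:, :3])
        with pytest.raises(ModelError, match="identical data"):
            aic_weights([f1, f2])


class TestSimulation:
    def test_bm_star_tip_difference_variance(self):
        tree = pm.PhyloTree.from_newick("(A:1,B:1,C:1);")
        draws = simulate_from_model(
            {"model": "BM", "rates": {"all": np.eye(1)}, "root_state": np.zeros(1)},
            tree, n_datasets=100_000, seed=0,
        )
        diff = draws[:, 0, 0] - draws[:, 1, 0]
        se = np.sqrt(2) * 2 / np.sqrt(100_000)  # SE of a variance estimate, var≈2
        assert abs(diff.var() - 2.0) < 3 * se

    def test_zero_rate_pins_tips_to_root_state(self, oracle_tree):
        draws = simulate_from_model(
            {"model": "BM", "rates": {"all": np.zeros((2, 2))},
             "root_state": np.array([3.0, -1.0])},
            oracle_tree, n_datasets=5, seed=1,
        )
        np.testing.assert_allclose(draws, np.broadcast_to([3.0, -1.0], draws.shape),
                                   atol=1e-6)

    def test_strong_pull_concentrates_tips_at_optimum(self, oracle_tree):
        theta = np.array([4.0, -2.0])
        draws = simulate_from_model(
            {"model": "OU1", "rates": {"all": 0.1 * np.eye(2)},
             "alpha": np.array([30.0, 30.0]), "theta": {"all": theta}},
            oracle_tree, RegimePainting.uniform(oracle_tree, "all"),
            n_datasets=2000, seed=2,
        )
        sd = np.sqrt(0.1 / (2 * 30.0))
        means = draws.mean(axis=(0, 1))
        assert np.abs(means - theta).max() < 3 * sd / np.sqrt(2000 * 4) + 1e-2

    def test_seeded_draws_reproducible(self, oracle_tree):
        kw = dict(n_datasets=3, seed=9)
        a = simulate_from_model(
            {"model": "BM", "rates": {"all": np.eye(2)}, "root_state": np.zeros(2)},
            oracle_tree, **kw)
        b = simulate_from_model(
            {"model": "BM", "rates": {"all": np.eye(2)}, "root_state": np.zeros(2)},
            oracle_tree, **kw)
        np.testing.assert_array_equal(a, b)


class TestParameterRecovery:
    def test_rate_diagonals_recovered_within_quarter(self, fixture_data):
        _, tree, prior = fixture_data
        paint = paint_from_hypothesis(tree, prior, derived_level="specialist")
        m = 2
        R_gen = np.array([[4e-4, 1e-4], [1e-4, 2e-4]])
        truth = {
            "BM": {"model": "BM", "rates": {"all": R_gen},
                   "root_state": np.zeros(m)},
            "BMM": {"model": "BMM",
                    "rates": {"generalist": R_gen, "specialist": 4 * R_gen},
                    "root_state": np.zeros(m)},
            # moderate pull (half-life ≈ 0.4 tree height): the diffusion rate
            # stays identifiable; under strong pull only σ²/2α is identified
            "OU1": {"model": "OU1", "rates": {"all": R_gen},
                    "alpha": np.full(m, 0.01),
                    "theta": {"all": np.zeros(m)}},
        }
        n_sim = 25
        for model, params in truth.items():
            paint_used = paint if model == "BMM" else None
            est = []
            true_diag = np.concatenate([
                np.diag(np.atleast_2d(v)) for v in params["rates"].values()
            ])
            for s in range(n_sim):
                Y = simulate_from_model(params, tree, paint_used, seed=1000 + s)[0]
                fit = fit_evo_model(
                    model, tree, Y, paint_used, n_starts=1, seed=s,
                    alpha_structure="scalar",
                )
                est.append(np.concatenate([
                    np.diag(fit.rates[k]) for k in params["rates"]
                ]) if model == "BMM" else np.diag(fit.rates["all"]))
            rel_bias = np.abs(np.mean(est, axis=0) - true_diag) / true_diag
            assert rel_bias.max() < 0.25, f"{model}: {rel_bias}"


class TestSurface:
    @staticmethod
    def _ou1_data(tree, s, m=2):
        return simulate_from_model(
            {"model": "OU1", "rates": {"all": 0.01 * np.eye(m)},
             "alpha": np.full(m, 0.02), "theta": {"all": np.zeros(m)}},
            tree, RegimePainting.uniform(tree, "all"), seed=s,
        )[0]

    def test_false_positive_rate_under_single_regime(self, fixture_data):
        _, tree, _ = fixture_data
        n_sim = 20
        hits = 0
        for s in range(n_sim):
            res = surface_forward(tree, self._ou1_data(tree, s))
            hits += len(res.shift_nodes) > 0
        rate = hits / n_sim
        # nominal bound 10%, Monte-Carlo allowance at this replicate count
        assert rate <= 0.10 + 2 * np.sqrt(0.1 * 0.9 / n_sim)

    def test_strong_shift_recovered_on_known_branch(self, fixture_data):
        _, tree, prior = fixture_data
        post = paint_from_hypothesis(
            tree, pm.synthetic.fixture_strategy_posterior(), derived_level="specialist"
        )
        shift_node = tree.mrca(pm.synthetic.FIXTURE_SPECIALISTS_POSTERIOR)
        target = set(tree.clade_tips(shift_node))
        n_sim = 15
        hits = 0
        for s in range(n_sim):
            Y = simulate_from_model(
                {"model": "OUM", "rates": {"all": 0.01 * np.eye(2)},
                 "alpha": np.full(2, 0.05),
                 "theta": {"generalist": np.zeros(2),
                           "specialist": np.array([3.0, -3.0])}},
                tree, post, seed=200 + s,
            )[0]
            res = surface_forward(tree, Y)
            for step in res.steps:
                if step["shift_node"] is None:
                    continue
                clade = set(step["shift_clade"].split(";"))
                node = tree.nodes[step["shift_node"]]
                neighbours = [set(tree.clade_tips(c)) for c in node.children]
                if clade == target or target in neighbours or (
                    node.parent is not None
                    and set(tree.clade_tips(node.parent)) == target
                ):
                    hits += 1
                    break
        assert hits / n_sim >= 0.8

    def test_aicc_non_increasing_over_steps(self, fixture_data, fixture_scores):
        _, tree, _ = fixture_data
        res = surface_forward(tree, fixture_scores)
        aiccs = [s["aicc"] for s in res.steps]
        assert all(b <= a for a, b in zip(aiccs, aiccs[1:]))


class TestAdequacy:
    def test_coverage_of_well_specified_bm(self, fixture_data):
        _, tree, _ = fixture_data
        params = {"model": "BM", "rates": {"all": np.diag([3e-4, 1.5e-4])},
                  "root_state": np.zeros(2)}
        inside = []
        for rep in range(25):
            Y = simulate_from_model(params, tree, seed=rep)[0]
            fit = fit_evo_model("BM", tree, Y)
            adeq = adequacy_bootstrap(fit, tree, n_sim=100, seed=rep)
            inside.extend(adeq.table["inside"].tolist())
        assert np.mean(inside) >= 0.85

    def test_misspecified_rate_falls_outside(self, fixture_data):
        _, tree, _ = fixture_data
        Y = simulate_from_model(
            {"model": "BM", "rates": {"all": np.eye(2)}, "root_state": np.zeros(2)},
            tree, seed=0,
        )[0]
        fit = fit_evo_model("BM", tree, Y)
        # pretend the fitted rate was 10× smaller and bootstrap from that
        wrong = fit
        wrong.rates = {"all": fit.rates["all"] / 10.0}
        adeq = adequacy_bootstrap(wrong, tree, n_sim=60, seed=1)
        obs = adeq.table.set_index("parameter")["observed"]
        hi = adeq.table.set_index("parameter")["ci_hi"]
        # the observed (unshrunk-world) data would sit far outside: check the
        # bootstrap interval itself concentrated near the wrong rate
        assert (hi < 10 * obs).all()

    def test_reported_fraction_and_verdict_consistent(self, fixture_data, fixture_scores):
        _, tree, _ = fixture_data
        fit = fit_evo_model("BM", tree, fixture_scores.iloc[:, :2])
        adeq = adequacy_bootstrap(fit, tree, n_sim=80, seed=5)
        assert adeq.adequate == bool(adeq.table["inside"].all())
        assert adeq.n_sim == 80
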