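import numpy as np
import pytest
import scipy.optimize
import scipy.stats

from flyvis.io_fixtures import SpeciesTraitTable
from flyvis.ou_adaptation import (
    OUFitError,
    OUFitResult,
    OUModelSpec,
    bm_covariance,
    compare_models,
    fit_ou_model,
    gls_fit,
    ou_covariance,
    regime_weights,
    rho,
)
from flyvis.synthetic_data import SimulationConfig, simulate_ou_traits, simulate_regimes, simulate_tree

from .conftest import random_tree


# ------------------------------------------------------- independent oracles
def oracle_shared_times(tree):
    """MRCA times by walking parent chains (independent of shared_times)."""
    tips = list(tree.tip_indices)
    t = tree.times
    S = np.zeros((len(tips), len(tips)))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            anc_a = set()
            n = int(a)
            while n != 0:
                anc_a.add(n)
                n = int(tree.parent[n])
            anc_a.add(0)
            n = int(b) if i != j else int(a)
            if i == j:
                S[i, j] = t[a]
                continue
            while n not in anc_a:
                n = int(tree.parent[n])
            S[i, j] = t[n]
    return S


def oracle_loglik(tree, painting, y, t_half, v_y):
    """Straightforward OU likelihood written from first principles."""
    alpha = np.log(2.0) / t_half
    S = oracle_shared_times(tree)
    ti = np.diag(S)
    D = ti[:, None] + ti[None, :] - 2 * S
    V = v_y * (1 - np.exp(-2 * alpha * S)) * np.exp(-alpha * D)
    regimes = painting.regimes
    t = tree.times
    W = np.zeros((tree.n_tips, len(regimes)))
    for i, tip in enumerate(tree.tip_indices):
        T = t[tip]
        n = int(tip)
        while n != 0:
            k = regimes.index(painting.branch_regime[n])
            t0, t1 = t[int(tree.parent[n])], t[n]
            W[i, k] += np.exp(-alpha * (T - t1)) - np.exp(-alpha * (T - t0))
            n = int(tree.parent[n])
        W[i, regimes.index(painting.root_regime)] += np.exp(-alpha * T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(W.T @ Vi @ W, W.T @ Vi @ y)
    e = y - W @ beta
    _, logdet = np.linalg.slogdet(V)
    return -0.5 * (len(y) * np.log(2 * np.pi) + logdet + e @ Vi @ e)


def make_table(tree, y, name="E_area"):
    import pandas as pd

    df = pd.DataFrame(
        {f"{name}_mean": np.exp(y)}, index=pd.Index(tree.tip_labels, name="species_id")
    )
    return SpeciesTraitTable(df)


# ------------------------------------------------------------------ rho & cov
class TestRho:
    def test_limits_and_monotonicity(self):
        x = np.geomspace(1e-6, 100, 200)
        r = rho(x)
        assert rho(0.0) == 0.0
        assert rho(np.inf) == 1.0
        assert np.all(np.diff(r) > 0)
        assert np.all((r > 0) & (r < 1))


class TestOUCovariance:
    def test_infinite_alpha_gives_iid_stationary_variance(self, tree18):
        V = ou_covariance(tree18, np.inf, 0.25)
        assert np.allclose(V, 0.25 * np.eye(tree18.n_tips))

    def test_small_alpha_matches_brownian_limit(self, tree18):
        alpha, sigma2 = 1e-8, 0.3
        V = ou_covariance(tree18, alpha, sigma2 / (2 * alpha))
        B = bm_covariance(tree18, sigma2)
        assert np.max(np.abs(V - B) / B.max()) < 1e-6

    def test_symmetric_positive_semidefinite(self, tree18):
        V = ou_covariance(tree18, 2.0, 0.1)
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-12
        # adding measurement error keeps it comfortably positive definite
        assert np.linalg.eigvalsh(V + 0.01 * np.eye(len(V))).min() > 0.009

    def test_negative_parameters_rejected(self, tree18):
        with pytest.raises(OUFitError):
            ou_covariance(tree18, -1.0, 0.1)

    def test_matches_monte_carlo_covariance(self):
        """Analytic covariance vs exact-transition simulation on a 5-tip tree."""
        from flyvis.synthetic_data import simulate_tip_values

        tree = simulate_tree(5, seed=3)
        assignment, painting, _ = simulate_regimes(tree, "clade_paint", seed=3)
        single = type(painting)(
            branch_regime={n: "SAT" for n in painting.branch_regime},
            root_regime="SAT",
            n_changes=0,
            node_state={n: "SAT" for n in painting.node_state},
        )
        cfg = SimulationConfig(
            n_tips=5, t_half_true=np.log(2.0), v_y_true=1.0, optima={"SAT": 0.0}
        )
        rng = np.random.default_rng(12345)
        n_rep = 8000
        ys = np.array(
            [simulate_tip_values(tree, single, cfg, seed=rng)[1] for _ in range(n_rep)]
        )
        V_true = ou_covariance(tree, 1.0, 1.0)
        prod = ys[:, :, None] * ys[:, None, :]
        V_mc = prod.mean(axis=0)
        se_mc = prod.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(V_mc - V_true) <= 3 * se_mc + 1e-12)


class TestRegimeWeights:
    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, 12)
        _, painting, _ = simulate_regimes(tree, "markov", seed=seed, rate=3.0)
        W = regime_weights(tree, painting, 2.0)
        assert np.max(np.abs(W.sum(axis=1) - 1.0)) < 1e-12

    def test_zero_alpha_concentrates_on_root_regime(self, painted_tree18):
        tree, _, painting = painted_tree18
        W = regime_weights(tree, painting, 0.0)
        root_col = painting.regimes.index(painting.root_regime)
        assert np.allclose(W[:, root_col], 1.0)
        assert np.allclose(W.sum(axis=1), 1.0)

    def test_infinite_alpha_is_tip_branch_indicator(self, painted_tree18):
        tree, _, painting = painted_tree18
        W = regime_weights(tree, painting, np.inf)
        for i, tip in enumerate(tree.tip_indices):
            expected = painting.regimes.index(painting.branch_regime[int(tip)])
            assert W[i, expected] == 1.0
            assert W[i].sum() == 1.0


class TestGLS:
    def test_identity_covariance_reduces_to_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.1, 6.9])
        X = np.column_stack([np.ones(6), x])
        fit = gls_fit(X, np.eye(6), y)
        ols = scipy.stats.linregress(x, y)
        assert fit.beta[1] == pytest.approx(ols.slope, abs=1e-10)
        assert fit.beta[0] == pytest.approx(ols.intercept, abs=1e-10)
        # GLS treats V as fully specified; rescaling by the residual
        # variance estimate recovers the textbook OLS standard error
        s = np.sqrt((fit.residuals @ fit.residuals) / 4)
        assert fit.se[1] * s == pytest.approx(ols.stderr, rel=1e-10)

    def test_exact_linear_response_gives_r2_one(self):
        x = np.arange(1.0, 7.0)
        X = np.column_stack([np.ones(6), x])
        fit = gls_fit(X, np.eye(6), 2 * x + 1)
        assert fit.R2_phylo == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(fit.residuals)) < 1e-12

    def test_beta_invariant_to_covariance_rescaling(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((8, 8))
        V = A @ A.T + 8 * np.eye(8)
        X = np.column_stack([np.ones(8), rng.standard_normal(8)])
        y = rng.standard_normal(8)
        b1 = gls_fit(X, V, y).beta
        b2 = gls_fit(X, 7.3 * V, y).beta
        assert np.allclose(b1, b2, atol=1e-10)

    def test_singular_design_rejected(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(OUFitError, match="rank deficient"):
            gls_fit(X, np.eye(5), np.arange(5.0))


# --------------------------------------------------------------------- fitting
@pytest.fixture(scope="module")
def ou_dataset():
    tree = simulate_tree(40, seed=5)
    assignment, painting, _ = simulate_regimes(tree, "clade_paint", seed=5)
    cfg = SimulationConfig(
        n_tips=40,
        t_half_true=0.1,
        v_y_true=0.05,
        optima={"SAT": 13.4, "NON_SAT": 12.9},
        specimen_cv=0.0,
        n_specimens=1,
    )
    table, truth = simulate_ou_traits(tree, painting, cfg, seed=5)
    return tree, painting, table, truth


class TestFitOUModel:
    def test_white_noise_grid_point_matches_closed_form(self, ou_dataset):
        tree, painting, table, _ = ou_dataset
        fit = fit_ou_model(
            tree,
            table,
            painting,
            OUModelSpec(response="E_area", predictor="regime"),
            t_half_grid=np.array([0.0]),
        )
        # at t_half = 0 the model is iid Normal around the tip-regime means
        y = np.log(table.mean("E_area").reindex(tree.tip_labels).to_numpy())
        groups = np.array(
            [painting.branch_regime[int(t)] for t in tree.tip_indices]
        )
        resid = y.copy()
        for g in np.unique(groups):
            resid[groups == g] -= y[groups == g].mean()
        n = len(y)
        best_logL = -0.5 * n * (np.log(2 * np.pi * (resid @ resid) / n) + 1)
        assert fit.t_half == 0.0
        assert fit.logL == pytest.approx(best_logL, abs=1e-6)

    def test_matches_independent_optimizer(self, ou_dataset):
        tree, painting, table, _ = ou_dataset
        fit = fit_ou_model(
            tree, table, painting, OUModelSpec(response="E_area", predictor="regime")
        )
        y = np.log(table.mean("E_area").reindex(tree.tip_labels).to_numpy())

        def neg(z):
            return -oracle_loglik(tree, painting, y, np.exp(z[0]), np.exp(z[1]))

        res = scipy.optimize.minimize(
            neg,
            x0=[np.log(0.1), np.log(0.05)],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        assert fit.logL == pytest.approx(-res.fun, abs=1e-4)

    def test_evolutionary_slope_is_attenuated_optimal_slope(self, ou_dataset):
        tree, painting, table, _ = ou_dataset
        fit = fit_ou_model(
            tree,
            table,
            painting,
            OUModelSpec(response="E_area", predictor="bm", predictor_trait="H_width"),
        )
        r = rho(fit.alpha * tree.depth)
        assert abs(fit.evolutionary_slope) <= abs(fit.optimal_slope) + 1e-12
        if np.isfinite(fit.optimal_slope):
            assert fit.evolutionary_slope == pytest.approx(
                fit.optimal_slope * r, rel=1e-10
            )

    def test_half_life_times_alpha_is_ln2(self, ou_dataset):
        tree, painting, table, _ = ou_dataset
        fit = fit_ou_model(
            tree, table, painting, OUModelSpec(response="E_area", predictor="regime")
        )
        if 0 < fit.t_half < np.inf:
            assert fit.alpha * fit.t_half == pytest.approx(np.log(2.0), rel=1e-12)
        assert fit.support_region[0] <= fit.t_half <= fit.support_region[1]

    def test_finer_grid_changes_logL_little(self, ou_dataset):
        tree, painting, table, _ = ou_dataset
        spec = OUModelSpec(response="E_area", predictor="regime")
        coarse = fit_ou_model(tree, table, painting, spec, n_t_half=60, n_v=15)
        fine = fit_ou_model(tree, table, painting, spec, n_t_half=240, n_v=60)
        assert abs(coarse.logL - fine.logL) < 0.01

    def test_aicc_small_sample_guard(self):
        from flyvis.ou_adaptation import _aicc

        # e.g. 4 species under the regime+body-size model: n - k - 1 < 0
        with pytest.raises(OUFitError, match="AICc undefined"):
            _aicc(0.0, 5, 4)
        assert _aicc(0.0, 3, 18) == pytest.approx(2 * 3 + 2 * 3 * 4 / 14)


class TestCompareModels:
    def _fake(self, response, predictor, aicc):
        return OUFitResult(
            spec=OUModelSpec(response=response, predictor=predictor),
            t_half=0.1,
            support_region=(0.0, 0.3),
            v_y=0.05,
            alpha=np.log(2) / 0.1,
            sigma2=1.0,
            optima={},
            optima_se={},
            optimal_slope=None,
            optimal_slope_se=None,
            evolutionary_slope=None,
            evolutionary_slope_se=None,
            logL=0.0,
            k_params=3,
            n=18,
            AICc=aicc,
            R2_phylo=0.5,
        )

    def test_study_eye_area_block(self):
        # AICc scores of the four eye-area models: only the full model wins
        fits = [
            self._fake("E_area", p, a)
            for p, a in zip(
                ("none", "bm", "regime", "regime_bm"), (18.40, 8.66, 14.10, -4.38)
            )
        ]
        table = compare_models(fits)
        assert table.fits[table.best_index].AICc == -4.38
        assert table.supported == [False, False, False, True]
        assert table.delta[table.best_index] == 0.0

    def test_order_invariance(self):
        fits = [
            self._fake("E_area", p, a)
            for p, a in zip(
                ("none", "bm", "regime", "regime_bm"), (18.40, 8.66, 14.10, -4.38)
            )
        ]
        rev = compare_models(fits[::-1])
        assert rev.fits[rev.best_index].AICc == -4.38

    def test_single_fit_rejected(self):
        with pytest.raises(OUFitError):
            compare_models([self._fake("E_area", "none", 1.0)])

    def test_mixed_responses_rejected(self):
        with pytest.raises(OUFitError, match="different responses"):
            compare_models(
                [self._fake("E_area", "none", 1.0), self._fake("OC_diameter", "bm", 2.0)]
            )
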