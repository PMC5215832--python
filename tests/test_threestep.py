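import numpy as np
import pandas as pd
import pytest

from multilca import (
    LCAParams,
    bch_distal_means,
    anova_equality_test,
    error_matrix,
    fit_covariates_ml,
    modal_assign,
    simulate_population,
)
from multilca.model import _component_log_probs
from multilca.simulate import CovariateSpec, OutcomeSpec, SyntheticConfig
from multilca.threestep import SeparationError, _wald_equality


def _posteriors(cfg, ds):
    params = LCAParams(cfg.class_proportions, cfg.item_probs)
    lp = _component_log_probs(params, ds.indicators)
    tau = np.exp(lp - lp.max(axis=1, keepdims=True))
    return tau / tau.sum(axis=1, keepdims=True)


@pytest.fixture(scope="module")
def three_class_setup():
    """Population from a three-class model with a class-linked binary
    covariate and outcomes, plus true-parameter posteriors."""
    cfg = SyntheticConfig(
        class_proportions=[0.5, 0.3, 0.2],
        item_probs=[
            [0.85, 0.8, 0.75, 0.7, 0.6],
            [0.2, 0.25, 0.15, 0.3, 0.2],
            [0.8, 0.2, 0.8, 0.2, 0.9],
        ],
        item_names=list("abcde"),
        covariates=[
            CovariateSpec(
                name="x", mode="logit", marginal=0.5, class_odds_ratios=[1.0, 2.0, 0.6]
            )
        ],
        outcomes=[OutcomeSpec(name="y", class_means=np.array([50.0, 45.0, 40.0]), sd=8.0)],
    )
    ds, labels = simulate_population(cfg, n=30_000, seed=31)
    tau = _posteriors(cfg, ds)
    assign = modal_assign(tau)
    d = error_matrix(tau, assign)
    return cfg, ds, labels, tau, assign, d


class TestMLCovariates:
    def test_identity_reduces_to_standard_mnlogit(self, three_class_setup):
        """With D = I the estimator must coincide with an ordinary
        multinomial logit on the modal classes (statsmodels as the
        independent reference implementation)."""
        import statsmodels.api as sm

        _, ds, _, _, assign, _ = three_class_setup
        z = ds.covariates["x"].to_numpy()[:10_000]
        labels = assign.modal_class[:10_000]
        ours = fit_covariates_ml(
            modal_assign(np.eye(3)[labels - 1]),
            np.eye(3),
            z,
            ref_class=1,
        )
        ref = sm.MNLogit(labels - 1, sm.add_constant(z)).fit(disp=False)
        np.testing.assert_allclose(ours.coefficients, ref.params.T, atol=1e-4)
        np.testing.assert_allclose(ours.standard_errors, ref.bse.T, atol=1e-3)

    def test_null_covariate_gives_unit_odds_ratios(self):
        cfg = SyntheticConfig(
            class_proportions=[0.6, 0.4],
            item_probs=[[0.8, 0.75, 0.7], [0.2, 0.25, 0.3]],
            item_names=list("abc"),
        )
        ds, _ = simulate_population(cfg, n=20_000, seed=41)
        rng = np.random.default_rng(42)
        z = rng.integers(0, 2, ds.n_persons).astype(float)  # independent of class
        tau = _posteriors(cfg, ds)
        assign = modal_assign(tau)
        d = error_matrix(tau, assign)
        model = fit_covariates_ml(assign, d, z)
        assert abs(model.odds_ratios[0, 1] - 1.0) < 0.1
        assert model.wald_pvalues["x1"] > 0.01

    def test_recovers_generator_odds_ratios(self, three_class_setup):
        cfg, ds, _, _, assign, d = three_class_setup
        model = fit_covariates_ml(assign, d, ds.covariates)
        assert model.odds_ratio(2, "x") == pytest.approx(2.0, abs=0.25)
        assert model.odds_ratio(3, "x") == pytest.approx(0.6, abs=0.15)
        # CI sanity: lower < OR < upper, OR > 0
        assert np.all(model.ci_lower < model.odds_ratios)
        assert np.all(model.odds_ratios < model.ci_upper)
        assert np.all(model.odds_ratios > 0)

    def test_reference_class_invariance(self, three_class_setup):
        """Coefficients under a different reference class are a linear
        transform of the originals; implied contrasts agree."""
        _, ds, _, _, assign, d = three_class_setup
        m1 = fit_covariates_ml(assign, d, ds.covariates, ref_class=1)
        m2 = fit_covariates_ml(assign, d, ds.covariates, ref_class=2)
        # log-odds of class 3 vs class 2 from both parameterizations
        b1 = m1.coefficients[1] - m1.coefficients[0]  # (3 vs 1) - (2 vs 1)
        b2 = m2.coefficients[1]  # 3 vs 2 directly
        np.testing.assert_allclose(b1, b2, atol=1e-3)

    def test_separation_raises(self):
        labels = np.array([1] * 50 + [2] * 50)
        z = (labels == 2).astype(float)  # perfect predictor
        with pytest.raises(SeparationError):
            fit_covariates_ml(modal_assign(np.eye(2)[labels - 1]), np.eye(2), z)


class TestBCHDistal:
    def test_identity_reduces_to_group_means(self, three_class_setup):
        _, ds, _, _, assign, _ = three_class_setup
        y = ds.outcomes["y"].to_numpy()
        entry = bch_distal_means(assign, np.eye(3), y, n_boot=20, seed=1)
        for t in range(3):
            sel = assign.modal_class == t + 1
            assert entry.means[t] == pytest.approx(y[sel].mean(), abs=1e-9)

    def test_corrects_attenuation_of_naive_means(self, three_class_setup):
        cfg, ds, _, _, assign, d = three_class_setup
        truth = cfg.outcomes[0].class_means
        entry = bch_distal_means(assign, d, ds.outcomes["y"], n_boot=50, seed=2)
        assert np.abs(entry.means - truth).max() < 0.5
        # naive modal means are pulled toward the grand mean
        assert np.abs(entry.naive_means - truth).max() > np.abs(entry.means - truth).max()

    def test_constant_outcome(self, three_class_setup):
        _, ds, _, _, assign, d = three_class_setup
        y = np.full(ds.n_persons, 3.14)
        entry = bch_distal_means(assign, d, y, n_boot=30, seed=3)
        np.testing.assert_allclose(entry.means, 3.14, atol=1e-9)
        assert entry.wald_statistic == 0.0
        assert entry.wald_pvalue == 1.0

    def test_ill_conditioned_matrix_falls_back(self, three_class_setup):
        _, ds, _, _, assign, _ = three_class_setup
        near_singular = np.array(
            [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]]
        )
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            entry = bch_distal_means(
                assign, near_singular, ds.outcomes["y"], n_boot=10, seed=4
            )
        assert entry.method == "naive-fallback"
        np.testing.assert_allclose(entry.means, entry.naive_means)


class TestEqualityTests:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            _wald_equality(np.array([1.0]), np.zeros((1, 1)), 1)

    def test_power_under_large_separation(self):
        """Two classes separated by more than two SDs are detected with
        p < 0.001 in every replicate."""
        cfg = SyntheticConfig(
            class_proportions=[0.5, 0.5],
            item_probs=[[0.9, 0.85, 0.9], [0.1, 0.15, 0.1]],
            item_names=list("abc"),
            outcomes=[OutcomeSpec(name="y", class_means=np.array([50.0, 30.0]), sd=8.0)],
        )
        for rep in range(5):
            ds, _ = simulate_population(cfg, n=3000, seed=100 + rep)
            tau = _posteriors(cfg, ds)
            assign = modal_assign(tau)
            d = error_matrix(tau, assign)
            entry = bch_distal_means(assign, d, ds.outcomes["y"], n_boot=100, seed=rep)
            assert entry.wald_pvalue < 1e-3
            assert entry.anova_pvalue < 1e-3
            res = anova_equality_test(entry)
            assert res["wald_pvalue"] == pytest.approx(entry.wald_pvalue)

    def test_type_one_error_near_nominal(self):
        """Under equal class means both equality tests reject at close to
        the nominal 5% level (the bootstrap Wald is known to run slightly
        liberal in moderate samples)."""
        cfg = SyntheticConfig(
            class_proportions=[0.5, 0.3, 0.2],
            item_probs=[
                [0.85, 0.8, 0.75, 0.7],
                [0.2, 0.25, 0.15, 0.3],
                [0.8, 0.2, 0.8, 0.2],
            ],
            item_names=list("abcd"),
        )
        n_rep = 150
        wald_rej = 0
        anova_rej = 0
        for rep in range(n_rep):
            seed = 1000 + rep
            ds, _ = simulate_population(cfg, n=2000, seed=seed)
            y = np.random.default_rng(seed + 50_000).normal(50, 10, ds.n_persons)
            tau = _posteriors(cfg, ds)
            assign = modal_assign(tau)
            d = error_matrix(tau, assign)
            entry = bch_distal_means(assign, d, y, n_boot=150, seed=seed + 1)
            wald_rej += entry.wald_pvalue < 0.05
            anova_rej += entry.anova_pvalue < 0.05
        assert 0.02 <= wald_rej / n_rep <= 0.11
        assert 0.02 <= anova_rej / n_rep <= 0.09
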