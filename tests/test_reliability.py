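import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from sdqnorm.reliability import (
    PolychoricModel,
    ReliabilityError,
    bvn_cdf,
    cronbach_alpha,
    nonlinear_sem_reliability,
    polychoric_matrix,
    polychoric_pair,
    rho_nl_from_model,
    scale_reliability,
    two_way_impute,
)


def _tau_equivalent_items(lam, thresholds, n, seed, k=5):
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    items = np.empty((n, k))
    for j in range(k):
        z = lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        items[:, j] = sum((z > t).astype(int) for t in thresholds)
    return items


class TestTwoWayImpute:
    def test_additive_matrix_recovered_exactly(self):
        # value = row effect + column effect: zero residual variance, so
        # deleted cells are reproduced exactly
        r = np.array([0.0, 1.0, 0.0, 1.0])
        c = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
        x = (r[:, None] + c[None, :]).astype(float)
        damaged = x.copy()
        damaged[1, 2] = np.nan
        out = two_way_impute(damaged, seed=0)
        assert out[1, 2] == x[1, 2]

    def test_observed_cells_untouched_and_seed_reproducible(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 3, size=(50, 5)).astype(float)
        x[rng.uniform(size=x.shape) < 0.1] = np.nan
        a = two_way_impute(x, seed=3)
        b = two_way_impute(x, seed=3)
        assert np.array_equal(a, b)
        obs = ~np.isnan(x)
        assert np.array_equal(a[obs], x[obs])
        assert np.all(np.isin(a, [0, 1, 2]))

    def test_mcar_deletion_preserves_item_means(self):
        deltas = []
        for seed in range(20):
            items = _tau_equivalent_items(0.6, (0.2, 1.2), 800, seed=seed)
            rng = np.random.default_rng(100 + seed)
            damaged = items.copy()
            damaged[rng.uniform(size=items.shape) < 0.05] = np.nan
            completed = two_way_impute(damaged, seed=seed)
            deltas.append(np.abs(completed.mean(axis=0) - items.mean(axis=0)).mean())
        assert np.mean(deltas) < 0.02

    def test_all_missing_column_rejected(self):
        x = np.ones((5, 3))
        x[:, 1] = np.nan
        with pytest.raises(ReliabilityError):
            two_way_impute(x)


class TestCronbachAlpha:
    def test_closed_form_three_items(self):
        # unit variances, pairwise covariance 0.5 -> alpha = 0.75
        cov = np.full((3, 3), 0.5)
        np.fill_diagonal(cov, 1.0)
        rng = np.random.default_rng(0)
        x = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        assert cronbach_alpha(x) == pytest.approx(0.75, abs=0.01)

    def test_identical_items_give_one(self):
        col = np.random.default_rng(1).normal(size=100)
        x = np.column_stack([col] * 4)
        assert cronbach_alpha(x) == pytest.approx(1.0, abs=1e-12)

    def test_matches_covariance_matrix_oracle(self):
        x = np.random.default_rng(2).integers(0, 3, size=(300, 6)).astype(float)
        k = x.shape[1]
        S = np.cov(x, rowvar=False)
        oracle = k / (k - 1) * (1 - np.trace(S) / S.sum())
        assert cronbach_alpha(x) == pytest.approx(oracle, abs=1e-12)

    def test_item_reordering_invariance(self):
        x = np.random.default_rng(3).integers(0, 3, size=(200, 5)).astype(float)
        assert cronbach_alpha(x) == pytest.approx(
            cronbach_alpha(x[:, ::-1]), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 3)))


class TestPolychoric:
    @pytest.mark.parametrize("rho", [-0.6, 0.0, 0.5, 0.8])
    def test_bvn_cdf_matches_scipy(self, rho):
        rng = np.random.default_rng(4)
        for _ in range(5):
            h, k = rng.normal(size=2)
            ref = multivariate_normal.cdf([h, k], mean=[0, 0],
                                          cov=[[1, rho], [rho, 1]])
            assert float(bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=1e-10)

    def test_recovery_from_discretized_bivariate_normal(self):
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=2000)
        x = (z > 0.2).astype(int) + (z > 1.1).astype(int)
        assert polychoric_pair(x[:, 0], x[:, 1]) == pytest.approx(0.5, abs=0.05)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 3, size=(2000, 2)).astype(float)
        assert abs(polychoric_pair(x[:, 0], x[:, 1])) < 0.05

    def test_identical_items_hit_upper_clamp(self):
        x = np.random.default_rng(7).integers(0, 3, size=500).astype(float)
        assert polychoric_pair(x, x) == pytest.approx(0.999, abs=1e-6)

    def test_matrix_and_common_loading(self):
        items = _tau_equivalent_items(0.7, (0.3, 1.2), 4000, seed=11)
        model = polychoric_matrix(items)
        assert model.loading == pytest.approx(0.7, abs=0.05)
        off = model.corr[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) <= 0.999)

    def test_degenerate_item_rejected(self):
        items = np.column_stack([np.zeros(100), np.arange(100) % 3])
        with pytest.raises(ReliabilityError):
            polychoric_matrix(items)


def _population_rho_nl_oracle(lam, thresholds, k=5):
    """Independent computation of the population coefficient via scipy's
    bivariate-normal CDF (not the package quadrature)."""
    def cell_cov(rho):
        mean = sum(1 - norm.cdf(t) for t in thresholds)
        exy = 0.0
        for a in thresholds:
            for b in thresholds:
                if rho == 1.0:
                    exy += 1 - norm.cdf(max(a, b))
                else:
                    exy += (1 - norm.cdf(a) - norm.cdf(b)
                            + multivariate_normal.cdf([a, b], mean=[0, 0],
                                                      cov=[[1, rho], [rho, 1]]))
        return exy - mean**2

    lam2 = lam * lam
    num = k * k * cell_cov(lam2)
    den = k * (k - 1) * cell_cov(lam2) + k * cell_cov(1.0)
    return num / den


class TestNonlinearSEMReliability:
    def test_no_common_factor_gives_near_zero(self):
        items = _tau_equivalent_items(0.0, (0.3, 1.2), 4000, seed=13)
        assert abs(nonlinear_sem_reliability(items)) < 0.05

    def test_recovery_against_population_oracle(self):
        thresholds = (0.3, 1.2)
        items = _tau_equivalent_items(0.7, thresholds, 5000, seed=14)
        pop = _population_rho_nl_oracle(0.7, thresholds)
        est = nonlinear_sem_reliability(items)
        assert est == pytest.approx(pop, abs=0.03)
        # the package's own closed-form-at-truth route agrees with the oracle
        truth = PolychoricModel(
            thresholds=np.tile(thresholds, (5, 1)),
            corr=np.full((5, 5), 0.49) + np.eye(5) * 0.51,
            loading=0.7)
        assert rho_nl_from_model(truth) == pytest.approx(pop, abs=1e-9)

    def test_two_item_binary_enumeration_oracle(self):
        # symmetric binary items (threshold 0), loading lambda: everything
        # is enumerable through the quadrant probability
        lam = 0.6
        model = PolychoricModel(
            thresholds=np.array([[0.0], [0.0]]),
            corr=np.array([[1.0, lam**2], [lam**2, 1.0]]),
            loading=lam)
        def quadrant(rho):
            return multivariate_normal.cdf([0, 0], mean=[0, 0],
                                           cov=[[1, rho], [rho, 1]])
        cov_f = quadrant(lam**2) - 0.25
        var = 0.25  # Bernoulli(1/2) variance (quadrant at rho=1 is 1/2)
        expected = (4 * cov_f) / (2 * cov_f + 2 * var)
        assert rho_nl_from_model(model) == pytest.approx(expected, abs=1e-6)

    def test_reflection_invariance(self):
        items = _tau_equivalent_items(0.7, (0.3, 1.2), 2000, seed=15)
        assert nonlinear_sem_reliability(2 - items) == pytest.approx(
            nonlinear_sem_reliability(items), abs=1e-9)

    def test_approaches_alpha_with_many_categories(self):
        # a finely discretized linear tau-equivalent model: the threshold
        # nonlinearity washes out and rho_NL approaches alpha
        rng = np.random.default_rng(16)
        f = rng.standard_normal(4000)
        lam = 0.7
        cont = np.column_stack([
            lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(4000)
            for _ in range(5)])
        edges = norm.ppf(np.linspace(0.1, 0.9, 8))
        coarse = sum((cont[..., None] > e).sum(-1) for e in [edges])
        a = cronbach_alpha(coarse)
        r = nonlinear_sem_reliability(coarse, n_cat=9)
        assert abs(a - r) < 0.05


class TestScaleReliability:
    def test_cohort_scale_estimates(self):
        from sdqnorm.simulate import SimulationConfig, generate_cohort

        cohort, _ = generate_cohort(SimulationConfig(n_subjects=1500, seed=19))
        est = scale_reliability(cohort, "hyperactivity", seed=1)
        assert 0.3 < est.alpha <= 1.0
        assert 0.3 < est.rho_nl <= 1.0
        assert est.rho_nl >= est.alpha - 0.05  # ordinal coefficient runs higher
        assert est.n_used == 1500
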