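import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from qfrpullback import (
    DegenerateLabelsError,
    InvalidParameterError,
    OptimalCutoff,
    cohens_kappa,
    fisher_exact_test,
    pearson_r,
    roc_optimal_cutoff,
    standardized_beta,
)
from qfrpullback.errors import CollinearityError, QfrPullbackError
from qfrpullback.stats import (
    DIRECTION_HIGH,
    DIRECTION_LOW,
    anova_oneway,
    group_tests,
)

from ._oracles import fisher_enumerate_2xc, roc_scan


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.3, 0.4, 0.6, 0.8])
        events = np.array([True, True, False, False])
        res = roc_optimal_cutoff(scores, events, DIRECTION_LOW)
        assert res.auc == pytest.approx(1.0)
        assert 0.4 < res.optimal_cutoff < 0.6
        assert res.sensitivity_at_optimum == 1.0
        assert res.specificity_at_optimum == 1.0

    def test_degenerate_labels(self):
        with pytest.raises(DegenerateLabelsError):
            roc_optimal_cutoff([0.1, 0.2], [True, True])

    def test_matches_sklearn_auc_and_bruteforce_optimum(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 60))
            scores = np.round(rng.uniform(0, 1, n), 2)  # ties on purpose
            events = rng.uniform(size=n) < 0.35
            if events.all() or not events.any():
                continue
            res = roc_optimal_cutoff(scores, events, DIRECTION_LOW)
            assert res.auc == pytest.approx(roc_auc_score(events, -scores), abs=1e-12)
            auc_o, cut_o, sens_o, spec_o = roc_scan(scores, events, direction_low=True)
            assert res.auc == pytest.approx(auc_o, abs=1e-12)
            assert res.optimal_cutoff == pytest.approx(cut_o)
            assert res.sensitivity_at_optimum == pytest.approx(sens_o)
            assert res.specificity_at_optimum == pytest.approx(spec_o)

    def test_permuted_labels_auc_near_half(self, rng):
        scores = rng.uniform(size=500)
        events = rng.permutation([True] * 250 + [False] * 250)
        res = roc_optimal_cutoff(scores, events)
        assert abs(res.auc - 0.5) < 0.1

    def test_estimator_fit_predict(self):
        scores = np.array([0.2, 0.3, 0.7, 0.9])
        events = np.array([True, True, False, False])
        est = OptimalCutoff(direction=DIRECTION_LOW).fit(scores, events)
        assert est.auc_ == 1.0
        np.testing.assert_array_equal(est.predict([0.1, 0.95]), [True, False])
        est_hi = OptimalCutoff(direction=DIRECTION_HIGH).fit(-scores, events)
        assert est_hi.auc_ == 1.0


class TestPearson:
    def test_exact_linear_relations(self, rng):
        x = rng.uniform(size=30)
        assert pearson_r(x, 2 * x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x + 3)[0] == pytest.approx(-1.0)

    def test_ci_covers_true_rho(self):
        rho, n = 0.6, 120
        cov = [[1, rho], [rho, 1]]
        hits = 0
        for seed in range(100):
            xy = np.random.default_rng(seed).multivariate_normal([0, 0], cov, size=n)
            r, (lo, hi) = pearson_r(xy[:, 0], xy[:, 1])
            hits += lo <= rho <= hi
        assert hits >= 90  # nominal 95% coverage

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            pearson_r([1, 2, 3], [1, 2, 3])
        with pytest.raises(QfrPullbackError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestKappa:
    def test_perfect_agreement(self):
        a = ["focal", "diffuse", "serial", "focal"]
        k, _ = cohens_kappa(a, list(a))
        assert k == pytest.approx(1.0)

    def test_constant_rater_is_chance_level(self):
        a = ["x"] * 10 + ["y"] * 10
        b = ["x"] * 20
        k, _ = cohens_kappa(a, b)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2_table(self):
        # table [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        a = ["p"] * 25 + ["q"] * 25
        b = ["p"] * 20 + ["q"] * 5 + ["p"] * 10 + ["q"] * 15
        k, (lo, hi) = cohens_kappa(a, b)
        assert k == pytest.approx(0.4, abs=1e-12)
        assert lo < 0.4 < hi

    def test_invariant_to_relabeling(self, rng):
        a = list(rng.choice(["u", "v", "w"], size=60))
        b = list(rng.choice(["u", "v", "w"], size=60))
        k1, _ = cohens_kappa(a, b)
        swap = {"u": "w", "v": "u", "w": "v"}
        k2, _ = cohens_kappa([swap[x] for x in a], [swap[x] for x in b])
        assert k1 == pytest.approx(k2, abs=1e-12)
        assert k1 <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            cohens_kappa(["a"], ["a", "b"])


class TestGroupTests:
    def test_fisher_2x2_no_association(self):
        assert fisher_exact_test([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_monte_carlo_matches_enumeration_on_2x3(self):
        table = [[8, 3, 1], [2, 6, 5]]
        exact = fisher_enumerate_2xc(table)
        mc = fisher_exact_test(table, n_resamples=100_000, seed=0)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_anova_detects_shift_and_validates(self, rng):
        g = np.repeat(["a", "b", "c"], 40)
        x = rng.normal(size=120) + np.repeat([0.0, 0.0, 1.0], 40)
        assert anova_oneway(x, g) < 0.001
        with pytest.raises(InvalidParameterError):
            anova_oneway(x[:40], g[:40])  # single group

    def test_family_is_bonferroni_adjusted(self, rng):
        g = np.repeat(["a", "b"], 30)
        res = group_tests(
            continuous={"x": rng.normal(size=60), "y": rng.normal(size=60)},
            categorical={"flag": rng.uniform(size=60) < 0.5},
            groups=g,
            n_resamples=2000,
        )
        assert len(res) == 3
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, 3 * r.p_raw))


class TestStandardizedBeta:
    def test_exact_linear_gives_unit_beta(self, rng):
        x = rng.normal(size=50)
        res = standardized_beta(3 * x + 1, pd.DataFrame({"x": x}))
        assert res[0].beta == pytest.approx(1.0, abs=1e-9)
        assert res[0].ci_high - res[0].ci_low < 1e-6

    def test_null_predictor_beta_near_zero(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = r.normal(size=500)
            x = r.normal(size=500)
            res = standardized_beta(y, pd.DataFrame({"x": x}))
            hits += abs(res[0].beta) < 0.1
        assert hits >= 95

    def test_cluster_robust_with_patient_groups(self, rng):
        n = 200
        cluster = np.repeat(np.arange(n // 2), 2)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        res = standardized_beta(y, pd.DataFrame({"x": x}), cluster=cluster)
        assert res[0].ci_low < res[0].beta < res[0].ci_high
        assert res[0].beta > 0.2

    def test_collinearity_rejected(self, rng):
        x = rng.normal(size=40)
        with pytest.raises(CollinearityError):
            standardized_beta(x, pd.DataFrame({"a": x, "b": 2 * x}))
        with pytest.raises(CollinearityError):
            standardized_beta(x, pd.DataFrame({"a": np.ones(40)}))
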