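"""PCC / RF weight matrices, permutation P values, and thresholding."""

import math

import numpy as np
import pandas as pd
import pytest

import micronet as mn


def _profile(values, labels=None):
    values = np.asarray(values, dtype=float)
    units = [f"U{i:02d}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return mn.AbundanceProfile(
        abundance=pd.DataFrame(values, index=units, columns=samples), level="KO"
    )


def pearson_oracle(x, y):
    """Naive two-loop Pearson correlation, written directly from the formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    dx = sum((x[i] - mx) ** 2 for i in range(n))
    dy = sum((y[i] - my) ** 2 for i in range(n))
    return num / math.sqrt(dx * dy)


class TestPccWeightMatrix:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        w = mn.pcc_weight_matrix(_profile([x, 2 * x]))
        assert w.weights[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        w = mn.pcc_weight_matrix(_profile([x, x.max() + 1 - x]))
        assert w.weights[0, 1] == pytest.approx(-1.0)

    def test_hand_evaluated_half(self):
        w = mn.pcc_weight_matrix(_profile([[1, 2, 3], [1, 3, 2]]))
        assert w.weights[0, 1] == pytest.approx(0.5)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.lognormal(size=(20, 10))
        w = mn.pcc_weight_matrix(_profile(X))
        for i in range(20):
            for j in range(i + 1, 20):
                assert w.weights[i, j] == pytest.approx(
                    pearson_oracle(X[i], X[j]), abs=1e-12
                )
        assert np.allclose(w.weights, w.weights.T)
        assert np.all(np.diag(w.weights) == 0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(12)
        X = rng.random((6, 9))
        base = mn.pcc_weight_matrix(_profile(X)).weights
        scaled = mn.pcc_weight_matrix(_profile(3.5 * X + 0.2)).weights
        assert np.allclose(base, scaled, atol=1e-12)

    def test_zero_variance_unit_rejected_by_name(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="U00"):
            mn.pcc_weight_matrix(_profile(X))


class TestPermutationPValues:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(13)
        prof = _profile(rng.random((5, 12)))
        a = mn.pcc_permutation_pvalues(prof, n_perm=200, seed=9)
        b = mn.pcc_permutation_pvalues(prof, n_perm=200, seed=9)
        assert np.array_equal(a.p, b.p)

    def test_minimum_attainable_p(self):
        # perfectly correlated pair: no permutation can beat |r| = 1
        x = np.arange(10.0)
        prof = _profile([x, 2 * x + 0.1])
        res = mn.pcc_permutation_pvalues(prof, n_perm=99, seed=1)
        assert res.p[0, 1] == pytest.approx(1 / 100)

    def test_null_p_not_extreme(self):
        """An independently shuffled copy should not look significant."""
        rng = np.random.default_rng(14)
        x = rng.random(50)
        y = rng.permutation(x)
        res = mn.pcc_permutation_pvalues(_profile([x, y]), n_perm=999, seed=2)
        assert res.p[0, 1] > 10 / 1000

    def test_symmetric_and_positive(self):
        rng = np.random.default_rng(15)
        res = mn.pcc_permutation_pvalues(_profile(rng.random((4, 8))), n_perm=50, seed=3)
        assert np.array_equal(res.p, res.p.T)
        assert (res.p > 0).all() and (res.p <= 1).all()

    def test_n_perm_validated(self):
        with pytest.raises(ValueError):
            mn.pcc_permutation_pvalues(_profile(np.random.default_rng(0).random((3, 5))), n_perm=0)


class TestRfWeightMatrix:
    def test_monotone_dependency_dominates(self):
        """A unit that is an exact monotone function of another should make
        that predictor the top importance in its column."""
        rng = np.random.default_rng(21)
        X = rng.lognormal(size=(20, 100))
        X[0] = np.sqrt(X[1])  # unit 0 determined by unit 1
        w = mn.rf_weight_matrix(_profile(X), n_trees=50, seed=4)
        col = w.weights[:, 0]
        assert np.argmax(col) == 1

    def test_same_seed_bitwise_identical(self):
        rng = np.random.default_rng(22)
        prof = _profile(rng.random((6, 20)))
        a = mn.rf_weight_matrix(prof, n_trees=20, seed=5)
        b = mn.rf_weight_matrix(prof, n_trees=20, seed=5)
        assert np.array_equal(a.weights, b.weights)
        assert not a.symmetric

    def test_independent_noise_not_above_shuffled_baseline(self):
        """With fully independent units, the top importance should be of the
        same order as importances for a shuffled (decoupled) target."""
        rng = np.random.default_rng(23)
        X = rng.lognormal(size=(10, 80))
        w = mn.rf_weight_matrix(_profile(X), n_trees=50, seed=6)
        Xs = X.copy()
        Xs[0] = rng.permutation(Xs[0])
        ws = mn.rf_weight_matrix(_profile(Xs), n_trees=50, seed=6)
        assert w.weights[:, 0].max() < 5 * ws.weights[:, 0].max()

    def test_constant_target_warns_and_zeroes(self):
        X = np.vstack([np.ones(10), np.random.default_rng(1).random((2, 10))])
        prof = _profile(X)
        with pytest.warns(UserWarning, match="constant"):
            w = mn.rf_weight_matrix(prof, n_trees=10, seed=0)
        assert np.all(w.weights[:, 0] == 0)


class TestSymmetrize:
    def test_max_and_mean_rules(self):
        w = mn.WeightMatrix(
            ["a", "b"], np.array([[0.0, 0.8], [0.2, 0.0]]), method="rf", symmetric=False
        )
        assert mn.symmetrize(w, "max").weights[0, 1] == pytest.approx(0.8)
        assert mn.symmetrize(w, "mean").weights[0, 1] == pytest.approx(0.5)

    def test_symmetric_input_unchanged(self):
        m = np.array([[0.0, 0.3], [0.3, 0.0]])
        w = mn.WeightMatrix(["a", "b"], m, method="rf", symmetric=False)
        assert np.array_equal(mn.symmetrize(w, "max").weights, m)

    def test_unknown_rule(self):
        w = mn.WeightMatrix(["a", "b"], np.zeros((2, 2)), method="rf", symmetric=False)
        with pytest.raises(ValueError):
            mn.symmetrize(w, "median")


class TestThresholdNetwork:
    def _wm(self, n, seed=0, method="pcc"):
        rng = np.random.default_rng(seed)
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        units = [f"U{i:03d}" for i in range(n)]
        return mn.WeightMatrix(units, m, method=method, symmetric=True)

    @pytest.mark.parametrize("n,expected", [(3, 3), (10, 15), (101, 151)])
    def test_edge_count_rule(self, n, expected):
        net = mn.threshold_network(self._wm(n), 1.5)
        assert net.number_of_edges() == min(expected, n * (n - 1) // 2)

    def test_saturates_at_all_pairs(self):
        net = mn.threshold_network(self._wm(3), 10.0)
        assert net.number_of_edges() == 3

    def test_tie_broken_lexicographically(self):
        m = np.zeros((4, 4))
        # U0-U1 strong; U0-U3 and U2-U3 tied at the cutoff
        m[0, 1] = m[1, 0] = 0.9
        m[0, 3] = m[3, 0] = 0.5
        m[2, 3] = m[3, 2] = 0.5
        w = mn.WeightMatrix(["U0", "U1", "U2", "U3"], m, method="rf", symmetric=True)
        net = mn.threshold_network(w, 0.5)  # floor(0.5*4) = 2 edges
        assert net.has_edge("U0", "U1")
        assert net.has_edge("U0", "U3")
        assert not net.has_edge("U2", "U3")

    def test_pcc_ranked_by_absolute_value_with_sign_attr(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = -0.9
        m[0, 2] = m[2, 0] = 0.4
        m[1, 2] = m[2, 1] = 0.1
        w = mn.WeightMatrix(["a", "b", "c"], m, method="pcc", symmetric=True)
        net = mn.threshold_network(w, 2 / 3)  # keep 2 edges
        assert net.has_edge("a", "b") and net.edges["a", "b"]["sign"] == -1
        assert net.has_edge("a", "c") and net.edges["a", "c"]["sign"] == 1

    def test_isolated_units_excluded(self):
        net = mn.threshold_network(self._wm(10), 0.3)  # 3 edges over 10 units
        assert net.number_of_nodes() <= 6

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            mn.threshold_network(self._wm(4), 0.0)

    def test_asymmetric_rejected(self):
        w = mn.WeightMatrix(["a", "b"], np.array([[0, 1.0], [0.5, 0]]), "rf", False)
        with pytest.raises(ValueError):
            mn.threshold_network(w)


class TestThresholdByPvalue:
    def _pv(self, p):
        n = p.shape[0]
        return mn.PermutationPValues([f"U{i}" for i in range(n)], p, n_perm=99, seed=0)

    def test_counts_edges_below_alpha(self):
        p = np.full((4, 4), 0.5)
        p[0, 1] = p[1, 0] = 0.001
        p[2, 3] = p[3, 2] = 0.005
        net = mn.threshold_by_pvalue(self._pv(p), alpha=0.01)
        assert net.number_of_edges() == 2

    def test_alpha_below_minimum_empty(self):
        p = np.full((3, 3), 0.01)
        net = mn.threshold_by_pvalue(self._pv(p), alpha=0.005)
        assert net.number_of_edges() == 0

    def test_alpha_one_complete(self):
        p = np.full((4, 4), 1.0)
        net = mn.threshold_by_pvalue(self._pv(p), alpha=1.0)
        assert net.number_of_edges() == 6

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            mn.threshold_by_pvalue(self._pv(np.ones((2, 2))), alpha=0.0)
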