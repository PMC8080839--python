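"""Indicator primitives and the thirteen-indicator catalogue."""

import numpy as np
import pytest
from scipy.linalg import eigh

from ewsbench.errors import (
    CatalogueError,
    NotApplicableError,
    UndefinedStatisticError,
)
from ewsbench.indicators import (
    INDICATOR_NAMES,
    MULTIVARIATE_ONLY,
    compute_all_indicators,
    compute_indicator,
    covariance_matrix,
    ksg_mutual_information,
    lag1_autocorrelation,
    maf_decomposition,
    orientation,
    whiten,
)


def ar1(rng, n, phi, ncols=1):
    e = rng.standard_normal((n, ncols))
    x = np.empty((n, ncols))
    x[0] = e[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


class TestLag1Autocorrelation:
    def test_alternating_series_hand_value(self):
        # mean 0, numerator -3, denominator 4
        assert lag1_autocorrelation([1, -1, 1, -1]) == pytest.approx(-0.75)

    def test_ar1_recovers_coefficient(self, rng):
        x = ar1(rng, 100_000, 0.8)
        assert lag1_autocorrelation(x) == pytest.approx(0.8, abs=0.01)

    def test_shuffled_noise_is_uncorrelated(self, rng):
        x = rng.standard_normal(50_000)
        rng.shuffle(x)
        assert abs(lag1_autocorrelation(x)) < 0.02

    def test_constant_series_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            lag1_autocorrelation(np.ones(10))


class TestCovariance:
    def test_matches_brute_force_pair_loop(self, rng):
        X = rng.standard_normal((60, 4))
        C = covariance_matrix(X)
        Xc = X - X.mean(axis=0)
        brute = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                brute[i, j] = (Xc[:, i] * Xc[:, j]).sum() / (60 - 1)
        assert C == pytest.approx(brute, abs=1e-12)

    def test_identical_columns_give_rank_one(self, rng):
        x = rng.standard_normal(100)
        C = covariance_matrix(np.column_stack([x, x]))
        assert C[0, 0] == pytest.approx(C[0, 1]) == pytest.approx(C[1, 1])


class TestWhiten:
    def test_output_has_identity_covariance(self, rng):
        X = rng.multivariate_normal([0, 0], [[2.0, 1.2], [1.2, 1.0]], 5000)
        Y, W = whiten(X)
        assert covariance_matrix(Y) == pytest.approx(np.eye(2), abs=1e-8)
        assert (X - X.mean(axis=0)) @ W == pytest.approx(Y)

    def test_single_variable_scales_by_inverse_sd(self, rng):
        x = rng.normal(0, 3.0, (1000, 1))
        Y, W = whiten(x)
        assert W[0, 0] == pytest.approx(1.0 / x.std(ddof=1), rel=1e-10)

    def test_rank_deficiency_drops_null_direction(self, rng):
        x = rng.standard_normal(200)
        X = np.column_stack([x, 2 * x])
        with pytest.warns(UserWarning, match="rank deficient"):
            Y, W = whiten(X)
        assert Y.shape[1] == 1


class TestMAF:
    def test_recovers_hidden_slow_direction(self, rng):
        # AR(1) + white noise, randomly rotated: the first MAF projection
        # must recover the autocorrelated axis
        n = 20_000
        slow = ar1(rng, n, 0.9)[:, 0]
        fast = rng.standard_normal(n)
        X = np.column_stack([slow, fast])
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        maf = maf_decomposition(X @ R.T)
        d = maf.weights[:, 0] / np.linalg.norm(maf.weights[:, 0])
        axis = R @ np.array([1.0, 0.0])
        assert abs(d @ axis) > 0.95

    def test_white_noise_eigenvalues_are_two(self, rng):
        # first difference of unit-variance white noise has variance 2
        maf = maf_decomposition(rng.standard_normal((50_000, 3)))
        assert maf.eigenvalues == pytest.approx(np.full(3, 2.0), abs=0.05)

    def test_equals_generalised_eigenproblem(self, rng):
        X = ar1(rng, 800, 0.6, ncols=4) + 0.3 * rng.standard_normal((800, 4))
        maf = maf_decomposition(X)
        CX = covariance_matrix(X)
        CD = covariance_matrix(np.diff(X, axis=0))
        gev = np.sort(eigh(CD, CX, eigvals_only=True))
        assert maf.eigenvalues == pytest.approx(gev, abs=1e-8)

    def test_eigenvalues_ascending_and_nonnegative(self, rng):
        maf = maf_decomposition(rng.standard_normal((500, 5)))
        assert np.all(np.diff(maf.eigenvalues) >= 0)
        assert np.all(maf.eigenvalues >= 0)


class TestKSGMutualInformation:
    def test_independent_samples_give_zero(self, rng):
        z = rng.standard_normal((5000, 2))
        assert abs(ksg_mutual_information(z[:, :1], z[:, 1:])) < 0.05

    @pytest.mark.parametrize("rho", [0.2, 0.5, 0.8])
    def test_bivariate_gaussian_closed_form(self, rho):
        # MI = -1/2 log2(1 - rho^2) bits for a correlated Gaussian pair
        rng = np.random.default_rng(314159)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 10_000)
        mi = ksg_mutual_information(z[:, :1], z[:, 1:])
        assert mi == pytest.approx(-0.5 * np.log2(1 - rho**2), abs=0.05)

    def test_self_information_diverges_with_n(self, rng):
        x = rng.standard_normal((2000, 1))
        small = ksg_mutual_information(x[:500], x[:500])
        large = ksg_mutual_information(x, x)
        assert small > 2.0
        assert large > small


class TestCatalogue:
    def test_has_thirteen_indicators_with_fixed_orientations(self):
        assert len(INDICATOR_NAMES) == 13
        falling = [n for n in INDICATOR_NAMES
                   if orientation(n) == "decreases_toward_transition"]
        assert falling == ["maf_eigenvalue"]

    def test_unknown_name_lists_catalogue(self, rng):
        with pytest.raises(CatalogueError, match="avg_variance"):
            compute_indicator("not_an_indicator", rng.standard_normal((50, 2)))

    def test_anticorrelated_pair_has_unit_cross_correlation(self, rng):
        x = rng.standard_normal(500)
        X = np.column_stack([x, -x + 1e-9 * rng.standard_normal(500)])
        v = compute_indicator("avg_cross_correlation", X)
        assert v.value == pytest.approx(1.0, abs=1e-6)

    def test_diagonal_covariance_family(self, rng):
        # construct data with covariance exactly diag(3, 1)
        n = 4000
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std(ddof=1)
        b -= (b @ a) / (a @ a) * a  # orthogonalise
        b = (b - b.mean()) / b.std(ddof=1)
        X = np.column_stack([np.sqrt(3) * a, b])
        assert compute_indicator("pca_variance", X).value == pytest.approx(3.0, rel=1e-9)
        assert compute_indicator("max_covariance", X).value == pytest.approx(3.0, rel=1e-9)
        assert compute_indicator("explained_variance", X).value == pytest.approx(0.75, rel=1e-9)

    def test_max_dominates_average(self, rng):
        X = ar1(rng, 2000, 0.5, ncols=4)
        mx_v = compute_indicator("node_max_variance", X).value
        av_v = compute_indicator("avg_variance", X).value
        mx_a = compute_indicator("node_max_autocorrelation", X).value
        av_a = compute_indicator("avg_autocorrelation", X).value
        assert mx_v >= av_v
        assert mx_a >= av_a

    def test_maf_autocorrelation_dominates_best_node(self, rng):
        # MAF maximises autocorrelation over linear combinations
        X = ar1(rng, 20_000, 0.8, ncols=2) + 0.2 * rng.standard_normal((20_000, 2))
        maf_ac = compute_indicator("maf_autocorrelation", X).value
        node_ac = compute_indicator("node_max_autocorrelation", X).value
        assert maf_ac >= node_ac - 0.02

    def test_pca_variance_equals_top_covariance_eigenvalue(self, rng):
        X = rng.multivariate_normal([0, 0, 0], np.diag([1.0, 2.0, 0.5]), 300)
        v = compute_indicator("pca_variance", X).value
        assert v == pytest.approx(np.linalg.eigvalsh(covariance_matrix(X))[-1],
                                  abs=1e-8)

    def test_bounded_indicators_stay_in_range(self, rng):
        X = rng.standard_normal((300, 3))
        ev = compute_indicator("explained_variance", X).value
        cc = compute_indicator("avg_cross_correlation", X).value
        assert 0 < ev <= 1
        assert 0 <= cc <= 1

    def test_multivariate_only_indicators_reject_single_variable(self, rng):
        x = rng.standard_normal((100, 1))
        for name in sorted(MULTIVARIATE_ONLY):
            with pytest.raises(NotApplicableError):
                compute_indicator(name, x)
        # univariate-capable ones still work
        assert np.isfinite(compute_indicator("avg_variance", x).value)

    def test_compute_all_skips_gracefully_on_single_variable(self, rng):
        with pytest.warns(UserWarning, match="skipping"):
            out = compute_all_indicators(rng.standard_normal((100, 1)))
        assert {v.name for v in out} == set(INDICATOR_NAMES) - MULTIVARIATE_ONLY
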