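import math
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from betashift.exceptions import (
    DegenerateInputError,
    RankDeficiencyError,
    StandardizationError,
)
from betashift.inference import (
    glm_fit,
    great_circle_matrix,
    mantel,
    mrm,
    paired_t,
    pairwise_change_matrix,
    relative_change,
    transform_standardize,
    vif,
)


def _rand_dist(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=(n, 3))
    return np.linalg.norm(x[:, None] - x[None, :], axis=2)


def _tril(M):
    i, j = np.tril_indices(M.shape[0], k=-1)
    return M[i, j]


class TestTransforms:
    def test_minmax(self):
        assert np.allclose(transform_standardize([2, 4, 6]), [0, 0.5, 1])

    def test_log_equal_spacing(self):
        assert np.allclose(transform_standardize([1, 10, 100], "log"),
                           [0, 0.5, 1])

    def test_constant_vector_raises(self):
        with pytest.raises(StandardizationError):
            transform_standardize([5, 5, 5])

    def test_log_domain_error(self):
        with pytest.raises(ValueError):
            transform_standardize([1, 0, 2], "log")

    def test_relative_change(self):
        assert relative_change(100, 60) == pytest.approx(-0.40)
        assert relative_change(7, 7) == 0.0
        assert relative_change(3, 6) == pytest.approx(1.0)
        with pytest.raises(ZeroDivisionError):
            relative_change(0, 1)

    def test_pairwise_change_matrix_modes(self):
        M = pairwise_change_matrix([1.0, 3.0], "abs_diff")
        assert M[0, 1] == 2.0
        M2 = pairwise_change_matrix([1.0, 3.0], "mean")
        assert M2[0, 1] == 2.0 and M2[0, 0] == 0.0

    def test_great_circle_sanity(self):
        # one degree of longitude at the equator is ~111 km
        d = great_circle_matrix([0.0, 1.0], [0.0, 0.0])
        assert d[0, 1] == pytest.approx(111.19, abs=0.5)


def brute_force_mantel_p(A, B):
    """Exact two-sided Mantel p by enumerating all n! relabelings of B."""
    a = _tril(A)
    a = (a - a.mean()) / a.std()
    n = A.shape[0]

    def r_of(perm):
        Bp = B[np.ix_(perm, perm)]
        b = _tril(Bp)
        return float(a @ ((b - b.mean()) / b.std()) / a.size)

    r_obs = r_of(tuple(range(n)))
    count = sum(abs(r_of(p)) >= abs(r_obs) - 1e-12
                for p in iter_permutations(range(n)))
    return r_obs, count / math.factorial(n)


class TestMantel:
    def test_self_comparison_is_maximal(self):
        A = _rand_dist(8, 0)
        res = mantel(A, A, nperm=99, seed=1)
        assert res.correlation == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100, abs=0.05)

    def test_spearman_monotone_decreasing(self):
        A = _rand_dist(8, 1)
        B = np.exp(-A)
        res = mantel(A, B, method="spearman", nperm=49, seed=0)
        assert res.correlation == pytest.approx(-1.0)

    def test_exact_enumeration_matches_brute_force(self):
        A = _rand_dist(4, 2)
        B = _rand_dist(4, 3)
        res = mantel(A, B, nperm="exact")
        r_ref, p_ref = brute_force_mantel_p(A, B)
        assert res.correlation == pytest.approx(r_ref)
        assert res.p_value == pytest.approx(p_ref)
        assert res.nperm == 24

    def test_constant_triangle_raises(self):
        with pytest.raises(DegenerateInputError):
            mantel(np.zeros((4, 4)), _rand_dist(4, 0), nperm=9)

    def test_matches_scikit_bio_correlation(self):
        skbio = pytest.importorskip("skbio")
        A, B = _rand_dist(10, 5), _rand_dist(10, 6)
        ours = mantel(A, B, nperm=999, seed=0)
        r, p, _ = skbio.stats.distance.mantel(
            A, B, method="pearson", permutations=999,
            alternative="two-sided")
        assert ours.correlation == pytest.approx(r, abs=1e-12)
        assert ours.p_value == pytest.approx(p, abs=0.05)


def brute_force_mrm_p(Y, preds):
    """Exact MRM coefficient p-values by full enumeration."""
    n = Y.shape[0]
    X = np.column_stack([np.ones(n * (n - 1) // 2)]
                        + [_tril(P) for P in preds])
    pinv = np.linalg.pinv(X)
    beta_obs = pinv @ _tril(Y)
    counts = np.zeros(len(beta_obs))
    for p in iter_permutations(range(n)):
        Yp = Y[np.ix_(p, p)]
        beta = pinv @ _tril(Yp)
        counts += np.abs(beta) >= np.abs(beta_obs) - 1e-12
    return beta_obs, counts / math.factorial(n)


class TestMRM:
    def test_exact_linear_response(self):
        P = _rand_dist(8, 7)
        res = mrm(3.0 * P, {"p": P}, nperm=49, seed=0)
        assert res.coefficients["p"] == pytest.approx(3.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_exact_enumeration_matches_brute_force(self):
        Y = _rand_dist(4, 8)
        P1, P2 = _rand_dist(4, 9), _rand_dist(4, 10)
        res = mrm(Y, {"p1": P1, "p2": P2}, nperm="exact")
        beta_ref, p_ref = brute_force_mrm_p(Y, [P1, P2])
        assert np.allclose(res.coefficients.to_numpy(), beta_ref)
        assert np.allclose(res.p_values.to_numpy(), p_ref)

    def test_collinear_predictors_raise(self):
        P = _rand_dist(6, 11)
        with pytest.raises(RankDeficiencyError):
            mrm(_rand_dist(6, 12), {"p1": P, "p2": 2.0 * P}, nperm=9)

    def test_independent_response_p_is_roughly_uniform(self):
        pvals = [mrm(_rand_dist(12, 100 + k), {"p": _rand_dist(12, 200 + k)},
                     nperm=99, seed=k).p_values["p"]
                 for k in range(40)]
        assert 0.3 <= np.median(pvals) <= 0.7


class TestGLM:
    def test_gaussian_exact_fit(self):
        x = np.arange(10, dtype=float)
        res = glm_fit(2.0 * x, pd.DataFrame({"x": x}), "gaussian")
        assert res.coefficients["x"] == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_poisson_group_means_closed_form(self):
        # binary covariate with group means 2 and 4: intercept ln2, slope ln2
        x = np.repeat([0.0, 1.0], 50)
        y = np.concatenate([np.full(50, 2.0), np.full(50, 4.0)])
        res = glm_fit(y, pd.DataFrame({"x": x}), "poisson")
        assert res.coefficients["const"] == pytest.approx(np.log(2), abs=1e-6)
        assert res.coefficients["x"] == pytest.approx(np.log(2), abs=1e-6)

    def test_duplicate_column_rank_deficient(self):
        x = np.arange(12, dtype=float)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(RankDeficiencyError):
            glm_fit(x, X, "gaussian")

    def test_parameter_recovery_gaussian(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
            y = 1.0 + 0.8 * X["a"] - 0.5 * X["b"] + rng.normal(0, 0.5, 60)
            res = glm_fit(y.to_numpy(), X, "gaussian")
            err = res.coefficients[["a", "b"]] - [0.8, -0.5]
            hits += bool((err.abs()
                          <= 3 * res.std_errors[["a", "b"]]).all())
        assert hits >= 47  # ~99.7% nominal coverage per coefficient


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        assert np.allclose(vif(X), 1.0)

    def test_constructed_r2_gives_vif_4(self):
        rng = np.random.default_rng(4)
        x1 = rng.normal(size=5000)
        noise = rng.normal(size=5000)
        # scale noise so that R2(x2 ~ x1) ~= 0.75 -> VIF ~= 4
        x2 = x1 * np.sqrt(3) + noise * 1.0
        X = pd.DataFrame({"x1": x1, "x2": x2})
        assert vif(X)["x2"] == pytest.approx(4.0, rel=0.1)

    def test_perfect_collinearity_is_infinite(self):
        x = np.arange(10, dtype=float)
        assert np.isinf(vif(pd.DataFrame({"a": x, "b": x}))["a"])


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])  # d = 1, 2, 3
        assert res.statistic == pytest.approx(2 / (1 / np.sqrt(3)))
        assert res.df == 2
        ref = stats.ttest_rel([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_identical_vectors_undefined(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_sign_flip_negates_t(self):
        a = np.array([3.0, 5.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 2.0, 1.0])
        assert paired_t(a, b).statistic == pytest.approx(
            -paired_t(b, a).statistic)
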