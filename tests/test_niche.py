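from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from divaxes import niche


def _table(x: np.ndarray, groups=None) -> pd.DataFrame:
    n, p = x.shape
    df = pd.DataFrame(x, columns=[f"v{i}" for i in range(p)])
    df.insert(0, "group", groups if groups is not None else ["a"] * n)
    df.insert(0, "site_id", [f"s{i}" for i in range(n)])
    return df


# ------------------------------------------------------------------ PCA


def test_pca_collinear_two_variables():
    x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
    res = niche.standardize_and_pca(_table(x))
    assert res.variance_fraction[0] == pytest.approx(1.0)
    assert res.variance_fraction[1] == pytest.approx(0.0, abs=1e-12)


def test_pca_reconstructs_standardized_data(rng):
    x = rng.standard_normal((15, 6))
    res = niche.standardize_and_pca(_table(x), n_axes=6)
    z = (x - x.mean(0)) / x.std(0, ddof=1)
    assert np.allclose(res.scores @ res.loadings.T, z, atol=1e-8)
    # orthonormal loadings, non-increasing variance fractions
    assert np.allclose(res.loadings.T @ res.loadings, np.eye(6), atol=1e-10)
    assert np.all(np.diff(res.variance_fraction) <= 1e-12)
    assert res.variance_fraction.sum() <= 1 + 1e-9


def test_pca_sign_convention_deterministic(rng):
    x = rng.standard_normal((12, 4))
    res = niche.standardize_and_pca(_table(x))
    peak = np.abs(res.loadings).argmax(axis=0)
    assert np.all(res.loadings[peak, np.arange(res.loadings.shape[1])] > 0)


def test_pca_constant_column_named_in_error():
    x = np.ones((5, 3))
    x[:, 0] = np.arange(5)
    x[:, 2] = np.arange(5) ** 2
    with pytest.raises(ValueError, match="v1"):
        niche.standardize_and_pca(_table(x))


def test_pca_axes_beyond_rank_rejected(rng):
    x = rng.standard_normal((4, 6))  # rank <= 3
    with pytest.raises(ValueError, match="rank"):
        niche.standardize_and_pca(_table(x), n_axes=5)


def test_pca_recovers_latent_variance_ratios():
    """Three orthogonal factors with variances 9:4:1, equal per-variable
    share (Hadamard loadings) and vanishing noise: the correlation-matrix
    eigenvalue fractions approach 9/14, 4/14, 1/14."""
    h = np.array(
        [[1, 1, 1], [1, -1, 1], [1, 1, -1], [1, -1, -1]], dtype=float
    )  # orthogonal columns, |col|^2 = 4
    lm = h / 2 * np.array([3.0, 2.0, 1.0])
    rng = np.random.default_rng(17)
    latent = rng.standard_normal((4000, 3))
    x = latent @ lm.T + rng.normal(scale=1e-4, size=(4000, 4))
    res = niche.standardize_and_pca(_table(x), n_axes=4)
    expected = np.array([9, 4, 1, 0]) / 14
    assert np.allclose(res.variance_fraction, expected, atol=0.02)


# ------------------------------------------------------------------- Di


def test_di_observed_hand_arithmetic():
    scores = np.array([[1.0], [2.0], [3.0], [4.0], [6.0]])
    groups = ["A", "A", "A", "B", "B"]
    assert niche.di_observed(scores, groups, 0) == pytest.approx(-3.0)


def test_di_observed_antisymmetric(rng):
    scores = rng.standard_normal((10, 2))
    groups = ["A"] * 5 + ["B"] * 5
    assert niche.di_observed(scores, groups, 1, order=("A", "B")) == pytest.approx(
        -niche.di_observed(scores, groups, 1, order=("B", "A"))
    )


def test_di_observed_requires_two_groups():
    with pytest.raises(ValueError):
        niche.di_observed(np.zeros((4, 1)), ["A"] * 4, 0)


def test_di_test_degenerate_scores_give_p_one():
    scores = np.ones((8, 1))
    res = niche.di_permutation_test(scores, ["A"] * 4 + ["B"] * 4, 0, 999, seed=0)
    assert res.di_observed == 0.0
    assert res.p_value == 1.0


def test_di_pvalue_consistent_with_stored_null(rng):
    """The declared formula holds against the stored null sample, under
    both tail policies and both denominator conventions."""
    scores = rng.standard_normal((12, 1))
    groups = ["A"] * 6 + ["B"] * 6
    two = niche.di_permutation_test(scores, groups, 0, 499, seed=3)
    assert two.p_value == pytest.approx(
        np.mean(np.abs(two.null_sample) >= abs(two.di_observed))
    )
    one = niche.di_permutation_test(scores, groups, 0, 499, seed=3, tail="greater")
    assert one.p_value == pytest.approx(np.mean(one.null_sample >= one.di_observed))
    plus = niche.di_permutation_test(scores, groups, 0, 499, seed=3, plus_one=True)
    count = int(np.sum(np.abs(plus.null_sample) >= abs(plus.di_observed)))
    assert plus.p_value == pytest.approx((count + 1) / 500)
    assert plus.p_value > 0


def test_di_exact_enumeration_matches_independent_oracle(rng):
    scores = rng.standard_normal((6, 1))
    groups = ["A", "A", "A", "B", "B", "B"]
    res = niche.di_permutation_test(scores, groups, 0, seed=0, exact=True)
    assert res.n_permutations == 20

    s = scores[:, 0]
    obs = s[:3].mean() - s[3:].mean()
    null = []
    for idx in combinations(range(6), 3):
        rest = [i for i in range(6) if i not in idx]
        null.append(s[list(idx)].mean() - s[rest].mean())
    p_oracle = sum(abs(d) >= abs(obs) for d in null) / 20
    assert res.p_value == pytest.approx(p_oracle)


def test_di_pvalue_invariant_to_affine_rescaling(rng):
    scores = rng.standard_normal((12, 2))
    groups = ["A"] * 6 + ["B"] * 6
    r1 = niche.di_permutation_test(scores, groups, 1, 499, seed=5)
    r2 = niche.di_permutation_test(scores * 3.7 - 11.0, groups, 1, 499, seed=5)
    assert r1.p_value == r2.p_value


def test_di_null_reproducible_from_seed(rng):
    scores = rng.standard_normal((10, 1))
    groups = ["A"] * 5 + ["B"] * 5
    a = niche.di_permutation_test(scores, groups, 0, 499, seed=123)
    b = niche.di_permutation_test(scores, groups, 0, 499, seed=123)
    assert np.array_equal(a.null_sample, b.null_sample)


# --------------------------------------------------------------- MANOVA


def test_manova_identical_means_lambda_one():
    rng = np.random.default_rng(4)
    a = rng.standard_normal((8, 3))
    b = -a + 2 * a.mean(axis=0)  # mirrored: identical group means
    y = np.vstack([a, b])
    groups = ["A"] * 8 + ["B"] * 8
    res = niche.wilks_manova(y, groups)
    assert res.wilks_lambda == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_manova_single_axis_reduces_to_anova(rng):
    from scipy import stats

    y = rng.standard_normal((14, 1)) + np.r_[np.zeros(7), np.ones(7)][:, None]
    groups = ["A"] * 7 + ["B"] * 7
    res = niche.wilks_manova(y, groups)
    f, p = stats.f_oneway(y[:7, 0], y[7:, 0])
    assert res.approx_F == pytest.approx(f)
    assert res.p_value == pytest.approx(p)


def test_manova_matches_statsmodels(rng):
    from statsmodels.multivariate.manova import MANOVA

    y = rng.standard_normal((20, 3))
    y[10:] += [0.8, -0.5, 0.2]
    groups = np.array(["A"] * 10 + ["B"] * 10)
    res = niche.wilks_manova(y, groups)
    df = pd.DataFrame(y, columns=["y1", "y2", "y3"])
    df["g"] = groups
    sm_res = MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df).mv_test()
    stats_tab = sm_res.results["g"]["stat"]
    assert res.wilks_lambda == pytest.approx(
        float(stats_tab.loc["Wilks' lambda", "Value"])
    )
    assert res.approx_F == pytest.approx(
        float(stats_tab.loc["Wilks' lambda", "F Value"]), rel=1e-6
    )


def test_manova_small_groups_rejected():
    y = np.random.default_rng(0).standard_normal((6, 3))
    with pytest.raises(ValueError):
        niche.wilks_manova(y, ["A"] * 3 + ["B"] * 3)  # group size == n_axes
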