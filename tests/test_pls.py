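"""The 2B-PLS core: decomposition, loadings, significance, invariants."""

import numpy as np
import pytest
from scipy import stats

from facepls.pls import (
    PLS2B,
    PLSDataError,
    correlation_with_scores,
    critical_r,
    preprocess,
    significance_mask,
    variance_shares,
)
from facepls.simulate import generate_blocks


def brute_force_max_cov(z1, z2, n_grid=300_000):
    """Independent oracle: maximise cov(Z1 u, Z2 v) over unit vectors.

    For fixed u the optimal v is C'u / ||C'u|| with C = Z1'Z2/(n-1), so a
    dense grid over the unit sphere of the smaller block suffices.  Only
    usable for blocks of <= 3 columns.
    """
    n = z1.shape[0]
    if z1.shape[1] > z2.shape[1]:
        z1, z2 = z2, z1
    c = z1.T @ z2 / (n - 1)
    p = c.shape[0]
    if p == 1:
        return float(np.linalg.norm(c))
    if p == 2:
        theta = np.linspace(0, np.pi, n_grid)
        u = np.stack([np.cos(theta), np.sin(theta)])
    elif p == 3:
        i = np.arange(n_grid, dtype=float)
        phi = np.arccos(1 - 2 * (i + 0.5) / n_grid)  # Fibonacci sphere
        lam = np.pi * (1 + 5**0.5) * i
        u = np.stack([np.sin(phi) * np.cos(lam), np.sin(phi) * np.sin(lam), np.cos(phi)])
    else:
        raise ValueError("oracle only supports p <= 3")
    return float(np.linalg.norm(u.T @ c, axis=1).max())


class TestPreprocess:
    def test_centering(self):
        z, rec = preprocess(np.array([[1.0], [2.0], [3.0]]), "center")
        np.testing.assert_allclose(z[:, 0], [-1, 0, 1])
        assert rec.constant_columns == ()

    def test_center_scale_gives_unit_sd(self):
        z, rec = preprocess(np.array([[1.0], [2.0], [3.0]]), "center_scale")
        np.testing.assert_allclose(z[:, 0], [-1, 0, 1])  # sd of [1,2,3] is exactly 1
        assert np.std(z[:, 0], ddof=1) == pytest.approx(1.0)

    def test_constant_column_zeroed_and_flagged(self):
        z, rec = preprocess(np.array([[2.0, 1.0], [2.0, 2.0], [2.0, 3.0]]), "center_scale")
        np.testing.assert_allclose(z[:, 0], 0.0)
        assert rec.constant_columns == (0,)

    def test_too_few_objects_rejected(self):
        with pytest.raises(PLSDataError, match="3 objects"):
            preprocess(np.ones((2, 2)))

    def test_nan_rejected(self):
        x = np.ones((4, 2))
        x[0, 0] = np.nan
        with pytest.raises(PLSDataError, match="missing"):
            preprocess(x)


class TestFit:
    def test_identical_single_columns_give_perfect_pair(self, rng):
        z = rng.standard_normal((20, 1))
        res = PLS2B(z, z).fit()
        assert res.k == 1
        np.testing.assert_allclose(np.abs(res.weights_b1), [[1.0]])
        r = np.corrcoef(res.scores_b1[:, 0], res.scores_b2[:, 0])[0, 1]
        assert r == pytest.approx(1.0)

    @pytest.mark.parametrize("p1,p2,seed", [(2, 3, 0), (3, 3, 1), (2, 2, 2), (3, 2, 3)])
    def test_first_singular_value_matches_brute_force_oracle(self, p1, p2, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.standard_normal((8, p1))
        x2 = rng.standard_normal((8, p2))
        res = PLS2B(x1, x2).fit()
        z1, _ = preprocess(x1)
        z2, _ = preprocess(x2)
        oracle = brute_force_max_cov(z1, z2)
        assert res.score_covariances[0] == pytest.approx(oracle, abs=1e-3)

    def test_paper_block_design_gives_13_structures(self, rng):
        res = PLS2B(rng.standard_normal((30, 13)), rng.standard_normal((30, 26))).fit()
        assert res.k == 13

    def test_row_count_mismatch_rejected(self, rng):
        with pytest.raises(PLSDataError, match="rows"):
            PLS2B(rng.standard_normal((10, 3)), rng.standard_normal((11, 3)))

    def test_fit_tolerates_more_columns_than_rows_and_collinearity(self, rng):
        # p >> n and exact linear combinations in block 2
        x1 = rng.standard_normal((5, 8))
        base = rng.standard_normal((5, 6))
        x2 = np.hstack([base, base[:, :3] + base[:, 3:6], 2.0 * base[:, :3]])
        res = PLS2B(x1, x2).fit()
        assert res.k == 8
        _assert_conservation(res)


def _assert_conservation(res, tol=1e-10):
    k = res.k
    np.testing.assert_allclose(res.weights_b1.T @ res.weights_b1, np.eye(k), atol=tol)
    np.testing.assert_allclose(res.weights_b2.T @ res.weights_b2, np.eye(k), atol=tol)
    assert abs(res.variance_share.sum() - 1.0) < tol
    cross = res.scores_b1.T @ res.scores_b2
    np.testing.assert_allclose(cross - np.diag(np.diag(cross)), 0.0, atol=1e-8)
    np.testing.assert_allclose(np.diag(cross) / (res.n_objects - 1),
                               res.score_covariances, atol=tol)
    assert (np.diff(res.singular_values) <= 1e-12).all()


class TestInvariants:
    def test_conservation_on_random_fits(self, rng):
        for n, p1, p2 in [(30, 5, 9), (162, 13, 26), (12, 4, 4)]:
            res = PLS2B(rng.standard_normal((n, p1)), rng.standard_normal((n, p2))).fit()
            _assert_conservation(res)

    def test_sign_convention_deterministic(self, rng):
        res = PLS2B(rng.standard_normal((25, 6)), rng.standard_normal((25, 8))).fit()
        for k in range(res.k):
            col = res.weights_b1[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_orthogonal_rotation_preserves_singular_values_and_rotates_weights(self, rng):
        x1 = rng.standard_normal((40, 5))
        x2 = rng.standard_normal((40, 7))
        z1, _ = preprocess(x1)
        z2, _ = preprocess(x2)
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        base = PLS2B(z1, z2, mode="center").fit()
        rot = PLS2B(z1 @ q, z2, mode="center").fit()
        np.testing.assert_allclose(rot.singular_values, base.singular_values, atol=1e-10)
        # weights of the rotated block are the rotated weights, up to per-axis sign
        expected = q.T @ base.weights_b1
        dots = np.abs(np.sum(expected * rot.weights_b1, axis=0))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_planted_weights_recovered_at_default_snr(self):
        hits = 0
        for seed in range(20):
            b1, b2, truth = generate_blocks(n=162, p1=13, p2=26, seed=seed)
            res = PLS2B(b1, b2).fit()
            r = abs(np.corrcoef(res.weights_b1[:, 0], truth["u1"])[0, 1])
            hits += r > 0.9
        assert hits >= 19


class TestVarianceShares:
    def test_arithmetic(self):
        np.testing.assert_allclose(variance_shares([2.0, 1.0, 1.0]), [4 / 6, 1 / 6, 1 / 6])

    def test_single_structure_normalises_to_one(self):
        np.testing.assert_allclose(variance_shares([3.7]), [1.0])

    def test_all_zero_is_an_error(self):
        with pytest.raises(PLSDataError, match="undefined"):
            variance_shares([0.0, 0.0])


class TestCorrelationLoadings:
    def test_variable_equal_to_score_loads_one(self, rng):
        t = rng.standard_normal((30, 1))
        r, flagged = correlation_with_scores(t, t)
        assert r[0, 0] == pytest.approx(1.0)
        assert not flagged.any()

    def test_orthogonal_variable_loads_zero(self):
        x = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        t = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        r, _ = correlation_with_scores(x, t)
        assert abs(r[0, 0]) < 1e-10

    def test_matches_direct_pearson_computation(self, rng):
        x = rng.standard_normal((20, 4))
        res = PLS2B(x, rng.standard_normal((20, 3))).fit()
        for j in range(4):
            for k in range(res.k):
                expected = stats.pearsonr(x[:, j], res.scores_b1[:, k]).statistic
                assert res.corr_loadings_b1[j, k] == pytest.approx(expected, abs=1e-12)

    def test_constant_variable_flagged_zero(self, rng):
        x = rng.standard_normal((15, 3))
        x[:, 1] = 4.2
        res = PLS2B(x, rng.standard_normal((15, 2))).fit()
        assert np.all(res.corr_loadings_b1[1] == 0.0)
        assert res.undefined_loadings_b1[1].all()


class TestSignificance:
    def test_null_and_perfect_correlations(self):
        assert not significance_mask(np.array([[0.0]]), 50).any()
        assert significance_mask(np.array([[1.0]]), 50).all()
        assert significance_mask(np.array([[-1.0]]), 50).all()

    def test_mask_flips_exactly_at_critical_r(self):
        n, alpha = 162, 0.05
        rc = critical_r(n, alpha)
        # numerically inverted threshold: p(rc) == alpha
        t = rc * np.sqrt((n - 2) / (1 - rc**2))
        assert 2 * stats.t.sf(t, n - 2) == pytest.approx(alpha, abs=1e-12)
        below, above = rc * (1 - 1e-9), rc * (1 + 1e-9)
        assert not significance_mask(np.array([[below]]), n, alpha).any()
        assert significance_mask(np.array([[above]]), n, alpha).all()

    def test_mask_monotone_in_alpha(self, rng):
        r = np.clip(rng.uniform(-0.5, 0.5, size=(6, 4)), -1, 1)
        strict = significance_mask(r, 40, alpha=0.01)
        loose = significance_mask(r, 40, alpha=0.05)
        assert (strict <= loose).all()

    def test_permutation_pvalues_contract(self):
        """Shuffle-based p-values: valid range, right shapes, seeded determinism."""
        b1, b2, _ = generate_blocks(n=40, p1=4, p2=5, snr=1.0, seed=5)
        res = PLS2B(b1, b2).fit()
        p1, p2 = res.permutation_loading_pvalues(n_permutations=49, seed=0)
        assert p1.shape == res.corr_loadings_b1.shape
        assert p2.shape == res.corr_loadings_b2.shape
        for p in (p1, p2):
            assert (p > 0).all() and (p <= 1).all()
        q1, _ = res.permutation_loading_pvalues(n_permutations=49, seed=0)
        np.testing.assert_array_equal(p1, q1)
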