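import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from rarepart import (
    HellingerTransformer,
    VariationPartitioning,
    adjusted_r2,
    rda_r2,
    transform_response,
    varpart2,
)


def _random_problem(rng, n=30, s=4, px=2, pw=2):
    Y = rng.normal(size=(n, s))
    X = rng.normal(size=(n, px))
    W = rng.normal(size=(n, pw))
    return Y, X, W


class TestTransforms:
    def test_hellinger_row_values(self):
        out = transform_response(np.array([[1.0, 3.0], [1.0, 3.0], [1.0, 3.0]]), "hellinger")
        # before centering every row is (sqrt(1/4), sqrt(3/4)); identical rows
        # centre to zero, so reconstruct from the uncentred transform
        from rarepart import hellinger

        raw = hellinger(np.array([[1.0, 3.0]]))
        np.testing.assert_allclose(raw, [[0.5, np.sqrt(3) / 2]])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_presence_absence(self):
        t = HellingerTransformer(mode="presence_absence").fit(np.zeros((3, 2)))
        raw = np.array([[0.0, 4.0], [2.0, 0.0], [0.0, 0.0]])
        out = t.transform(raw)
        binary = out + (raw > 0).mean(axis=0)
        np.testing.assert_array_equal(binary, [[0, 1], [1, 0], [0, 0]])

    def test_none_is_identity_on_centered(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(8, 3))
        Y -= Y.mean(axis=0)
        out = transform_response(Y, "none")
        np.testing.assert_allclose(out.values, Y, atol=1e-14)

    def test_columns_sum_to_zero_all_modes(self):
        rng = np.random.default_rng(1)
        Y = rng.poisson(2.0, size=(20, 7)).astype(float) + 0.1
        for mode in ("hellinger", "presence_absence", "none"):
            out = transform_response(Y, mode)
            np.testing.assert_allclose(out.values.sum(axis=0), 0.0, atol=1e-10 * 20)

    def test_zero_row_warns_under_hellinger(self):
        Y = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        with pytest.warns(UserWarning, match="zero total"):
            transform_response(Y, "hellinger")


class TestRdaR2:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        Yt = (x - x.mean()).reshape(-1, 1)
        assert rda_r2(Yt, x.reshape(-1, 1)) == pytest.approx(1.0, abs=1e-12)

    def test_empty_block_is_null_model(self):
        rng = np.random.default_rng(2)
        Yt = rng.normal(size=(10, 3))
        assert rda_r2(Yt, np.empty((10, 0))) == 0.0

    def test_matches_normal_equations_oracle(self):
        """R² equals SS(fitted)/SS(total) from explicitly solved normal equations."""
        rng = np.random.default_rng(3)
        Yt = rng.normal(size=(20, 3))
        X = rng.normal(size=(20, 2))
        Yc = Yt - Yt.mean(axis=0)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
        fitted = Xc @ beta
        expected = np.sum(fitted**2) / np.sum(Yc**2)
        assert rda_r2(Yt, X) == pytest.approx(expected, abs=1e-10)

    def test_saturated_model_errors(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="saturated"):
            rda_r2(rng.normal(size=(4, 2)), rng.normal(size=(4, 3)))

    def test_scale_and_duplication_invariance(self):
        rng = np.random.default_rng(5)
        Yt = rng.normal(size=(15, 3))
        X = rng.normal(size=(15, 2))
        r = rda_r2(Yt, X)
        assert rda_r2(Yt, X * 7.3) == pytest.approx(r, abs=1e-12)
        assert rda_r2(Yt, np.hstack([X, X])) == pytest.approx(r, abs=1e-10)


class TestAdjustedR2:
    @pytest.mark.parametrize(
        "r2,n,m,expected",
        [
            (0.5, 11, 1, 1 - 0.5 * 10 / 9),
            (1.0, 30, 5, 1.0),
            (0.0, 20, 5, 1 - 19 / 14),
            (0.3, 50, 0, 0.3),
        ],
    )
    def test_closed_form(self, r2, n, m, expected):
        assert adjusted_r2(r2, n, m) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 5, 4)
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 5, -1)


class TestVarpart2:
    def test_duplicated_block_zeroes_pure_fractions(self):
        rng = np.random.default_rng(6)
        Yt = rng.normal(size=(20, 3))
        X = rng.normal(size=(20, 2))
        res = varpart2(Yt, X, X.copy())
        assert res.frac_a == pytest.approx(0.0, abs=1e-10)
        assert res.frac_c == pytest.approx(0.0, abs=1e-10)

    def test_residualization_oracle(self):
        """Fractions agree with explicit semipartial residualization.

        Regress Yt on W, regress the residuals on X: the gain in unadjusted
        R² is R²(full) − R²(W); applying the same Ezekiel adjustment scheme
        reproduces every subtraction-scheme fraction.
        """
        rng = np.random.default_rng(7)
        Y, X, W = _random_problem(rng, n=30, s=4, px=2, pw=2)
        res = varpart2(Y, X, W)

        def r2_explicit(Yc, block):
            Bc = block - block.mean(axis=0)
            beta = np.linalg.pinv(Bc) @ Yc
            fitted = Bc @ beta
            return np.sum(fitted**2) / np.sum(Yc**2)

        Yc = Y - Y.mean(axis=0)
        n = 30
        r2w = r2_explicit(Yc, W)
        r2x = r2_explicit(Yc, X)
        r2f = r2_explicit(Yc, np.hstack([X, W]))
        # semipartial identity: residualize on W, regress residuals on
        # residualized X -> increment equals r2f - r2w
        Wc = W - W.mean(axis=0)
        Pw = Wc @ np.linalg.pinv(Wc)
        Yres = Yc - Pw @ Yc
        Xres = (X - X.mean(axis=0)) - Pw @ (X - X.mean(axis=0))
        inc = np.sum((Xres @ (np.linalg.pinv(Xres) @ Yres)) ** 2) / np.sum(Yc**2)
        assert inc == pytest.approx(r2f - r2w, abs=1e-10)

        A = 1 - (1 - r2x) * (n - 1) / (n - 2 - 1)
        C = 1 - (1 - r2w) * (n - 1) / (n - 2 - 1)
        T = 1 - (1 - r2f) * (n - 1) / (n - 4 - 1)
        assert res.frac_a == pytest.approx(T - C, abs=1e-8)
        assert res.frac_b == pytest.approx(A + C - T, abs=1e-8)
        assert res.frac_c == pytest.approx(T - A, abs=1e-8)
        assert res.frac_d == pytest.approx(1 - T, abs=1e-8)

    def test_matches_vegan_frozen_values(self, vegan_fixture):
        """Frozen expected values computed with vegan::varpart 2.7-1."""
        Y, X, W = vegan_fixture
        res = varpart2(transform_response(Y, "hellinger"), X, W)
        assert res.r2_env == pytest.approx(0.183799625452, abs=1e-10)
        assert res.r2_space == pytest.approx(0.221257992864, abs=1e-10)
        assert res.r2_full == pytest.approx(0.308030747167, abs=1e-10)
        assert res.frac_a == pytest.approx(-0.1355844679532, abs=1e-10)
        assert res.frac_b == pytest.approx(0.1380062323949, abs=1e-10)
        assert res.frac_c == pytest.approx(-0.0898020188938, abs=1e-10)
        assert res.frac_d == pytest.approx(1.0873802544521, abs=1e-10)
        assert set(res.negative_fractions) == {"frac_a", "frac_c"}

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        Y, X, W = _random_problem(rng, n=rng.integers(12, 40), s=rng.integers(2, 6))
        res = varpart2(Y, X, W)
        total = res.frac_a + res.frac_b + res.frac_c + res.frac_d
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(8)
        Y, X, W = _random_problem(rng)
        r1 = varpart2(Y, X, W)
        r2 = varpart2(Y, W, X)
        assert r1.frac_a == pytest.approx(r2.frac_c, abs=1e-12)
        assert r1.frac_c == pytest.approx(r2.frac_a, abs=1e-12)
        assert r1.frac_b == pytest.approx(r2.frac_b, abs=1e-12)
        assert r1.frac_d == pytest.approx(r2.frac_d, abs=1e-12)

    def test_noise_column_does_not_inflate_pure_env(self):
        """Adjustment property: adding a noise predictor leaves the expected
        pure-environment fraction unchanged (mean difference <= 0 + 2 SE
        over 200 Monte-Carlo draws)."""
        rng = np.random.default_rng(9)
        diffs = np.empty(200)
        for i in range(200):
            Y, X, W = _random_problem(rng, n=25, s=3, px=2, pw=2)
            base = varpart2(Y, X, W).frac_a
            noisy = varpart2(Y, np.hstack([X, rng.normal(size=(25, 1))]), W).frac_a
            diffs[i] = noisy - base
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert diffs.mean() <= 2 * se

    def test_noiseless_linear_response(self):
        """Y an exact linear function of X, W pure noise: pure space vanishes
        and pure environment carries the whole adjusted fit."""
        rng = np.random.default_rng(10)
        n = 100
        X = rng.normal(size=(n, 3))
        Y = X @ rng.normal(size=(3, 4))
        W = rng.normal(size=(n, 2))
        res = varpart2(Y, X, W)
        assert res.frac_c == pytest.approx(0.0, abs=1e-8)
        T = res.frac_a + res.frac_b + res.frac_c
        assert res.frac_a == pytest.approx(T, abs=0.02)

    def test_zero_variance_response_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            varpart2(np.ones((10, 2)), np.random.default_rng(0).normal(size=(10, 1)), None)


class TestEstimator:
    def test_fit_and_clone(self, small_community):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(10, 2))
        W = rng.normal(size=(10, 2))
        est = VariationPartitioning(transform="hellinger").fit(small_community, X, W)
        assert set(est.fractions_) == {"a", "b", "c", "d"}
        assert sum(est.fractions_.values()) == pytest.approx(1.0, abs=1e-10)
        assert est.score() == pytest.approx(1.0 - est.result_.frac_d, abs=1e-12)
        cloned = clone(est)
        assert cloned.get_params()["transform"] == "hellinger"
        assert not hasattr(cloned, "result_")
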