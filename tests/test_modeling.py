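import math

import numpy as np
import pytest

from cisrate.fold_features import FeatureMatrix
from cisrate.modeling import (
    UndersizedPartError,
    bootstrap_r2,
    collinearity_overlap,
    combined_model,
    exhaustive_select_bic,
    fit_multipart,
    forward_select_bic,
    utr_length_increment,
)


def _fm(X, prefix="c"):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix.from_dict(
        [f"g{i}" for i in range(X.shape[0])],
        {f"{prefix}{j}": X[:, j] for j in range(X.shape[1])},
    )


class TestFitMultipart:
    def test_simple_regression_closed_form(self, rng):
        x = rng.standard_normal(80)
        y = 2.0 + 1.5 * x + rng.standard_normal(80) * 0.1
        fit = fit_multipart(x[:, None], y, ["part1"] * 80, ["x"])
        slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        b0, b = fit.per_part_coefficients["part1"]
        assert b0 == pytest.approx(intercept)
        assert b[0] == pytest.approx(slope)
        assert fit.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_exact_linear_r2_one(self, rng):
        X = rng.standard_normal((50, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3
        fit = fit_multipart(X, y, ["part1"] * 50)
        assert fit.r2 == pytest.approx(1.0)

    def test_pooled_r2_equals_squared_pearson(self, rng):
        for _ in range(30):
            n = 120
            X = rng.standard_normal((n, 4))
            y = X @ rng.standard_normal(4) + rng.standard_normal(n)
            parts = rng.choice(["a", "b", "c"], n)
            fit = fit_multipart(X, y, parts)
            r = np.corrcoef(y, fit.predictions)[0, 1]
            assert abs(fit.r2 - r**2) < 1e-10

    def test_per_part_coefficients_differ(self, rng):
        n = 100
        x = rng.standard_normal(n)
        parts = np.array(["a"] * 50 + ["b"] * 50)
        y = np.where(parts == "a", 2 * x, -3 * x)
        fit = fit_multipart(x[:, None], y, parts, ["x"])
        assert fit.per_part_coefficients["a"][1][0] == pytest.approx(2.0)
        assert fit.per_part_coefficients["b"][1][0] == pytest.approx(-3.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_undersized_part_error(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        parts = ["a"] * 5 + ["b"] * 5
        with pytest.raises(UndersizedPartError, match="part"):
            fit_multipart(X, y, parts)

    def test_nesting(self, rng):
        X = rng.standard_normal((60, 5))
        y = rng.standard_normal(60)
        parts = ["p"] * 60
        r2_small = fit_multipart(X[:, :2], y, parts).r2
        r2_big = fit_multipart(X, y, parts).r2
        assert r2_big >= r2_small - 1e-9


class TestForwardSelectBic:
    def test_signal_vs_noise(self, rng):
        n = 300
        X = rng.standard_normal((n, 8))
        y = 1.2 * X[:, 3] + 0.4 * rng.standard_normal(n)
        fit = forward_select_bic(_fm(X), y, ["p"] * n)
        assert "c3" in fit.selected_features

    def test_matches_exhaustive(self, rng):
        for _ in range(15):
            n = 150
            k = int(rng.integers(5, 11))
            X = rng.standard_normal((n, k))
            y = X[:, 0] + 0.6 * X[:, 1] + rng.standard_normal(n)
            fm = _fm(X)
            fwd = forward_select_bic(fm, y, ["p"] * n)
            names, bic = exhaustive_select_bic(fm, y, ["p"] * n)
            assert sorted(fwd.selected_features) == sorted(names)
            assert fwd.bic == pytest.approx(bic, abs=1e-6)

    def test_null_selects_nothing(self, rng):
        empties = 0
        for _ in range(10):
            n = 500
            X = rng.standard_normal((n, 10))
            y = rng.standard_normal(n)
            fit = forward_select_bic(_fm(X), y, ["p"] * n)
            empties += not fit.selected_features
        assert empties >= 9

    def test_duplicate_column_ignored(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = x + 0.3 * rng.standard_normal(n)
        fm = FeatureMatrix.from_dict(
            [f"g{i}" for i in range(n)], {"a": x, "b": x.copy()}
        )
        fit = forward_select_bic(fm, y, ["p"] * n)
        assert len(fit.selected_features) == 1  # the duplicate never helps

    def test_multipart_selection_is_joint(self, rng):
        n = 200
        X = rng.standard_normal((n, 4))
        parts = np.array(["a"] * 100 + ["b"] * 100)
        y = np.where(parts == "a", 2.0, -1.0) * X[:, 2] + 0.3 * rng.standard_normal(n)
        fit = forward_select_bic(_fm(X), y, parts)
        assert "c2" in fit.selected_features
        assert set(fit.per_part_coefficients) == {"a", "b"}


class TestBootstrap:
    def test_b1_degenerate(self, rng):
        X = rng.standard_normal((50, 2))
        y = X @ np.array([1.0, 0.5]) + rng.standard_normal(50) * 0.3
        lo, hi = bootstrap_r2(X, y, ["p"] * 50, B=1, seed=4)
        assert lo == pytest.approx(hi)

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((80, 2))
        y = X[:, 0] + rng.standard_normal(80)
        a = bootstrap_r2(X, y, ["p"] * 80, B=50, seed=9)
        b = bootstrap_r2(X, y, ["p"] * 80, B=50, seed=9)
        assert a == b

    def test_ci_contains_full_r2_mostly(self, rng):
        hits = 0
        for trial in range(20):
            n = 150
            X = rng.standard_normal((n, 3))
            y = X @ np.array([1.0, 0.5, -0.5]) + rng.standard_normal(n)
            full = fit_multipart(X, y, ["p"] * n).r2
            lo, hi = bootstrap_r2(X, y, ["p"] * n, B=200, seed=trial)
            if lo - 0.01 <= full <= hi + 0.01:
                hits += 1
        assert hits >= 18


class TestOverlap:
    def test_identical_sets_full_overlap(self, rng):
        X = rng.standard_normal((100, 2))
        y = X[:, 0] + rng.standard_normal(100)
        a = _fm(X, "a")
        b = _fm(X, "b")
        ov = collinearity_overlap(a, b, y, ["p"] * 100)
        assert ov.overlap_pct == pytest.approx(100.0)

    def test_orthogonal_predictors_no_overlap(self, rng):
        n = 400
        M = rng.standard_normal((n, 2))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))
        y = Q[:, 0] + Q[:, 1]
        ov = collinearity_overlap(_fm(Q[:, :1], "a"), _fm(Q[:, 1:], "b"), y, ["p"] * n)
        assert ov.overlap_pct == pytest.approx(0.0, abs=1e-6)

    def test_nesting_invariant(self, rng):
        for _ in range(50):
            n = 150
            X = rng.standard_normal((n, 4))
            y = X @ rng.standard_normal(4) + rng.standard_normal(n)
            ov = collinearity_overlap(_fm(X[:, :2], "a"), _fm(X[:, 2:], "b"), y, ["p"] * n)
            assert ov.r2_ab >= max(ov.r2_a, ov.r2_b) - 1e-9
            if ov.overlap_pct is not None:
                assert 0 <= ov.overlap_pct <= 100

    def test_nonpositive_r2_undefined(self, rng):
        n = 60
        y = rng.standard_normal(n)
        const = _fm(np.ones((n, 1)), "a")
        x = _fm(rng.standard_normal((n, 1)), "b")
        ov = collinearity_overlap(const, x, y, ["p"] * n)
        assert ov.overlap_pct is None


class TestCombinedModel:
    def test_nesting_over_singles(self, rng):
        n = 200
        X = rng.standard_normal((n, 4))
        y = X @ np.array([1, 0.5, -0.5, 0.2]) + rng.standard_normal(n)
        sets = {"s1": _fm(X[:, :2], "a"), "s2": _fm(X[:, 2:], "b")}
        fit, contrib = combined_model(sets, y, ["p"] * n)
        assert fit.r2 >= max(c["r2"] for c in contrib.values()) - 1e-9

    def test_bootstrap_attached(self, rng):
        n = 100
        X = rng.standard_normal((n, 2))
        y = X[:, 0] + rng.standard_normal(n)
        fit, _ = combined_model({"s": _fm(X)}, y, ["p"] * n, bootstrap=20, seed=1)
        assert fit.bootstrap_ci is not None


class TestUtrLengthIncrement:
    def test_nonnegative_and_duplicate_zero(self, rng):
        n = 120
        utr = rng.integers(5, 200, n)
        x = np.log10(utr + 1.0)
        y = x + 0.2 * rng.standard_normal(n)
        base_with = FeatureMatrix.from_dict([f"g{i}" for i in range(n)], {"dup": x})
        inc = utr_length_increment(base_with, utr, y, ["p"] * n)
        assert inc == pytest.approx(0.0, abs=1e-9)
        base_without = _fm(rng.standard_normal((n, 1)))
        inc2 = utr_length_increment(base_without, utr, y, ["p"] * n)
        assert inc2 >= -1e-9
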