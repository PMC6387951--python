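"""Combination validation: splits, OLS, NRMSE, optimism adjustment."""

from itertools import combinations
from math import comb

import numpy as np
import pytest

from plicasym import (
    SplitResult,
    enumerate_splits,
    fit_line,
    nrmse,
    optimism_adjusted_r2,
    select_best_line,
    validate,
)


class TestEnumerateSplits:
    def test_nine_choose_three(self):
        splits = enumerate_splits(9, 3)
        assert len(splits) == 84
        test_sets = [s[1] for s in splits]
        assert len(set(test_sets)) == 84
        for subject in range(9):
            assert sum(subject in t for t in test_sets) == comb(8, 2) == 28

    def test_small_cases_and_errors(self):
        assert len(enumerate_splits(3, 1)) == 3
        assert enumerate_splits(4, 2)[0] == ((2, 3), (0, 1))
        with pytest.raises(ValueError):
            enumerate_splits(3, 3)

    def test_splits_partition_cohort(self):
        for train, test in enumerate_splits(7, 3):
            assert sorted(train + test) == list(range(7))
            assert not set(train) & set(test)


class TestFitLine:
    def test_noiseless_line(self):
        x = np.arange(6.0)
        slope, intercept, r2 = fit_line(x, 2 * x + 1)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(30):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            slope, intercept, r2 = fit_line(x, y)
            # independent normal-equations solve
            sxx = np.sum((x - x.mean()) ** 2)
            b = np.sum((x - x.mean()) * (y - y.mean())) / sxx
            a = y.mean() - b * x.mean()
            assert slope == pytest.approx(b, rel=1e-10)
            assert intercept == pytest.approx(a, rel=1e-10, abs=1e-12)
            resid = y - (b * x + a)
            r2_oracle = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
            assert r2 == pytest.approx(r2_oracle, rel=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            fit_line([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="constant outcome"):
            _, _, r2 = fit_line([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert r2 == 0.0


class TestNRMSE:
    def test_values(self):
        assert nrmse([1.0, 2.0], [1.0, 2.0], 5.0) == 0.0
        assert nrmse([1.0, 9.0], [0.0, 10.0], 10.0) == pytest.approx(0.1)

    def test_scale_invariance(self, rng):
        pred, obs = rng.normal(size=5), rng.normal(size=5)
        assert nrmse(2 * pred, 2 * obs, 2 * 3.0) == pytest.approx(nrmse(pred, obs, 3.0))

    def test_invalid_normalizer(self):
        with pytest.raises(ValueError):
            nrmse([1.0], [1.0], 0.0)


def _split(err, idx=0):
    return SplitResult((idx,), (idx,), 0.0, 0.0, 0.5, err)


class TestSelectBestLine:
    def test_selection_rules(self):
        single = _split(0.4)
        assert select_best_line([single]) is single
        splits = [_split(e, i) for i, e in enumerate([0.1, 0.2, 0.3])]
        assert select_best_line(splits) is splits[1]  # mean 0.2
        tied = [_split(0.25, 0), _split(0.75, 1)]  # both 0.25 from mean 0.5
        assert select_best_line(tied) is tied[0]


class TestOptimismAdjustedR2:
    def test_hand_values(self):
        assert optimism_adjusted_r2(0.9, [0.9, 0.9]) == pytest.approx(0.9)
        assert optimism_adjusted_r2(0.9, [0.95, 0.85]) == pytest.approx(0.9)
        assert optimism_adjusted_r2(0.83, [1.0] * 84) == pytest.approx(0.66)


class TestValidate:
    def test_perfect_fit_limit(self):
        x = np.linspace(0, 1, 9)
        y = -40 * x + 60
        s = validate(x, y)
        assert len(s.splits) == 84
        assert s.r2_adjusted == pytest.approx(1.0)
        assert s.final_nrmse == pytest.approx(0.0, abs=1e-12)

    def test_missing_values_dropped_then_error(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan])
        y = np.arange(6.0)
        with pytest.warns(UserWarning, match="dropping"):
            s = validate(x, y, k_test=1)
        assert s.n == 5
        with pytest.raises(ValueError, match="five"):
            validate([1.0, 2, 3, np.nan], [1.0, 2, 3, 4], k_test=1)

    def test_deterministic(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=9)
        s1, s2 = validate(x, y), validate(x, y)
        assert s1.r2_adjusted == s2.r2_adjusted
        assert s1.best_line.test_ids == s2.best_line.test_ids
        assert [a.nrmse_test for a in s1.splits] == [a.nrmse_test for a in s2.splits]

    def test_full_procedure_against_brute_force(self, rng):
        """Independent reimplementation at n=5, leave-1-out, agrees to 12 s.f."""
        x, y = rng.normal(size=5), rng.normal(size=5)
        got = validate(x, y, k_test=1)
        exp = _brute_force_validation(x, y)
        assert got.r2_full == pytest.approx(exp["r2_full"], rel=1e-12)
        assert got.r2_adjusted == pytest.approx(exp["r2_adjusted"], rel=1e-12)
        assert got.mean_nrmse_test == pytest.approx(exp["mean_nrmse"], rel=1e-12)
        assert got.final_nrmse == pytest.approx(exp["final_nrmse"], rel=1e-12)
        assert got.best_line.test_ids == exp["best_test"]

    def test_permuted_outcomes_near_zero(self, rng):
        """Null relation gives small (often negative) adjusted r2."""
        vals = []
        for _ in range(40):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            vals.append(validate(x, y).r2_adjusted)
        assert abs(np.median(vals)) < 0.3


def _brute_force_validation(x, y):
    """Plain-loop re-derivation of the whole procedure (test oracle)."""
    n = len(x)
    rng_all = list(range(n))

    def ols(xs, ys):
        mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
        b = sum((a - mx) * (c - my) for a, c in zip(xs, ys)) / sum(
            (a - mx) ** 2 for a in xs
        )
        a0 = my - b * mx
        ss_res = sum((c - (b * a + a0)) ** 2 for a, c in zip(xs, ys))
        ss_tot = sum((c - my) ** 2 for c in ys)
        return b, a0, 1 - ss_res / ss_tot

    norm = max(y) - min(y)
    cells = []
    for test in combinations(rng_all, 1):
        train = [j for j in rng_all if j not in test]
        b, a0, r2 = ols([x[j] for j in train], [y[j] for j in train])
        sq = [(b * x[j] + a0 - y[j]) ** 2 for j in test]
        cells.append((test, b, a0, r2, (sum(sq) / len(sq)) ** 0.5 / norm))
    mean_nrmse = sum(c[4] for c in cells) / len(cells)
    best = min(cells, key=lambda c: abs(c[4] - mean_nrmse))
    bsq = [(best[1] * x[j] + best[2] - y[j]) ** 2 for j in rng_all]
    _, _, r2_full = ols(list(x), list(y))
    return {
        "r2_full": r2_full,
        "r2_adjusted": r2_full - sum(c[3] - r2_full for c in cells) / len(cells),
        "mean_nrmse": mean_nrmse,
        "final_nrmse": (sum(bsq) / n) ** 0.5 / norm,
        "best_test": tuple(best[0]),
    }
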