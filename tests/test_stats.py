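import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from credyn.stats import friedman, ks2, stars


# --- independent oracles -----------------------------------------------------

def friedman_q_oracle(x):
    """Tie-corrected Friedman statistic computed directly from ranks."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    ranks = np.array([sps.rankdata(row) for row in x])
    rj = ranks.sum(axis=0)
    tie = sum(
        float(np.sum(c**3 - c))
        for row in x
        for c in [np.unique(row, return_counts=True)[1]]
    )
    c = 1.0 - tie / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0, 0.0
    return (12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)) / c, c


def friedman_exact_p_oracle(x):
    """Exhaustive p over all (k!)^n within-row value permutations."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    q_obs, _ = friedman_q_oracle(x)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(perms, repeat=n):
        xp = np.array([x[i, list(p)] for i, p in enumerate(combo)])
        q, _ = friedman_q_oracle(xp)
        total += 1
        if q >= q_obs - 1e-12:
            count += 1
    return count / total


def ks_d_oracle(x, y):
    """Supremum ECDF distance evaluated over all pooled points."""
    pts = np.concatenate([x, y])
    fx = np.array([(np.asarray(x) <= p).mean() for p in pts])
    fy = np.array([(np.asarray(y) <= p).mean() for p in pts])
    return np.max(np.abs(fx - fy))


def ks_exact_p_oracle(m, n, d_obs):
    """Exhaustive p over all C(m+n, n) interleavings of tie-free samples."""
    total = 0
    count = 0
    positions = range(m + n)
    for x_pos in itertools.combinations(positions, m):
        xv = np.array(x_pos, dtype=float)
        yv = np.array(sorted(set(positions) - set(x_pos)), dtype=float)
        total += 1
        if ks_d_oracle(xv, yv) >= d_obs - 1e-12:
            count += 1
    return count / total


# --- Friedman ----------------------------------------------------------------

class TestFriedman:
    def test_fully_tied_rows(self):
        res = friedman([[1.0, 1.0, 1.0]] * 4)
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_strictly_increasing_rows_closed_form(self, n):
        """n strictly increasing rows at k=3 give Q = 2n exactly."""
        x = np.tile([1.0, 2.0, 5.0], (n, 1)) + np.arange(n)[:, None]
        res = friedman(x, exact_n_max=0)
        assert res.statistic == pytest.approx(2 * n)
        assert res.df == 2

    def test_exact_p_matches_enumeration(self, rng):
        """Exact path vs exhaustive (k!)^n permutation oracle, n <= 4, k = 3."""
        for trial in range(25):
            n = int(rng.integers(2, 5))
            x = np.round(rng.random((n, 3)) * 4, 1)  # rounding induces ties
            res = friedman(x)
            assert res.method == "friedman_exact"
            assert res.p_value == pytest.approx(friedman_exact_p_oracle(x))

    def test_chi2_path_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.random((15, 3))
            res = friedman(x)
            ref = sps.friedmanchisquare(*x.T)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_statistic_matches_scipy_under_ties(self, rng):
        x = np.round(rng.random((12, 4)) * 3)
        res = friedman(x, exact_n_max=0)
        ref = sps.friedmanchisquare(*x.T)
        assert res.statistic == pytest.approx(ref.statistic)

    def test_monotone_transform_invariance(self, rng):
        x = rng.random((8, 3))
        a = friedman(x)
        b = friedman(np.exp(3 * x) + 7)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_null_rejection_rate(self, rng):
        """Type-I error at alpha=0.05 within 3 MC SDs over null datasets."""
        n_sim = 4000
        rejections = 0
        for _ in range(n_sim):
            x = rng.random((20, 3))
            if friedman(x).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sim
        sd = math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 3 * sd

    def test_input_validation(self):
        with pytest.raises(ValueError):
            friedman([[1.0, 2.0]])
        with pytest.raises(ValueError):
            friedman(np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            friedman([[1.0, np.nan, 2.0], [1.0, 2.0, 3.0]])


# --- Kolmogorov-Smirnov ------------------------------------------------------

class TestKS:
    def test_identical_samples(self):
        res = ks2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_disjoint_support(self):
        res = ks2([1.0, 2.0], [5.0, 6.0, 7.0])
        assert res.statistic == 1.0

    def test_exact_p_matches_enumeration(self, rng):
        """Exact path vs full-interleaving oracle for all m, n <= 6."""
        for m in range(1, 7):
            for n in range(1, 7):
                x = rng.random(m)
                y = rng.random(n)
                res = ks2(x, y)
                assert res.method == "ks_exact"
                assert res.statistic == pytest.approx(ks_d_oracle(x, y))
                assert res.p_value == pytest.approx(ks_exact_p_oracle(m, n, res.statistic))

    def test_exact_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.random(int(rng.integers(2, 9)))
            y = rng.random(int(rng.integers(2, 9)))
            res = ks2(x, y)
            ref = sps.ks_2samp(x, y, method="exact")
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_asymptotic_path_used_for_large_samples(self, rng):
        x, y = rng.random(40), rng.random(50)
        res = ks2(x, y)
        assert res.method == "ks_asymptotic"
        ref = sps.ks_2samp(x, y, method="asymp")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)

    def test_ties_force_asymptotic_fallback(self):
        res = ks2([1.0, 2.0, 3.0], [2.0, 4.0])
        assert res.method == "ks_asymptotic"

    def test_invariance_under_increasing_transform(self, rng):
        x, y = rng.random(8), rng.random(5)
        a = ks2(x, y)
        b = ks2(np.exp(x), np.exp(y))
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks2([], [1.0])


# --- stars --------------------------------------------------------------------

class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.04, "*"), (0.05, "ns"), (0.2, "ns"), (0.009, "**"),
            (0.01, "*"), (0.0009, "***"), (5e-5, "****"), (1e-4, "***"),
            (0.0, "****"), (1.0, "ns"),
        ],
    )
    def test_thresholds_strict(self, p, expected):
        assert stars(p) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            stars(1.5)
        with pytest.raises(ValueError):
            stars(-0.1)
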