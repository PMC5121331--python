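"""eCDF convolution, bootstrap bands, mDD binning, and the equality test."""

import numpy as np
import pytest

import clonedd as cd
from clonedd.addition import CategoricalCounts


# ---------------------------------------------------------------------------
# eCDF and convolution
# ---------------------------------------------------------------------------

def test_ecdf_examples():
    F = cd.ecdf([2, 2, 4])
    assert F.support.tolist() == [2, 4]
    assert F.cdf.tolist() == pytest.approx([2 / 3, 1.0])
    assert cd.ecdf([5]).evaluate([4.9, 5.0, 6.0]).tolist() == [0.0, 1.0, 1.0]
    F = cd.ecdf([1, 2, 3, 4])
    assert F.cdf.tolist() == pytest.approx([0.25, 0.5, 0.75, 1.0])
    with pytest.raises(ValueError):
        cd.ecdf([])


def test_convolve_ecdf_examples():
    FG = cd.convolve_ecdf(cd.ecdf([1]), cd.ecdf([2]))
    assert FG.support.tolist() == [3] and FG.cdf.tolist() == [1.0]
    FG = cd.convolve_ecdf(cd.ecdf([0, 1]), cd.ecdf([0, 1]))
    assert FG.support.tolist() == [0, 1, 2]
    assert FG.cdf.tolist() == pytest.approx([0.25, 0.75, 1.0])


def test_convolve_ecdf_matches_bruteforce(rng):
    """MLE convolution equals the eCDF of all pairwise sums, exactly."""
    for _ in range(25):
        x = rng.integers(0, 8, size=rng.integers(1, 30)).astype(float)
        y = np.round(rng.normal(size=rng.integers(1, 30)), 3)
        conv = cd.convolve_ecdf(cd.ecdf(x), cd.ecdf(y))
        brute = cd.ecdf((x[:, None] + y[None, :]).ravel())
        assert np.array_equal(conv.support, brute.support)
        assert np.array_equal(conv.weights, brute.weights)


# ---------------------------------------------------------------------------
# Bootstrap band
# ---------------------------------------------------------------------------

def test_bootstrap_band_degenerate_and_deterministic():
    grid, lo, hi = cd.bootstrap_sum_band([3.0] * 10, [2.0] * 8, K=200, seed=0)
    assert np.array_equal(lo, hi) and lo.tolist() == [1.0]

    x = [2, 3, 3, 4, 5]
    y = [1, 1, 2, 4]
    g1, l1, u1 = cd.bootstrap_sum_band(x, y, K=200, seed=11)
    g2, l2, u2 = cd.bootstrap_sum_band(x, y, K=200, seed=11)
    assert np.array_equal(l1, l2) and np.array_equal(u1, u2)
    assert np.all(l1 <= u1)
    assert np.all(np.diff(l1) >= 0) and np.all(np.diff(u1) >= 0)
    with pytest.raises(ValueError):
        cd.bootstrap_sum_band(x, y, K=10)


def test_bootstrap_band_covers_truth(rng):
    """Pointwise coverage of the true CDF at the median under resampling
    from the true model is near nominal."""
    hits = 0
    reps = 120
    for _ in range(reps):
        x = rng.integers(0, 3, 40)   # uniform on {0,1,2}
        y = rng.integers(0, 3, 40)
        grid, lo, hi = cd.bootstrap_sum_band(x, y, K=300, seed=rng)
        # true CDF of the sum at z=2: P(X+Y<=2)=6/9*... enumerate
        truth = np.mean([(a + b) <= 2 for a in range(3) for b in range(3)])
        i = np.searchsorted(grid, 2)
        hits += lo[i] <= truth <= hi[i]
    assert 0.85 <= hits / reps <= 1.0


# ---------------------------------------------------------------------------
# mDD binning
# ---------------------------------------------------------------------------

def test_bin_mdd_examples():
    c = cd.bin_mdd([3.0, 3.5, 8.2])
    as_dict = dict(zip(c.categories, c.counts))
    assert as_dict["{3}"] == 1
    assert as_dict["(3,4)"] == 1
    assert as_dict["[7,inf)"] == 1
    assert len(c.categories) == 11


def test_bin_mdd_underflow_flagged():
    with pytest.warns(UserWarning, match="underflow"):
        c = cd.bin_mdd([1.5, 3.0])
    assert c.categories[0] == "[0,2)!"
    assert c.counts[0] == 1


# ---------------------------------------------------------------------------
# Category projection
# ---------------------------------------------------------------------------

def test_projection_identity_when_populated():
    e = np.array([20.0, 30.0, 25.0])
    P = cd.project_to_common_categories(e, e, 5.0)
    assert np.array_equal(P, np.eye(3))
    P = cd.project_to_common_categories(e, e, 0.0)
    assert np.array_equal(P, np.eye(3))


def test_projection_merges_sparse_tail():
    e1 = np.array([30.0, 40.0, 1.0])
    e2 = np.array([30.0, 35.0, 2.0])
    P = cd.project_to_common_categories(e1, e2, 5.0)
    assert P.shape == (2, 3)
    assert P[1].tolist() == [0.0, 1.0, 1.0]   # tail folded into neighbour


def test_projection_too_sparse_errors():
    with pytest.raises(ValueError):
        cd.project_to_common_categories([1.0, 1.0], [1.0, 1.0], 5.0)


# ---------------------------------------------------------------------------
# Convolution equality test
# ---------------------------------------------------------------------------

def _counts(vals, cats=tuple("abcd")):
    return CategoricalCounts(cats, np.asarray(vals))


def test_identical_counts_give_p_one():
    X = _counts([30, 60, 40, 20])
    Y = _counts([40, 50, 40, 20])
    res = cd.convolution_equality_test(X, Y, X, Y)
    assert res.statistic == pytest.approx(0.0, abs=1e-20)
    assert res.p_value == 1.0


def test_pair_swap_symmetry(rng):
    """With equal sample sizes, swapping which pair is called (X,Y) leaves
    the statistic unchanged."""
    X = _counts(rng.multinomial(200, [0.2, 0.3, 0.3, 0.2]))
    Y = _counts(rng.multinomial(200, [0.4, 0.3, 0.2, 0.1]))
    A = _counts(rng.multinomial(200, [0.25, 0.25, 0.3, 0.2]))
    B = _counts(rng.multinomial(200, [0.3, 0.3, 0.2, 0.2]))
    r1 = cd.convolution_equality_test(X, Y, A, B)
    r2 = cd.convolution_equality_test(A, B, X, Y)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)


def test_incompatible_categories_error():
    X = _counts([10, 10, 10, 10])
    Z = CategoricalCounts(("a", "b"), np.array([10, 10]))
    with pytest.raises(ValueError):
        cd.convolution_equality_test(X, Z, X, Z)


def test_detects_shifted_distribution(rng):
    x = np.array([0.15, 0.45, 0.3, 0.1])
    y = np.array([0.25, 0.4, 0.25, 0.1])
    a = np.roll(x, 1)
    res = cd.convolution_equality_test(
        _counts(rng.multinomial(400, x)),
        _counts(rng.multinomial(400, y)),
        _counts(rng.multinomial(400, a)),
        _counts(rng.multinomial(400, y)),
    )
    assert res.p_value < 0.01


def test_power_monotone_in_sample_size(rng):
    """Rejection rate against a fixed alternative does not decrease along
    n = 50, 100, 200, 400."""
    x = np.array([0.15, 0.45, 0.3, 0.1])
    y = np.array([0.25, 0.4, 0.25, 0.1])
    a = np.array([0.3, 0.3, 0.25, 0.15])
    rates = []
    for n in (50, 100, 200, 400):
        rej = 0
        for _ in range(60):
            res = cd.convolution_equality_test(
                _counts(rng.multinomial(n, x)),
                _counts(rng.multinomial(n, y)),
                _counts(rng.multinomial(n, a)),
                _counts(rng.multinomial(n, y)),
            )
            rej += res.p_value < 0.05
        rates.append(rej / 60)
    assert all(b >= a - 0.15 for a, b in zip(rates, rates[1:]))
    assert rates[-1] > rates[0]
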