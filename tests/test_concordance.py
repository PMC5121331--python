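"""Beta-binomial family model: profile, likelihoods, range law, rho MLE."""

import numpy as np
import pytest
from scipy import integrate, stats

import clonedd as cd
from clonedd.concordance import FullTreeCounts


# ---------------------------------------------------------------------------
# Progression profile
# ---------------------------------------------------------------------------

def test_profile_examples():
    assert cd.estimate_progression_profile([0, 0, 8]).p == (1.0, 1.0, 0.0)
    assert cd.estimate_progression_profile([1, 0], 1).p == (0.0, 0.0)
    p = cd.estimate_progression_profile([0, 1, 2])
    assert p.p[1] == pytest.approx(0.5)   # (2/4) / (1/2 + 2/4)
    assert p.p[-1] == 0.0


def test_profile_errors():
    with pytest.raises(ValueError):
        cd.estimate_progression_profile([0, 0, 0])
    with pytest.raises(ValueError):
        cd.estimate_progression_profile([0, 0, 8], max_depth=1)


def test_profile_recovered_from_simulation(rng):
    """Pooled per-generation DD proportions reproduce the input profile
    irrespective of the family correlation."""
    profile = cd.dd_distribution_to_profile([0, 0.1, 0.3, 0.4, 0.2])
    for rho in (0.0, 0.9):
        trees = cd.simulate_full_trees(profile, rho, 100_000, rng)
        pooled = trees.sum(axis=0)
        est = cd.estimate_progression_profile(pooled, profile.max_depth)
        assert np.allclose(est.p[:-1], profile.p[:-1], rtol=0.02, atol=0.005)


# ---------------------------------------------------------------------------
# Beta-binomial pmf
# ---------------------------------------------------------------------------

def test_betabinom_limits():
    assert cd.betabinom_pmf(2, 1, 0.5, 0.0) == pytest.approx(0.5)
    assert cd.betabinom_pmf(3, 3, 0.7, 1.0) == pytest.approx(0.7)
    assert cd.betabinom_pmf(3, 0, 0.7, 1.0) == pytest.approx(0.3)
    assert cd.betabinom_pmf(3, 2, 0.7, 1.0) == 0.0


def test_betabinom_quadrature_oracle():
    """Mass at (n=2, k=0, p=0.5, rho=0.5) equals the Beta-mixture integral."""
    a = b = 0.5 * (1 - 0.5) / 0.5
    oracle, _ = integrate.quad(
        lambda q: stats.binom.pmf(0, 2, q) * stats.beta.pdf(q, a, b), 0, 1
    )
    assert cd.betabinom_pmf(2, 0, 0.5, 0.5) == pytest.approx(oracle, rel=1e-6)


def test_betabinom_validation():
    with pytest.raises(ValueError):
        cd.betabinom_pmf(2, 3, 0.5, 0.0)
    with pytest.raises(ValueError):
        cd.betabinom_pmf(2, 1, 1.5, 0.0)
    with pytest.raises(ValueError):
        cd.betabinom_pmf(2, 1, 0.5, -0.1)


def test_betabinom_pairwise_correlation(rng):
    """The intraclass correlation of the mixing construction is exactly rho."""
    n, p, rho = 2, 0.6, 0.35
    ks = np.arange(n + 1)
    pmf = np.array([cd.betabinom_pmf(n, k, p, rho) for k in ks])
    mean = (ks * pmf).sum()
    var = ((ks - mean) ** 2 * pmf).sum()
    # var of sum of 2 exchangeable Bernoullis: 2p(1-p)(1 + rho)
    assert var == pytest.approx(2 * p * (1 - p) * (1 + rho), rel=1e-9)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

def test_enumeration_examples():
    assert [t.t for t in cd.enumerate_full_trees(0)] == [(1,)]
    assert sorted(t.t for t in cd.enumerate_full_trees(1)) == [(0, 2), (1, 0)]
    assert sorted(t.t for t in cd.enumerate_full_trees(2)) == [
        (0, 0, 4), (0, 1, 2), (0, 2, 0), (1, 0, 0)
    ]


def test_enumeration_valid_and_unique():
    trees = cd.enumerate_full_trees(4)
    seen = {t.t for t in trees}
    assert len(seen) == len(trees) == 36
    for t in trees:
        assert cd.cohort_mass(t.t) == 1


def test_enumeration_depth_guard():
    with pytest.raises(ValueError):
        cd.enumerate_full_trees(9)
    with pytest.raises(ValueError):
        cd.enumerate_full_trees(-1)


def test_full_tree_counts_invariants():
    with pytest.raises(ValueError):
        FullTreeCounts((0, 3))        # t_1 > c_1
    with pytest.raises(ValueError):
        FullTreeCounts((0, 1))        # does not terminate
    t = FullTreeCounts((0, 1, 2))
    assert t.cells == (1, 2, 2)
    assert t.n_cells == 3


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def test_full_tree_likelihood_examples():
    m0 = cd.ConcordanceModel(cd.ProgressionProfile((0.0,)), 0.3)
    assert cd.full_tree_likelihood(FullTreeCounts((1,)), m0) == pytest.approx(1.0)
    m1 = cd.ConcordanceModel(cd.ProgressionProfile((1.0, 0.0)), 0.7)
    assert cd.full_tree_likelihood(FullTreeCounts((0, 2)), m1) == pytest.approx(1.0)
    m2 = cd.ConcordanceModel(cd.ProgressionProfile((0.5, 0.5, 0.0)), 0.0)
    assert cd.full_tree_likelihood(FullTreeCounts((0, 1, 2)), m2) == pytest.approx(0.25)


def test_likelihood_normalization_random_models(rng):
    for D in (2, 3, 4):
        trees = cd.enumerate_full_trees(D)
        for _ in range(5):
            p = tuple(rng.random(D)) + (0.0,)
            model = cd.ConcordanceModel(cd.ProgressionProfile(p), rng.random())
            total = sum(cd.full_tree_likelihood(t, model) for t in trees)
            assert total == pytest.approx(1.0, abs=1e-9)


def test_subtree_sampling_likelihood():
    assert cd.subtree_sampling_likelihood(
        (0, 2), FullTreeCounts((0, 2)), 1.0
    ) == pytest.approx(1.0)
    assert cd.subtree_sampling_likelihood(
        (0, 1), FullTreeCounts((0, 2)), 0.5
    ) == pytest.approx(0.5)
    assert cd.subtree_sampling_likelihood(
        (0, 0, 0), FullTreeCounts((0, 0, 4)), 0.5
    ) == pytest.approx(0.0625)
    with pytest.raises(ValueError):
        cd.subtree_sampling_likelihood((0, 3), FullTreeCounts((0, 2)), 0.5)


# ---------------------------------------------------------------------------
# Range distribution
# ---------------------------------------------------------------------------

def test_range_distribution_examples():
    prof2 = cd.ProgressionProfile((0.5, 0.5, 0.0))
    assert cd.range_distribution(cd.ConcordanceModel(prof2, 1.0, 1.0))[0] == pytest.approx(1.0)
    prof1 = cd.ProgressionProfile((0.5, 0.0))
    assert cd.range_distribution(cd.ConcordanceModel(prof1, 0.0, 1.0))[0] == pytest.approx(1.0)
    d = cd.range_distribution(cd.ConcordanceModel(prof2, 0.0, 1.0))
    assert d[1] == pytest.approx(0.25)  # only tree (0,1,2) has range 1


def test_range_distribution_normalized(rng):
    for _ in range(5):
        p = tuple(rng.random(4)) + (0.0,)
        model = cd.ConcordanceModel(
            cd.ProgressionProfile(p), rng.random(), 0.3 + 0.7 * rng.random()
        )
        d = cd.range_distribution(model)
        assert sum(d.prob.values()) == pytest.approx(1.0, abs=1e-9)


def test_range_concordance_monotone_in_rho():
    prof = cd.dd_distribution_to_profile([0, 0.1, 0.3, 0.4, 0.2])
    p0 = [
        cd.range_distribution(cd.ConcordanceModel(prof, rho, 0.6))[0]
        for rho in np.linspace(0, 1, 11)
    ]
    assert np.all(np.diff(p0) >= -1e-12)


def test_range_distribution_ci():
    prof1 = cd.ProgressionProfile((0.5, 0.0))
    sure = cd.range_distribution_ci(cd.ConcordanceModel(prof1, 0.0, 1.0), 50)
    assert sure.ci[0] == (1.0, 1.0)

    # P(0)=0.5 engineered: rho=1 coin flip between depth-0 and depth-1 trees
    # gives all-concordant clones, so use binomial quantiles directly instead
    lo, hi = stats.binom.ppf([0.025, 0.975], 100, 0.5) / 100
    assert (lo, hi) == pytest.approx((0.40, 0.60), abs=0.01)

    one = cd.range_distribution_ci(cd.ConcordanceModel(prof1, 0.0, 1.0), 1)
    for f, (a, b) in one.ci.items():
        assert 0.0 <= a <= b <= 1.0
    with pytest.raises(ValueError):
        cd.range_distribution_ci(cd.ConcordanceModel(prof1, 0.0, 1.0), 0)


# ---------------------------------------------------------------------------
# rho fitting
# ---------------------------------------------------------------------------

def test_fit_rho_concordant_data_hits_boundary(rng):
    profile = cd.dd_distribution_to_profile([0, 0, 0.3, 0.4, 0.3])
    trees = cd.simulate_full_trees(profile, 1.0, 100, rng)
    fit = cd.fit_rho(list(trees), profile, 1.0)
    assert fit.rho_hat == 1.0


def test_fit_rho_independent_data_near_zero(rng):
    profile = cd.dd_distribution_to_profile([0, 0.1, 0.4, 0.3, 0.2])
    trees = cd.simulate_full_trees(profile, 0.0, 500, rng)
    fit = cd.fit_rho(list(trees), profile, 1.0)
    assert fit.rho_hat < 0.2


def test_fit_rho_range_statistic_variant(rng):
    profile = cd.dd_distribution_to_profile([0, 0, 0.3, 0.4, 0.3])
    trees = cd.simulate_full_trees(profile, 0.9, 150, rng)
    s = rng.binomial(trees, 0.7)
    obs = [row for row in s if row.sum() > 0]
    full = cd.fit_rho(obs, profile, 0.7, statistic="counts")
    coarse = cd.fit_rho(obs, profile, 0.7, statistic="range")
    assert 0.5 <= full.rho_hat <= 1.0
    assert 0.3 <= coarse.rho_hat <= 1.0   # coarser statistic, looser estimate


def test_fit_rho_errors():
    profile = cd.ProgressionProfile((0.5, 0.0))
    with pytest.raises(ValueError):
        cd.fit_rho([], profile, 0.5)
    with pytest.raises(ValueError):
        cd.fit_rho([(0, 0)], profile, 0.5)
    with pytest.raises(ValueError):
        cd.fit_rho([(0, 2)], profile, 1.5)
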