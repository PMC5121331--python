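"""Beta-binomial correlated family division-destiny model.

The model: a founder (generation 0) gives rise to a binary-division family
tree.  Of the ``c_k`` cells alive in generation k, the number progressing
past k (rather than taking division destiny there) is beta-binomially
distributed with per-generation progression probability ``p_k`` and a
within-family pairwise correlation ``rho`` in [0,1].  ``rho = 0`` recovers
independent binomial fate decisions; ``rho = 1`` means the whole family
shares a single decision per generation.  Whatever ``rho``, the pooled
per-generation progression proportions across many families equal the
``p_k`` profile, so the profile is estimated directly from pooled data
(cohort-corrected) and ``rho`` alone is fitted by maximum likelihood.

Observed clones are binomially thinned versions of full trees: each DD
cell is recovered independently with a per-condition probability ``r``.
The model therefore predicts the distribution of the clonal *range*
(max minus min occupied generation of the recovered cells), the statistic
used to quantify familial concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "ProgressionProfile",
    "FullTreeCounts",
    "ConcordanceModel",
    "RangeDistribution",
    "RhoFit",
    "estimate_progression_profile",
    "betabinom_pmf",
    "enumerate_full_trees",
    "full_tree_likelihood",
    "subtree_sampling_likelihood",
    "range_distribution",
    "range_distribution_ci",
    "fit_rho",
]

MAX_ENUMERATION_DEPTH = 8


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProgressionProfile:
    """Per-generation progression probabilities ``p_k``.

    ``p[k]`` is the probability that a cell in generation k progresses past
    k instead of taking DD there; the final entry is 0 (all cells stop by
    the maximal depth D = len(p) - 1).
    """

    p: tuple[float, ...]

    def __post_init__(self):
        p = tuple(float(v) for v in self.p)
        if len(p) == 0:
            raise ValueError("profile must have at least one entry")
        if any(not (0.0 <= v <= 1.0) for v in p):
            raise ValueError("progression probabilities must lie in [0,1]")
        if p[-1] != 0.0:
            raise ValueError("final progression probability must be 0")
        object.__setattr__(self, "p", p)

    @property
    def max_depth(self) -> int:
        return len(self.p) - 1


@dataclass(frozen=True)
class FullTreeCounts:
    """A fully observed family tree summarized by DD counts per generation.

    ``t[i]`` is the number of cells taking DD in generation i; the alive
    counts follow ``c_0 = 1``, ``c_{i+1} = 2 (c_i - t_i)`` and the tree
    terminates (``c_{D+1} = 0``).  The cohort mass ``sum t_i 2^{-i}`` of
    any such tree is exactly 1.
    """

    t: tuple[int, ...]

    def __post_init__(self):
        t = tuple(int(v) for v in self.t)
        object.__setattr__(self, "t", t)
        c = 1
        for v in t:
            if not 0 <= v <= c:
                raise ValueError(f"inconsistent DD counts {t}")
            c = 2 * (c - v)
        if c != 0:
            raise ValueError(f"tree {t} does not terminate by depth {len(t) - 1}")

    @property
    def cells(self) -> tuple[int, ...]:
        """Alive counts ``c_i`` per generation."""
        out, c = [], 1
        for v in self.t:
            out.append(c)
            c = 2 * (c - v)
        return tuple(out)

    @property
    def n_cells(self) -> int:
        return sum(self.t)


@dataclass(frozen=True)
class ConcordanceModel:
    """Progression profile + within-family correlation + recovery probability."""

    profile: ProgressionProfile
    rho: float
    r: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0,1]")
        if not 0.0 < self.r <= 1.0:
            raise ValueError("sampling probability r must lie in (0,1]")


@dataclass
class RangeDistribution:
    """Probability of each clonal range value, with optional 95% CIs."""

    prob: dict[int, float]
    ci: dict[int, tuple[float, float]] | None = None

    def __post_init__(self):
        total = sum(self.prob.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"range probabilities sum to {total}, not 1")

    def __getitem__(self, f: int) -> float:
        return self.prob.get(f, 0.0)


@dataclass
class RhoFit:
    """Maximum-likelihood fit of the within-family DD correlation."""

    rho_hat: float
    grid: np.ndarray
    loglik: np.ndarray
    n_clones: int
    statistic: str = "counts"


# ---------------------------------------------------------------------------
# Progression profile from pooled data
# ---------------------------------------------------------------------------

def estimate_progression_profile(
    pooled_dd_counts: Sequence[float], max_depth: int | None = None
) -> ProgressionProfile:
    """Estimate ``p_k`` from pooled per-generation DD cell counts.

    With cohort-corrected counts ``w_j = n_j 2^{-j}``,

        p_k = sum_{j>k} w_j / sum_{j>=k} w_j,

    the conditional probability of progressing past generation k given
    arrival there.  This pooled estimator is invariant to the value of the
    within-family correlation.
    """
    n = np.asarray(pooled_dd_counts, dtype=float)
    if n.ndim != 1 or n.size == 0 or np.any(n < 0):
        raise ValueError("pooled counts must be a non-empty non-negative vector")
    if not np.any(n > 0):
        raise ValueError("pooled DD counts are all zero")
    if max_depth is None:
        max_depth = int(np.nonzero(n)[0][-1])
    if max_depth < int(np.nonzero(n)[0][-1]):
        raise ValueError("max_depth below the highest occupied generation")
    w = np.zeros(max_depth + 1)
    w[: n.size] = n / 2.0 ** np.arange(n.size)
    tail = np.cumsum(w[::-1])[::-1]  # tail[k] = sum_{j>=k} w_j
    p = np.zeros(max_depth + 1)
    for k in range(max_depth):
        p[k] = (tail[k + 1] / tail[k]) if tail[k] > 0 else 0.0
    return ProgressionProfile(tuple(p))


# ---------------------------------------------------------------------------
# Beta-binomial
# ---------------------------------------------------------------------------

def betabinom_pmf(n: int, k: int, p: float, rho: float) -> float:
    """Beta-binomial pmf with mean ``n p`` and pairwise correlation ``rho``.

    Parameterized by the Beta(a, b) mixing density with
    ``a = p (1-rho)/rho``, ``b = (1-p)(1-rho)/rho`` so the intraclass
    correlation is exactly ``rho``.  ``rho = 0`` is the binomial limit;
    ``rho = 1`` the shared-decision two-point law (k = n w.p. p, else 0).
    """
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    if not (0.0 <= p <= 1.0 and 0.0 <= rho <= 1.0):
        raise ValueError("p and rho must lie in [0,1]")
    return float(_betabinom_pmf_vec(np.array([n]), np.array([k]), p, rho)[0])


def _betabinom_pmf_vec(
    n: np.ndarray, k: np.ndarray, p: float, rho: float
) -> np.ndarray:
    """Vectorized beta-binomial pmf; n == 0 contributes pmf 1 at k == 0."""
    n = np.asarray(n, dtype=np.int64)
    k = np.asarray(k, dtype=np.int64)
    out = np.zeros(np.broadcast(n, k).shape, dtype=float)
    n, k = np.broadcast_arrays(n, k)
    empty = n == 0
    out[empty & (k == 0)] = 1.0
    live = ~empty
    if not live.any():
        return out
    nl, kl = n[live], k[live]
    if p == 0.0:
        vals = (kl == 0).astype(float)
    elif p == 1.0:
        vals = (kl == nl).astype(float)
    elif rho == 0.0:
        vals = stats.binom.pmf(kl, nl, p)
    elif rho == 1.0:
        vals = np.where(kl == nl, p, 0.0) + np.where(kl == 0, 1.0 - p, 0.0)
    else:
        a = p * (1.0 - rho) / rho
        b = (1.0 - p) * (1.0 - rho) / rho
        vals = stats.betabinom.pmf(kl, nl, a, b)
    out[live] = vals
    return out


# ---------------------------------------------------------------------------
# Tree enumeration and likelihoods
# ---------------------------------------------------------------------------

_TREE_CACHE: dict[int, np.ndarray] = {}


def _enumerate_tree_array(D: int) -> np.ndarray:
    """All DD-count vectors (t_0..t_D) of full trees of depth <= D, as an
    (n_trees, D+1) integer array.  Cached per D."""
    if D in _TREE_CACHE:
        return _TREE_CACHE[D]

    rows: list[tuple[int, ...]] = []

    def recurse(prefix: list[int], c: int, depth: int) -> None:
        if depth == D:
            rows.append(tuple(prefix + [c]))  # all remaining cells stop
            return
        if c == 0:
            rows.append(tuple(prefix + [0] * (D - depth + 1)))
            return
        for t in range(c + 1):
            recurse(prefix + [t], 2 * (c - t), depth + 1)

    recurse([], 1, 0)
    arr = np.array(rows, dtype=np.int64)
    _TREE_CACHE[D] = arr
    return arr


def enumerate_full_trees(D: int) -> list[FullTreeCounts]:
    """Brute-force enumeration of every full tree of depth at most D.

    Vectors are padded with trailing zeros to length D+1.  Depths above
    8 are rejected: the enumeration grows combinatorially.
    """
    if D < 0:
        raise ValueError("depth must be non-negative")
    if D > MAX_ENUMERATION_DEPTH:
        raise ValueError(
            f"enumeration depth {D} > {MAX_ENUMERATION_DEPTH}: "
            "the full-tree space explodes combinatorially"
        )
    return [FullTreeCounts(tuple(row)) for row in _enumerate_tree_array(D)]


def _tree_cells(trees: np.ndarray) -> np.ndarray:
    """Alive counts c_i for an array of tree DD-count rows."""
    n, width = trees.shape
    c = np.zeros_like(trees)
    c[:, 0] = 1
    for i in range(width - 1):
        c[:, i + 1] = 2 * (c[:, i] - trees[:, i])
    return c


def _tree_likelihoods(trees: np.ndarray, profile: ProgressionProfile, rho: float) -> np.ndarray:
    """Likelihood of each tree row: product over generations of the
    beta-binomial probability that c_i - t_i of c_i cells progress."""
    D = profile.max_depth
    if trees.shape[1] != D + 1:
        raise ValueError("tree array width does not match profile depth")
    c = _tree_cells(trees)
    lik = np.ones(trees.shape[0])
    for i in range(D + 1):
        lik *= _betabinom_pmf_vec(c[:, i], c[:, i] - trees[:, i], profile.p[i], rho)
    return lik


def full_tree_likelihood(tree: FullTreeCounts, model: ConcordanceModel) -> float:
    """Probability of a full tree under the correlated progression model.

    At each generation i, the number of the ``c_i`` alive cells that
    progress past i is beta-binomial(c_i, p_i, rho); the tree likelihood is
    the product of these terms, and likelihoods over all full trees of the
    profile's depth sum to 1.
    """
    D = model.profile.max_depth
    t = np.zeros(D + 1, dtype=np.int64)
    if len(tree.t) > D + 1 and any(tree.t[D + 1 :]):
        raise ValueError("tree deeper than the model's profile")
    t[: min(len(tree.t), D + 1)] = tree.t[: D + 1]
    return float(_tree_likelihoods(t[None, :], model.profile, model.rho)[0])


def subtree_sampling_likelihood(
    s: Sequence[int], tree: FullTreeCounts, r: float
) -> float:
    """Binomial-thinning likelihood of an observed subtree.

    Each DD cell of the full tree is recovered independently w.p. ``r``:
    ``prod_i C(t_i, s_i) r^{s_i} (1-r)^{t_i - s_i}``.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("sampling probability r must lie in (0,1]")
    s = np.asarray(s, dtype=np.int64)
    t = np.zeros(max(s.size, len(tree.t)), dtype=np.int64)
    t[: len(tree.t)] = tree.t
    s_full = np.zeros_like(t)
    s_full[: s.size] = s
    if np.any(s_full < 0) or np.any(s_full > t):
        raise ValueError("observed counts exceed the full tree's DD counts")
    return float(np.prod(stats.binom.pmf(s_full, t, r)))


# ---------------------------------------------------------------------------
# Range distribution
# ---------------------------------------------------------------------------

def range_distribution(model: ConcordanceModel, D: int | None = None) -> RangeDistribution:
    """Distribution of the clonal range of a sampled (non-empty) subtree.

    Marginalizes the double sum over full trees T and subtrees S of T:
    per tree, sampling is independent across cells, so the probability that
    the recovered cells' minimum and maximum occupied generations are
    (a, b) factorizes over generations through the occupancy probabilities
    ``1 - (1-r)^{t_i}``.  Mass is conditioned on a non-empty recovered
    subtree (clones with no detected progeny are unobservable).
    """
    if D is None:
        D = model.profile.max_depth
    if D != model.profile.max_depth:
        raise ValueError("D must equal the profile's max depth")
    trees = _enumerate_tree_array(D)
    lik = _tree_likelihoods(trees, model.profile, model.rho)
    r = model.r
    miss = (1.0 - r) ** trees  # per-generation all-missed probability
    occ = 1.0 - miss
    # prefix products of miss: left[:, a] = prod_{i<a} miss_i
    width = D + 1
    left = np.ones((trees.shape[0], width + 1))
    np.cumprod(miss, axis=1, out=left[:, 1:])
    right = np.ones((trees.shape[0], width + 1))
    right[:, :-1] = np.cumprod(miss[:, ::-1], axis=1)[:, ::-1]
    # right[:, b+1] = prod_{i>b} miss_i
    prob = np.zeros(width)
    for a in range(width):
        # min = max = a
        outside = left[:, a] * right[:, a + 1]
        prob[0] += float(lik @ (outside * occ[:, a]))
        for b in range(a + 1, width):
            outside = left[:, a] * right[:, b + 1]
            prob[b - a] += float(lik @ (outside * occ[:, a] * occ[:, b]))
    p_empty = float(lik @ left[:, width])
    prob /= 1.0 - p_empty
    return RangeDistribution({f: float(prob[f]) for f in range(width)})


def range_distribution_ci(
    model: ConcordanceModel,
    n_families: int,
    level: float = 0.95,
    D: int | None = None,
) -> RangeDistribution:
    """Model range distribution with finite-sample binomial envelopes.

    For each range value f, the CI is the ``level`` central interval of
    ``Binomial(n_families, P(f)) / n_families`` — the sampling variability
    of an empirical range frequency from the number of families actually
    recovered.
    """
    if n_families < 1:
        raise ValueError("need at least one recovered family")
    dist = range_distribution(model, D)
    alpha = (1.0 - level) / 2.0
    ci = {}
    for f, p in dist.prob.items():
        lo = stats.binom.ppf(alpha, n_families, p) / n_families
        hi = stats.binom.ppf(1.0 - alpha, n_families, p) / n_families
        ci[f] = (float(lo), float(hi))
    return RangeDistribution(dist.prob, ci)


# ---------------------------------------------------------------------------
# rho maximum likelihood
# ---------------------------------------------------------------------------

def _observed_matrix(observed: Sequence[Sequence[int]], D: int) -> np.ndarray:
    obs = np.zeros((len(observed), D + 1), dtype=np.int64)
    for i, s in enumerate(observed):
        s = np.asarray(s, dtype=np.int64)
        if np.any(s < 0):
            raise ValueError("observed DD counts must be non-negative")
        if s.size > D + 1 and np.any(s[D + 1 :] > 0):
            raise ValueError(
                f"observed clone occupies generations beyond depth {D}"
            )
        obs[i, : min(s.size, D + 1)] = s[: D + 1]
    if not np.all(obs.sum(axis=1) > 0):
        raise ValueError("every observed clone must have at least one cell")
    return obs


def _sampling_matrix(obs: np.ndarray, trees: np.ndarray, r: float) -> np.ndarray:
    """M[c, T] = likelihood of clone c's counts as a binomial thinning of
    tree T (0 where the clone cannot be a subtree of T)."""
    n_clones = obs.shape[0]
    n_trees = trees.shape[0]
    M = np.zeros((n_clones, n_trees))
    log1mr = math.log1p(-r) if r < 1.0 else -math.inf
    tree_tot = trees.sum(axis=1)
    for c in range(n_clones):
        s = obs[c]
        feasible = np.all(trees >= s[None, :], axis=1)
        if not feasible.any():
            continue
        sub = trees[feasible]
        combs = special.comb(sub, s[None, :])
        log_comb = np.log(combs).sum(axis=1)
        k = int(s.sum())
        if r < 1.0:
            loglik = log_comb + k * math.log(r) + (tree_tot[feasible] - k) * log1mr
        else:
            exact = tree_tot[feasible] == k
            loglik = np.where(exact, log_comb, -np.inf)
        M[c, feasible] = np.exp(loglik)
    return M


def _range_probability_table(
    trees: np.ndarray, lik: np.ndarray, r: float, width: int
) -> np.ndarray:
    """P(range = f | non-empty) for f = 0..width-1 given tree likelihoods."""
    miss = (1.0 - r) ** trees
    occ = 1.0 - miss
    left = np.ones((trees.shape[0], width + 1))
    np.cumprod(miss, axis=1, out=left[:, 1:])
    right = np.ones((trees.shape[0], width + 1))
    right[:, :-1] = np.cumprod(miss[:, ::-1], axis=1)[:, ::-1]
    prob = np.zeros(width)
    for a in range(width):
        prob[0] += float(lik @ (left[:, a] * right[:, a + 1] * occ[:, a]))
        for b in range(a + 1, width):
            prob[b - a] += float(
                lik @ (left[:, a] * right[:, b + 1] * occ[:, a] * occ[:, b])
            )
    p_empty = float(lik @ left[:, width])
    return prob / (1.0 - p_empty)


def fit_rho(
    observed: Sequence[Sequence[int]],
    profile: ProgressionProfile,
    r: float,
    grid_step: float = 0.01,
    statistic: str = "counts",
) -> RhoFit:
    """Maximum-likelihood within-family DD correlation.

    ``observed`` is one per-generation DD count vector per recovered clone
    (all-quiescent clones).  The likelihood of a clone marginalizes over
    every full tree it could have been thinned from:

        L(S | rho) = sum_T L(T | p, rho) L(S | T, r) / P(non-empty)

    conditioned on the clone being recovered at all.  ``statistic="range"``
    instead fits the likelihood of each clone's range value only (a
    coarser, comparison-only variant).  A deterministic grid of step
    ``grid_step`` is scanned and the optimum refined by bounded search;
    estimates at the boundary are reported as exactly 0 or 1.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("sampling probability r must lie in (0,1]")
    if len(observed) == 0:
        raise ValueError("no observed clones")
    if statistic not in ("counts", "range"):
        raise ValueError("statistic must be 'counts' or 'range'")
    D = profile.max_depth
    trees = _enumerate_tree_array(D)
    obs = _observed_matrix(observed, D)
    if statistic == "counts":
        M = _sampling_matrix(obs, trees, r)
    else:
        occupied = obs > 0
        ranges = np.array(
            [
                int(np.nonzero(row)[0][-1] - np.nonzero(row)[0][0])
                for row in occupied
            ]
        )
    miss_total = (1.0 - r) ** trees.sum(axis=1)

    def negloglik(rho: float) -> float:
        lik = _tree_likelihoods(trees, profile, rho)
        p_nonempty = 1.0 - float(lik @ miss_total)
        if statistic == "counts":
            clone_lik = M @ lik
        else:
            table = _range_probability_table(trees, lik, r, D + 1)
            clone_lik = table[ranges] * p_nonempty  # undo shared conditioning
        with np.errstate(divide="ignore"):
            ll = np.log(clone_lik) - math.log(p_nonempty)
        if not np.all(np.isfinite(ll)):
            return math.inf
        return -float(ll.sum())

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid[-1] = 1.0
    nll = np.array([negloglik(rho) for rho in grid])
    best = int(np.argmin(nll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            negloglik, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-5},
        )
        rho_hat = float(res.x) if res.fun <= nll[best] else float(grid[best])
    else:
        rho_hat = float(grid[best])
    if rho_hat < 1e-4:
        rho_hat = 0.0
    elif rho_hat > 1.0 - 1e-4:
        rho_hat = 1.0
    return RhoFit(
        rho_hat=rho_hat,
        grid=grid,
        loglik=-nll,
        n_clones=len(observed),
        statistic=statistic,
    )
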