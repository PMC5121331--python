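"""Linking clonal division destiny to in-vivo burst-size observations.

Two desk-scale calculations: (i) given a probability distribution of
family DD over divisions, reintroduce exponential expansion to obtain the
cumulative contribution of clones to total response magnitude — a small
high-DD minority of clones produces the bulk of the responding cells; and
(ii) the reverse direction, inferring a (binned) DD distribution from
observed clone sizes assuming concordant families and minimal death, via
DD = ceil(log2 N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DDProbabilityFunction",
    "clonal_contribution_curve",
    "dd_from_clone_sizes",
    "synthetic_ddpf",
]


@dataclass(frozen=True)
class DDProbabilityFunction:
    """Discretized probability that a clonal family reaches DD in each
    division, with the mean initial (founder) cell number of the response."""

    divisions: np.ndarray
    f: np.ndarray
    mN0: float = 1808.0

    def __post_init__(self):
        divisions = np.asarray(self.divisions, dtype=int)
        f = np.asarray(self.f, dtype=float)
        if divisions.size != f.size or divisions.size == 0:
            raise ValueError("divisions/probabilities mismatch")
        if np.any(f < 0) or f.sum() <= 0:
            raise ValueError("probabilities must be non-negative, positive total")
        if self.mN0 <= 0:
            raise ValueError("mean initial cell number must be positive")
        object.__setattr__(self, "divisions", divisions)
        object.__setattr__(self, "f", f / f.sum())


def synthetic_ddpf(
    lo: int = 4, hi: int = 19, mean: float = 11.0, sd: float = 3.0,
    mN0: float = 1808.0,
) -> DDProbabilityFunction:
    """Synthetic default DD distribution: a discretized normal over
    divisions [lo, hi], standing in for a fitted in-vivo distribution."""
    divisions = np.arange(lo, hi + 1)
    f = np.exp(-0.5 * ((divisions - mean) / sd) ** 2)
    return DDProbabilityFunction(divisions, f, mN0)


def clonal_contribution_curve(ddpf: DDProbabilityFunction) -> pd.DataFrame:
    """Cumulative clone share vs cumulative response-magnitude share.

    The number of progeny from clones reaching DD in division i is
    ``N_i = f_i mN0 2^i`` (expansion reintroduced); its percentage of the
    total is each division's contribution to response magnitude.  Clones
    are cumulated from the largest DD down, so the curve reads "the top
    x% of clones by DD contribute y% of the response".  Percentages are
    invariant to mN0.
    """
    order = np.argsort(ddpf.divisions)[::-1]
    div = ddpf.divisions[order]
    f = ddpf.f[order]
    magnitude = f * ddpf.mN0 * 2.0 ** div
    contribution = 100.0 * magnitude / magnitude.sum()
    return pd.DataFrame(
        {
            "division": div,
            "pct_clones": 100.0 * f,
            "pct_magnitude": contribution,
            "cum_pct_clones": np.cumsum(100.0 * f),
            "cum_pct_magnitude": np.cumsum(contribution),
        }
    )


def dd_from_clone_sizes(
    sizes: Sequence[float], bin_width: int = 2
) -> tuple[np.ndarray, pd.DataFrame]:
    """Estimate each clone's DD from its progeny count as ceil(log2 N).

    Assumes concordant families and minimal death: a clone of N cells that
    expanded concordantly divided about log2(N) times.  Returns the DD per
    clone and a histogram over bins of ``bin_width`` divisions starting at
    the smallest observed DD.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0 or np.any(sizes < 1):
        raise ValueError("clone sizes must be >= 1 cell")
    dd = np.ceil(np.log2(sizes)).astype(int)
    lo = int(dd.min())
    hi = int(dd.max())
    edges = np.arange(lo, hi + bin_width + 1, bin_width)
    counts, _ = np.histogram(dd, bins=edges)
    hist = pd.DataFrame(
        {
            "dd_bin_start": edges[:-1],
            "dd_bin_end": edges[1:] - 1,
            "n_clones": counts,
        }
    )
    return dd, hist
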