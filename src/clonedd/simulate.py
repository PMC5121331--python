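"""Synthetic clone-table generator.

Emulates the statistical structure of a multiplex division-tracking clone
assay: per condition, founder cells grow beta-binomially correlated
division-destiny trees; wells are harvested at fixed times mapped to
division frontiers by a nominal division cadence; each cell is recovered
independently with probability ``r``; and the quiescence call (small cell
size) is flipped with a small misclassification probability.  It also
provides additive-condition constructions — family DD vectors built as
convolutions of independent base and increment draws — the generative
model under the independent-signal-integration hypothesis.

Defaults emulate the four-condition costimulation experiment: conditions
N4, N4+aCD28, N4+IL-2 and N4+aCD28+IL-2 with founder inputs 96/224/96/224,
DD mass in generations 2–6, within-family correlation 0.9, recovery
probability 0.9, 4% quiescence misclassification, and harvests at
54/62/72 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .clone_table import COLUMNS, CloneTable
from .concordance import ProgressionProfile, estimate_progression_profile
from .trees import convolve

__all__ = [
    "ConditionConfig",
    "SimulationConfig",
    "default_config",
    "dd_distribution_to_profile",
    "simulate_full_tree",
    "simulate_full_trees",
    "simulate_clone_table",
    "simulate_additive_condition",
    "tree_sampler",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def dd_distribution_to_profile(dd_probs: Sequence[float]) -> ProgressionProfile:
    """Convert a founder-equivalent DD distribution (probability that a
    lineage unit stops in generation i) into a progression profile."""
    f = np.asarray(dd_probs, dtype=float)
    if np.any(f < 0) or f.sum() <= 0:
        raise ValueError("DD distribution must be non-negative with positive mass")
    f = f / f.sum()
    # profile estimation expects cohort-corrected *cell* counts n_i = f_i 2^i
    return estimate_progression_profile(f * 2.0 ** np.arange(f.size))


@dataclass
class ConditionConfig:
    """One stimulation condition of the simulated assay."""

    name: str
    profile: ProgressionProfile
    rho: float = 0.9
    r: float = 0.9
    n_founders: int = 96

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0,1]")
        if not 0.0 < self.r <= 1.0:
            raise ValueError("recovery probability r must lie in (0,1]")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")


@dataclass
class SimulationConfig:
    """Full assay simulation: conditions, harvests, noise, seed.

    ``first_division_h`` and ``division_h`` set the nominal division
    cadence mapping a harvest time to the division frontier G(h) =
    floor((h - first_division_h)/division_h) + 1: cells whose DD exceeds
    the frontier are emitted as still dividing at the frontier generation.
    """

    conditions: list[ConditionConfig]
    harvest_times: tuple[float, ...] = (54.0, 62.0, 72.0)
    misclass_rate: float = 0.04
    first_division_h: float = 30.0
    division_h: float = 8.0
    experiment_id: str = "sim"
    seed: int | None = None

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("at least one condition required")
        if not 0.0 <= self.misclass_rate < 0.5:
            raise ValueError("misclassification rate must lie in [0, 0.5)")
        if not self.harvest_times:
            raise ValueError("at least one harvest time required")

    def frontier(self, harvest_h: float) -> int:
        g = int(np.floor((harvest_h - self.first_division_h) / self.division_h)) + 1
        return max(g, 0)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        conditions = [
            ConditionConfig(
                name=c["name"],
                profile=dd_distribution_to_profile(c["dd_distribution"]),
                rho=float(c.get("rho", 0.9)),
                r=float(c.get("r", 0.9)),
                n_founders=int(c.get("n_founders", 96)),
            )
            for c in raw["conditions"]
        ]
        return cls(
            conditions=conditions,
            harvest_times=tuple(raw.get("harvest_times", (54.0, 62.0, 72.0))),
            misclass_rate=float(raw.get("misclass_rate", 0.04)),
            first_division_h=float(raw.get("first_division_h", 30.0)),
            division_h=float(raw.get("division_h", 8.0)),
            experiment_id=str(raw.get("experiment_id", "sim")),
            seed=raw.get("seed"),
        )


# Condition DD distributions (founder-equivalent mass per generation),
# placing DD in generations 2-6 with condition-dependent means.
_DEFAULT_DD = {
    "N4": (0.0, 0.0, 0.15, 0.50, 0.30, 0.05),
    "N4+aCD28": (0.0, 0.0, 0.0, 0.15, 0.50, 0.30, 0.05),
    "N4+IL-2": (0.0, 0.0, 0.0, 0.30, 0.50, 0.20),
    "N4+aCD28+IL-2": (0.0, 0.0, 0.0, 0.0, 0.20, 0.50, 0.30),
}
_DEFAULT_FOUNDERS = {"N4": 96, "N4+aCD28": 224, "N4+IL-2": 96, "N4+aCD28+IL-2": 224}


def default_config(seed: int | None = None, rho: float = 0.9, r: float = 0.9) -> SimulationConfig:
    """The standard four-condition costimulation assay configuration."""
    conditions = [
        ConditionConfig(
            name=name,
            profile=dd_distribution_to_profile(dd),
            rho=rho,
            r=r,
            n_founders=_DEFAULT_FOUNDERS[name],
        )
        for name, dd in _DEFAULT_DD.items()
    ]
    return SimulationConfig(conditions=conditions, seed=seed)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_full_trees(
    profile: ProgressionProfile,
    rho: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` full DD trees generation by generation.

    Of the ``c_i`` cells alive in generation i, the number progressing is
    beta-binomial(c_i, p_i, rho): rho=0 draws a plain binomial, rho=1 an
    all-or-none shared decision, and in between the success probability is
    drawn per family from the matching Beta density.  Returns an
    (n, D+1) array of DD counts per generation.
    """
    D = profile.max_depth
    t = np.zeros((n, D + 1), dtype=np.int64)
    c = np.ones(n, dtype=np.int64)
    for i in range(D + 1):
        p = profile.p[i]
        if p == 0.0:
            prog = np.zeros(n, dtype=np.int64)
        elif p == 1.0:
            prog = c.copy()
        elif rho == 0.0:
            prog = rng.binomial(c, p)
        elif rho == 1.0:
            shared = rng.random(n) < p
            prog = np.where(shared, c, 0)
        else:
            a = p * (1.0 - rho) / rho
            b = (1.0 - p) * (1.0 - rho) / rho
            q = rng.beta(a, b, size=n)
            prog = rng.binomial(c, q)
        t[:, i] = c - prog
        c = 2 * prog
    return t


def simulate_full_tree(
    profile: ProgressionProfile, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Single-tree convenience wrapper around :func:`simulate_full_trees`."""
    return simulate_full_trees(profile, rho, 1, rng)[0]


def tree_sampler(
    profile: ProgressionProfile, rho: float
) -> Callable[[np.random.Generator], np.ndarray]:
    """A DD-vector sampler drawing full trees from the given model."""

    def draw(rng: np.random.Generator) -> np.ndarray:
        return simulate_full_tree(profile, rho, rng)

    return draw


# ---------------------------------------------------------------------------
# Clone-table simulation
# ---------------------------------------------------------------------------

def simulate_clone_table(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> CloneTable:
    """Simulate the full assay into a :class:`CloneTable`.

    Founders are split round-robin across harvest times (each well is
    measured once).  At a harvest with division frontier G, cells with
    DD <= G appear quiescent in their DD generation; lineages still
    progressing appear as dividing cells in generation G.  Every cell is
    then kept with probability ``r`` and its quiescence flag flipped with
    the misclassification rate.  Clones with no recovered cell are dropped
    (as unobservable).  Deterministic under a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for cond in config.conditions:
        trees = simulate_full_trees(cond.profile, cond.rho, cond.n_founders, rng)
        D = cond.profile.max_depth
        cells = np.ones((cond.n_founders, D + 2), dtype=np.int64)
        for i in range(D + 1):
            cells[:, i + 1] = 2 * (cells[:, i] - trees[:, i])
        for j in range(cond.n_founders):
            harvest = config.harvest_times[j % len(config.harvest_times)]
            G = config.frontier(harvest)
            clone_id = f"{cond.name}:{j:04d}"
            emitted = []  # (generation, quiescent, count)
            for g in range(min(G, D) + 1):
                if trees[j, g] > 0:
                    emitted.append((g, 1, int(trees[j, g])))
            if G <= D:
                dividing = int(cells[:, G][j] - trees[j, G])
                if dividing > 0:
                    emitted.append((G, 0, dividing))
            for g, quiescent, count in emitted:
                kept = rng.binomial(count, cond.r)
                if kept == 0:
                    continue
                flipped = rng.binomial(kept, config.misclass_rate)
                if kept - flipped > 0:
                    rows.append(
                        (config.experiment_id, cond.name, harvest, clone_id,
                         g, kept - flipped, quiescent)
                    )
                if flipped > 0:
                    rows.append(
                        (config.experiment_id, cond.name, harvest, clone_id,
                         g, flipped, 1 - quiescent)
                    )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return CloneTable(
        df,
        sampling={c.name: c.r for c in config.conditions},
        founder_input={c.name: c.n_founders for c in config.conditions},
    )


# ---------------------------------------------------------------------------
# Additive-condition construction
# ---------------------------------------------------------------------------

def simulate_additive_condition(
    base_sampler: Callable[[np.random.Generator], np.ndarray],
    increment_sampler: Callable[[np.random.Generator], np.ndarray],
    n: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Family DD vectors under independent signal addition.

    Each family's DD vector is the convolution of an independent draw from
    the base-condition sampler and one from the increment sampler — the
    generative model when a costimulus adds an independent expansion
    effect to every clone.
    """
    out = []
    for _ in range(n):
        out.append(convolve(base_sampler(rng), increment_sampler(rng)))
    return out
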