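"""Per-clone and population division-destiny summary statistics.

All statistics use the cohort convention of division-tracking analysis:
a cell count in generation i is divided by 2^i, converting cell numbers to
founder-cell equivalents so that expansion does not bias averages.  The
clone-level quantities are

* range   — max minus min generation over a clone's detected cells
            (range 0 = perfectly concordant clone);
* mDD     — cohort-normalized mean generation of DD within a clone;
* maxDD   — largest generation of a fully quiescent clone.

Population DD is summarized by the cohort-weighted mean division number
per timepoint; its maximum over a timecourse estimates the population mDD
(the plateau reached when cells stop dividing).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clone_table import CloneTable

__all__ = [
    "clone_range",
    "cohort_normalize",
    "clone_mdd",
    "clone_maxdd",
    "filter_dd_clones",
    "mixed_clone_summary",
    "population_mean_division_number",
    "population_mdd",
    "summarize_clones",
]


def _weighted_generations(cells) -> tuple[np.ndarray, np.ndarray]:
    """(generations, cell counts) from a clone's rows or a generation list."""
    if isinstance(cells, pd.DataFrame):
        return cells["generation"].to_numpy(int), cells["n_cells"].to_numpy(int)
    gens = np.asarray(list(cells), dtype=int)
    return gens, np.ones_like(gens)


def clone_range(cells) -> int:
    """Max minus min generation over all detected cells of one clone.

    Quiescent and dividing cells count alike.  ``cells`` is a clone's
    DataFrame rows or an iterable of generation numbers.
    """
    gens, counts = _weighted_generations(cells)
    gens = gens[counts > 0]
    if gens.size == 0:
        raise ValueError("clone has no detected progeny")
    return int(gens.max() - gens.min())


def cohort_normalize(n: Sequence[int]) -> np.ndarray:
    """Cohort-normalized DD proportions ``q_i = (n_i 2^{-i}) / sum_j n_j 2^{-j}``.

    Renormalization excludes cells lost to incomplete recovery; the output
    sums to exactly 1.
    """
    n = np.asarray(n, dtype=float)
    if n.ndim != 1 or n.size == 0 or np.any(n < 0):
        raise ValueError("DD counts must be a non-empty non-negative vector")
    w = n / 2.0 ** np.arange(n.size)
    total = w.sum()
    if total <= 0:
        raise ValueError("DD counts are all zero")
    return w / total


def clone_mdd(n: Sequence[int]) -> float:
    """Cohort-normalized mean DD of a clone: ``sum_i i q_i``."""
    q = cohort_normalize(n)
    return float(np.arange(q.size) @ q)


def clone_maxdd(cells) -> int:
    """Largest generation in a clone whose cells have all reached DD.

    Raises if any cell is still dividing: maxDD is only defined for clones
    at division destiny.
    """
    if isinstance(cells, pd.DataFrame):
        if (cells["quiescent"] == 0).any():
            raise ValueError("clone has dividing cells; maxDD undefined")
        gens = cells["generation"].to_numpy(int)
    else:
        gens_list = []
        for cell in cells:
            gen, quiescent = cell
            if not quiescent:
                raise ValueError("clone has dividing cells; maxDD undefined")
            gens_list.append(gen)
        gens = np.asarray(gens_list, dtype=int)
    if gens.size == 0:
        raise ValueError("clone has no detected progeny")
    return int(gens.max())


def filter_dd_clones(table: CloneTable) -> CloneTable:
    """Retain only clones whose every detected cell is quiescent.

    Data are pooled across timepoints within condition: a clone qualifies
    if no row of it, at any harvest, is a dividing cell.
    """
    df = table.data
    if not len(df):
        return CloneTable(df.copy(), table.sampling, table.founder_input)
    all_quiescent = df.groupby("clone_id")["quiescent"].transform("min") == 1
    return CloneTable(df[all_quiescent].copy(), table.sampling, table.founder_input)


def mixed_clone_summary(table: CloneTable) -> pd.DataFrame:
    """Classify each clone as all-quiescent / all-dividing / mixed.

    For mixed clones, ``ordered`` is True iff no dividing cell sits in a
    later generation than any quiescent cell of the same clone
    (max dividing generation <= min quiescent generation) — the signature
    of slight timing variation within an otherwise synchronized clone.
    """
    rows = []
    for clone_id, sub in table.clones():
        qui = sub[sub["quiescent"] == 1]["generation"]
        div = sub[sub["quiescent"] == 0]["generation"]
        if len(div) == 0:
            cls, ordered = "all-quiescent", True
        elif len(qui) == 0:
            cls, ordered = "all-dividing", True
        else:
            cls = "mixed"
            ordered = bool(div.max() <= qui.min())
        rows.append(
            {
                "clone_id": clone_id,
                "condition": sub["condition"].iloc[0],
                "class": cls,
                "ordered": ordered,
            }
        )
    return pd.DataFrame(rows, columns=["clone_id", "condition", "class", "ordered"])


def population_mean_division_number(counts: Sequence[float]) -> float:
    """Cohort-weighted mean division number of one timepoint.

    With cohort numbers ``C_i = count_i / 2^i`` (founder equivalents per
    generation), returns ``sum_i i C_i / sum_i C_i``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0 or np.any(counts < 0):
        raise ValueError("counts must be a non-empty non-negative vector")
    cohorts = counts / 2.0 ** np.arange(counts.size)
    total = cohorts.sum()
    if total <= 0:
        raise ValueError("all-zero cell counts")
    return float(np.arange(counts.size) @ cohorts / total)


def population_mdd(timecourse: Mapping[float, Sequence[float]]) -> float:
    """Population mean division destiny: the maximum mean division number
    over all timepoints (assuming little death, MDN plateaus at DD)."""
    if not timecourse:
        raise ValueError("empty timecourse")
    return max(
        population_mean_division_number(counts) for counts in timecourse.values()
    )


def summarize_clones(table: CloneTable) -> pd.DataFrame:
    """One summary row per clone: range, mDD, maxDD (if at DD) and class."""
    classes = mixed_clone_summary(table).set_index("clone_id")
    rows = []
    for clone_id, sub in table.clones():
        cls = classes.loc[clone_id, "class"]
        at_dd = cls == "all-quiescent"
        entry = {
            "clone_id": clone_id,
            "condition": sub["condition"].iloc[0],
            "range": clone_range(sub),
            "class": cls,
        }
        if at_dd:
            counts = table.dd_counts(clone_id)
            entry["mdd"] = clone_mdd(counts)
            entry["maxdd"] = clone_maxdd(sub)
        else:
            entry["mdd"] = np.nan
            entry["maxdd"] = np.nan
        rows.append(entry)
    return pd.DataFrame(
        rows, columns=["clone_id", "condition", "range", "mdd", "maxdd", "class"]
    )
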