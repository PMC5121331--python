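"""Clone-table container and its TSV dialect.

The clone table is the input boundary of the pipeline: one row per
(clone, generation, quiescence, timepoint) cell count, as produced by a
multiplex division-tracking flow-cytometry assay after gating.  Columns:

    experiment_id  condition  timepoint_h  clone_id  generation  n_cells  quiescent

``generation`` is 0-based (the founder is generation 0), ``quiescent`` is
0/1 (small cell size = returned to quiescence).  Header row is mandatory;
lines beginning with ``#`` carry the parameterization: per-condition
sampling (recovery) probability ``r`` and founder-cell input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CloneTable", "read_clone_table", "write_clone_table", "COLUMNS"]

COLUMNS = [
    "experiment_id",
    "condition",
    "timepoint_h",
    "clone_id",
    "generation",
    "n_cells",
    "quiescent",
]


@dataclass
class CloneTable:
    """Long-format record of detected cells per clone plus assay metadata.

    ``sampling`` maps condition -> per-cell recovery probability r in (0,1];
    ``founder_input`` maps condition -> number of founder cells sorted.
    """

    data: pd.DataFrame
    sampling: dict[str, float] = field(default_factory=dict)
    founder_input: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"clone table missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        df = self.data
        if len(df) and (df["generation"] < 0).any():
            raise ValueError("negative generation in clone table")
        if len(df) and (df["n_cells"] <= 0).any():
            raise ValueError("non-positive cell count in clone table")
        if len(df) and (df["timepoint_h"] <= 0).any():
            raise ValueError("non-positive timepoint in clone table")
        for cond, r in self.sampling.items():
            if not (0 < r <= 1):
                raise ValueError(f"sampling probability for {cond!r} not in (0,1]: {r}")
        # each clone belongs to exactly one condition
        if len(df):
            ncond = df.groupby("clone_id")["condition"].nunique()
            bad = ncond[ncond > 1]
            if len(bad):
                raise ValueError(
                    f"clone ids mapped to multiple conditions: {list(bad.index)[:5]}"
                )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    def for_condition(self, condition: str) -> "CloneTable":
        sub = self.data[self.data["condition"] == condition]
        return CloneTable(
            sub.copy(),
            {k: v for k, v in self.sampling.items() if k == condition},
            {k: v for k, v in self.founder_input.items() if k == condition},
        )

    def clones(self):
        """Iterate (clone_id, sub-DataFrame) over clones."""
        return self.data.groupby("clone_id", sort=True)

    def dd_counts(self, clone_id) -> np.ndarray:
        """Per-generation quiescent-cell counts for one clone."""
        sub = self.data[
            (self.data["clone_id"] == clone_id) & (self.data["quiescent"] == 1)
        ]
        if not len(sub):
            raise ValueError(f"clone {clone_id!r} has no quiescent cells")
        out = np.zeros(int(sub["generation"].max()) + 1, dtype=np.int64)
        for g, n in zip(sub["generation"], sub["n_cells"]):
            out[int(g)] += int(n)
        return out


def write_clone_table(table: CloneTable, path: str | Path) -> None:
    """Write TSV with '#'-prefixed parameterization header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for cond in sorted(set(table.sampling) | set(table.founder_input)):
            if cond in table.sampling:
                fh.write(f"# sampling_probability\t{cond}\t{table.sampling[cond]!r}\n")
            if cond in table.founder_input:
                fh.write(f"# founder_input\t{cond}\t{table.founder_input[cond]}\n")
        table.data.to_csv(fh, sep="\t", index=False, columns=COLUMNS)


def read_clone_table(path: str | Path) -> CloneTable:
    """Read and validate a clone-table TSV; malformed rows are reported with
    1-based file line numbers."""
    path = Path(path)
    sampling: dict[str, float] = {}
    founders: dict[str, int] = {}
    body_lines: list[str] = []
    line_numbers: list[int] = []  # file line number of each body line
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 3 and parts[0] == "sampling_probability":
                    sampling[parts[1]] = float(parts[2])
                elif len(parts) == 3 and parts[0] == "founder_input":
                    founders[parts[1]] = int(parts[2])
                continue
            if line.strip():
                body_lines.append(line)
                line_numbers.append(lineno)
    if not body_lines:
        raise ValueError(f"{path}: empty clone table")
    header = body_lines[0].rstrip("\n").split("\t")
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t")

    errors: list[str] = []

    def _check(mask: pd.Series, message: str) -> None:
        for i in np.nonzero(mask.to_numpy())[0][:10]:
            errors.append(f"line {line_numbers[i + 1]}: {message}")

    num = pd.to_numeric(df["generation"], errors="coerce")
    _check(num.isna() | (num < 0) | (num != num.round()),
           "generation must be a non-negative integer")
    ncells = pd.to_numeric(df["n_cells"], errors="coerce")
    _check(ncells.isna() | (ncells <= 0) | (ncells != ncells.round()),
           "n_cells must be a positive integer")
    _check(~df["quiescent"].isin([0, 1]), "quiescent must be 0 or 1")
    if errors:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(errors))
    df["generation"] = df["generation"].astype(int)
    df["n_cells"] = df["n_cells"].astype(int)
    df["quiescent"] = df["quiescent"].astype(int)
    return CloneTable(df, sampling, founders)
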