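"""Q-sort datasets and stimulus variable designs: containers, I/O, validation.

The on-disk dialect mirrors common practice in Q-methodology software:

* a *sort matrix* CSV with stimuli in rows and participants in columns
  (first column: stimulus IDs; header row: participant IDs), every column
  being a permutation of the grid's rank multiset;
* a *design* CSV with stimuli in rows and one column per variable, each cell
  giving the level of that stimulus on that variable.  Levels are categorical
  labels even when entered as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .grid import QGrid

__all__ = [
    "QSortError",
    "QSortDataset",
    "VariableDesign",
    "read_qsort",
    "read_design",
    "write_qsort",
    "write_design",
    "validation_report",
]


class QSortError(ValueError):
    """Raised when Q-sort data violate the forced-distribution contract."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen, dupes = set(), []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise QSortError(f"duplicate {what} IDs: {sorted(set(dupes))}")
    return ids


@dataclass
class QSortDataset:
    """Stimuli x participants rank matrix bound to its forced grid.

    Every column must be a permutation of ``grid.multiset()``; as a
    consequence all columns share the same sum, median and deviance, so
    there is no subject-level location/scale variation by construction.
    """

    stimulus_ids: list[str]
    participant_ids: list[str]
    ranks: np.ndarray  # (n_stimuli, n_participants) int
    grid: QGrid

    def __post_init__(self) -> None:
        self.stimulus_ids = _check_unique(self.stimulus_ids, "stimulus")
        self.participant_ids = _check_unique(self.participant_ids, "participant")
        self.ranks = np.asarray(self.ranks, dtype=int)
        if self.ranks.shape != (len(self.stimulus_ids), len(self.participant_ids)):
            raise QSortError(
                f"rank matrix shape {self.ranks.shape} does not match "
                f"{len(self.stimulus_ids)} stimuli x {len(self.participant_ids)} participants"
            )
        for violation in self.violations():
            raise QSortError(violation)

    def violations(self) -> list[str]:
        """All grid-multiset violations, one message per offending column."""
        out = []
        expected = self.grid.multiset()
        for j, pid in enumerate(self.participant_ids):
            if not np.array_equal(np.sort(self.ranks[:, j]), expected):
                out.append(
                    f"participant {pid!r}: column is not a permutation of the "
                    f"grid multiset {expected.tolist()}"
                )
        return out

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ranks, index=self.stimulus_ids, columns=self.participant_ids
        )

    def column(self, participant_id: str) -> np.ndarray:
        j = self.participant_ids.index(str(participant_id))
        return self.ranks[:, j]


@dataclass
class VariableDesign:
    """Level assignment of every stimulus on every design variable.

    ``levels[v]`` lists each variable's levels in first-appearance order;
    the first listed level is the reference level for model coding, so the
    row order of the design file is meaningful.
    """

    stimulus_ids: list[str]
    assignments: pd.DataFrame  # stimuli x variables, categorical labels

    def __post_init__(self) -> None:
        self.stimulus_ids = _check_unique(self.stimulus_ids, "stimulus")
        df = pd.DataFrame(self.assignments).astype(str)
        df.index = pd.Index(self.stimulus_ids)
        if df.isna().any().any():
            raise QSortError("every stimulus needs exactly one level per variable")
        for v in df.columns:
            if df[v].nunique() < 2:
                raise QSortError(f"variable {v!r} has fewer than 2 distinct levels")
        self.assignments = df

    @property
    def variables(self) -> list[str]:
        return [str(c) for c in self.assignments.columns]

    @property
    def levels(self) -> dict[str, list[str]]:
        """Levels per variable, in order of first appearance down the rows."""
        return {
            v: list(dict.fromkeys(self.assignments[v])) for v in self.variables
        }

    @property
    def n_levels(self) -> dict[str, int]:
        return {v: len(lv) for v, lv in self.levels.items()}

    @property
    def balanced(self) -> bool:
        """True iff every level of every variable covers equally many stimuli."""
        for v in self.variables:
            if self.assignments[v].value_counts().nunique() != 1:
                return False
        return True

    def level_of(self, variable: str) -> pd.Series:
        if variable not in self.assignments.columns:
            raise KeyError(f"unknown variable {variable!r}")
        return self.assignments[variable]

    def aligned_to(self, stimulus_ids: list[str]) -> "VariableDesign":
        """Reorder rows to match a dataset's stimulus IDs (match by ID)."""
        missing = [s for s in stimulus_ids if s not in self.assignments.index]
        if missing:
            raise QSortError(f"stimuli absent from the design: {missing}")
        sub = self.assignments.loc[list(stimulus_ids)]
        return VariableDesign(list(stimulus_ids), sub)


# ---------------------------------------------------------------------------
# readers / writers (RFC-4180 CSV, UTF-8, header row)
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise QSortError(f"{path}: expected an ID column plus data columns")
    df = df.set_index(df.columns[0])
    return df


def read_qsort(path: str | Path, grid: QGrid | str = "infer") -> QSortDataset:
    """Read a stimuli x participants sort matrix from CSV.

    With ``grid="infer"`` the grid is taken as the rank multiset of the
    first participant column and every other column is validated against it.
    """
    df = _read_table(path)
    ranks = np.empty(df.shape, dtype=int)
    for j, col in enumerate(df.columns):
        for i, (sid, cell) in enumerate(df[col].items()):
            try:
                ranks[i, j] = int(cell)
            except ValueError:
                raise QSortError(
                    f"{path}: non-integer rank {cell!r} at stimulus {sid!r}, "
                    f"participant {col!r}"
                ) from None
    if isinstance(grid, str):
        if grid != "infer":
            raise ValueError("grid must be a QGrid or 'infer'")
        values, counts = np.unique(ranks[:, 0], return_counts=True)
        grid = QGrid(tuple(values.tolist()), tuple(counts.tolist()))
    return QSortDataset(list(df.index), list(df.columns), ranks, grid)


def read_design(path: str | Path) -> VariableDesign:
    """Read a stimuli x variables design table from CSV."""
    df = _read_table(path)
    return VariableDesign(list(df.index), df)


def write_qsort(data: QSortDataset, path: str | Path) -> None:
    frame = data.to_frame()
    frame.index.name = "stimulus"
    frame.to_csv(path)


def write_design(design: VariableDesign, path: str | Path) -> None:
    frame = design.assignments.copy()
    frame.index.name = "stimulus"
    frame.to_csv(path)


def validation_report(
    data_path: str | Path,
    design_path: str | Path | None = None,
    grid: QGrid | str = "infer",
) -> list[str]:
    """Run every structural check and return the list of violations.

    Unlike the constructors this never raises on invalid content: each
    violation becomes one message, so a caller can show all of them at once.
    """
    violations: list[str] = []
    data = None
    try:
        df = _read_table(data_path)
    except Exception as exc:  # unreadable file is a single violation
        return [f"data: {exc}"]
    try:
        data = read_qsort(data_path, grid=grid)
    except QSortError as exc:
        # re-validate column by column so every bad participant is named
        try:
            ranks = df.map(lambda c: int(c)).to_numpy()
            if isinstance(grid, str):
                values, counts = np.unique(ranks[:, 0], return_counts=True)
                g = QGrid(tuple(values.tolist()), tuple(counts.tolist()))
            else:
                g = grid
            expected = g.multiset()
            for j, col in enumerate(df.columns):
                if not np.array_equal(np.sort(ranks[:, j]), expected):
                    violations.append(
                        f"data: participant {col!r} violates the grid multiset"
                    )
            if not violations:
                violations.append(f"data: {exc}")
        except Exception:
            violations.append(f"data: {exc}")
    if design_path is not None:
        try:
            design = read_design(design_path)
            if data is not None:
                missing = [
                    s for s in data.stimulus_ids if s not in design.assignments.index
                ]
                for s in missing:
                    violations.append(f"design: stimulus {s!r} missing from design")
        except Exception as exc:
            violations.append(f"design: {exc}")
    return violations
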