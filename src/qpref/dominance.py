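"""Dominance of a variable in forced-distribution rank data.

*Preference* is the liking of one level over another within a variable
(smooth over rough texture); *dominance* is the importance of a variable
across variables (how strongly texture, rather than size, drives where a
sorter places the stimuli).  Dominance is measured from the spread of a
variable's levels across the sorting grid:

* raw dominance  ``D_v``   — the largest difference between the summed
  scores of any two levels of the variable (rank-sum units);
* weighted dominance ``WD_v`` — ``D_v`` divided by the largest difference
  the grid allows for a variable with that many levels, making variables
  with different level counts comparable (0..1 for balanced designs);
* comparable score difference ``CSD_v`` — ``WD_v`` mapped back to rank-sum
  units on a scale shared by all variables (``WD_v`` times the average,
  over variables, of their maximal attainable differences);
* proportion of dominance ``PD_v`` — ``WD_v`` normalized to sum to one
  across variables, the per-unit attention weight profile.

The unit of analysis is either a participant's raw sort or a cluster's
factor-score profile (continuous z-scores or grid-rounded ranks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import VariableDesign
from .grid import QGrid

__all__ = [
    "DominanceResult",
    "level_sums",
    "raw_dominance",
    "max_attainable_difference",
    "qdominance",
]


def level_sums(scores, design: VariableDesign, variable: str) -> dict[str, float]:
    """Sum of scores over the stimuli at each level of one variable.

    ``scores`` must be aligned to ``design``'s stimulus order.  The level
    sums partition the stimuli, so they always total the grand score sum.
    """
    levels = design.level_of(variable)  # raises KeyError on unknown variable
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(levels),):
        raise ValueError(
            f"scores length {scores.shape} does not match {len(levels)} stimuli"
        )
    out: dict[str, float] = {}
    for lv in design.levels[variable]:
        out[lv] = float(scores[(levels == lv).to_numpy()].sum())
    return out


def raw_dominance(scores, design: VariableDesign, variable: str) -> float:
    """Raw dominance D: the maximum pairwise difference between level sums.

    Over all unordered pairs of levels, the largest absolute difference of
    their score sums — equivalently max(level sums) - min(level sums).
    """
    sums = level_sums(scores, design, variable)
    vals = list(sums.values())
    return float(max(vals) - min(vals))


def max_attainable_difference(grid: QGrid, n_levels: int) -> float:
    """Largest level-sum difference a grid permits for an n-level variable.

    Attained when one level occupies the ``floor(n_stimuli / n_levels)``
    highest slots and another the same number of lowest slots; by the grid's
    symmetry this equals twice the top-k slot sum.  For asymmetric grids the
    top-k and bottom-k sums are combined explicitly.
    """
    n_levels = int(n_levels)
    if n_levels < 2:
        raise ValueError("a variable needs at least 2 levels")
    if n_levels > grid.n_stimuli:
        raise ValueError(
            f"{n_levels} levels exceed the {grid.n_stimuli} stimuli in the grid"
        )
    k = grid.n_stimuli // n_levels
    ms = grid.multiset()
    top = float(ms[::-1][:k].sum())
    bottom = float(ms[:k].sum())
    return top - bottom  # == 2 * top for symmetric grids


@dataclass
class DominanceResult:
    """Per-unit dominance profile across the design variables.

    ``defined`` is False when the unit shows zero dominance on every
    variable (constant scores), in which case PD is undefined and NaN.
    """

    unit_id: str
    D: pd.Series
    WD: pd.Series
    CSD: pd.Series
    PD: pd.Series
    defined: bool = True
    approximate: bool = field(default=False, repr=False)  # unbalanced design

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.unit_id, "variable": self.D.index,
             "D": self.D.values, "WD": self.WD.values,
             "CSD": self.CSD.values, "PD": self.PD.values}
        )


def qdominance(
    scores,
    design: VariableDesign,
    grid: QGrid,
    is_factor_scores: bool = False,
    unit_ids: list[str] | None = None,
) -> list[DominanceResult]:
    """Dominance profiles (D, WD, CSD, PD) for each unit's score column.

    Parameters
    ----------
    scores : array-like or DataFrame, stimuli x units
        Raw grid ranks per participant (``is_factor_scores=False``) or
        factor-score profiles per cluster — continuous z-scores or
        grid-rounded ranks (``is_factor_scores=True``).  A single vector is
        treated as one unit.
    design : VariableDesign
        Stimulus-level assignments, aligned to the score rows.
    grid : QGrid
        The forced distribution; its top-slot sums normalize WD and CSD.
    is_factor_scores : bool
        Marks the unit of analysis; the numbers are computed identically,
        the flag controls how reporting layers label and select columns.
    """
    if isinstance(scores, pd.DataFrame):
        if unit_ids is None:
            unit_ids = [str(c) for c in scores.columns]
        mat = scores.to_numpy(dtype=float)
    else:
        mat = np.asarray(scores, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
    if unit_ids is None:
        prefix = "F" if is_factor_scores else "U"
        unit_ids = [f"{prefix}{j + 1:02d}" for j in range(mat.shape[1])]
    if mat.shape[0] != len(design.stimulus_ids):
        raise ValueError(
            f"{mat.shape[0]} score rows for {len(design.stimulus_ids)} stimuli"
        )

    if not design.balanced:
        warnings.warn(
            "unbalanced design: WD normalization presumes equal level sizes; "
            "weighted dominance is approximate",
            UserWarning,
            stacklevel=2,
        )

    variables = design.variables
    max_diff = {v: max_attainable_difference(grid, design.n_levels[v]) for v in variables}
    # the CSD scale factor: average over variables of their attainable maxima
    csd_scale = float(np.mean([max_diff[v] for v in variables]))

    results = []
    for j, uid in enumerate(unit_ids):
        col = mat[:, j]
        D = pd.Series({v: raw_dominance(col, design, v) for v in variables})
        WD = pd.Series({v: D[v] / max_diff[v] for v in variables})
        total = float(WD.sum())
        if total > 0:
            PD = WD / total
            defined = True
        else:
            PD = pd.Series(np.nan, index=WD.index)
            defined = False
        CSD = WD * csd_scale
        results.append(
            DominanceResult(
                unit_id=str(uid), D=D, WD=WD, CSD=CSD, PD=PD,
                defined=defined, approximate=not design.balanced,
            )
        )
    return results


def dominance_table(results: list[DominanceResult]) -> pd.DataFrame:
    """Tidy long table (unit_id, variable, D, WD, CSD, PD) over all units."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)


def weights_matrix(results: list[DominanceResult]) -> pd.DataFrame:
    """Units x variables matrix of PD weights (the attention-weight table)."""
    return pd.DataFrame({r.unit_id: r.PD for r in results}).T
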