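"""Published summary tables of the interactive-objects (IO) study.

The worked example behind this package is a Q-methodology study in which
18 participants rank-ordered 32 handheld interactive objects — varying in
Size (Small/Large), Surface texture (Smooth/Rough), Contour
(Round/Angular) and autonomous Behavior (Light/Sound/Vibrate/Quiescent) —
into an 11-column forced grid from -5 (least preferred) to +5 (most
preferred).

The raw individual sorts were deposited with the article's supplementary
material and are not redistributed here, but the published *summary*
tables are small and are bundled as printed: the stimulus design, each
participant's dominance-weight profile, the three-factor loading matrix
(with its defining-sort flags) and the per-factor grid-rounded factor
scores.  They drive the analyses that need only summary inputs and serve
as reference values in the test-suite.

Stimulus labels encode the levels positionally, e.g. ``LRRL`` = Large,
Rough texture, Round contour, Lighting behavior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import VariableDesign
from .grid import QGrid

__all__ = [
    "io_grid",
    "io_design",
    "participant_weights",
    "factor_loadings",
    "factor_flags",
    "factor_grid_scores",
]

#: canonical 32-stimulus forced grid, ranks -5 .. +5
_GRID = QGrid(tuple(range(-5, 6)), (1, 2, 3, 3, 4, 6, 4, 3, 3, 2, 1))

# the 32 stimulus labels in published order (reference levels listed first:
# Large, Rough, Angular, Quiescent)
_STIMULI = [
    "LRAQ", "LRAV", "LRAL", "LRAS", "LRRQ", "LRRV", "LRRL", "LRRS",
    "LSAQ", "LSAV", "LSAL", "LSAS", "LSRQ", "LSRV", "LSRL", "LSRS",
    "SRAQ", "SRAV", "SRAL", "SRAS", "SRRQ", "SRRV", "SRRL", "SRRS",
    "SSAQ", "SSAV", "SSAL", "SSAS", "SSRQ", "SSRV", "SSRL", "SSRS",
]

_LEVEL_CODES = {
    "Size": {"L": "Large", "S": "Small"},
    "Texture": {"R": "Rough", "S": "Smooth"},
    "Contour": {"A": "Angular", "R": "Round"},
    "Behavior": {"Q": "Quiescent", "V": "Vibrate", "L": "Light", "S": "Sound"},
}

# participants x variables dominance weights (PD), published to 2 decimals
_WEIGHTS = """\
P01 0.19 0.21 0.06 0.53
P02 0.20 0.23 0.04 0.53
P03 0.17 0.48 0.13 0.21
P04 0.14 0.27 0.23 0.36
P05 0.18 0.09 0.05 0.68
P06 0.05 0.16 0.16 0.63
P07 0.08 0.15 0.38 0.40
P08 0.18 0.49 0.04 0.30
P09 0.14 0.23 0.23 0.39
P10 0.18 0.34 0.04 0.44
P11 0.03 0.03 0.13 0.81
P12 0.02 0.00 0.24 0.74
P13 0.02 0.44 0.08 0.46
P14 0.02 0.37 0.21 0.40
P15 0.07 0.18 0.22 0.52
P16 0.44 0.15 0.13 0.28
P17 0.09 0.03 0.00 0.88
P18 0.15 0.14 0.20 0.50"""

# participants x factors rotated loadings; '*' marks the defining sorts
_LOADINGS = """\
P01  0.28  0.70* 0.29
P02  0.24  0.74* 0.05
P03 -0.36  0.65* -0.38
P04  0.58* 0.18  0.47
P05  0.47  0.61* -0.04
P06  0.54  0.43  0.41
P07  0.16  0.80* 0.22
P08  0.82* -0.16  0.13
P09  0.71* 0.16  0.16
P10  0.89* 0.27  -0.15
P11  0.02  -0.04  0.86*
P12  0.09  0.28  0.86*
P13  0.91* 0.16  0.02
P14  0.83* 0.26  0.05
P15  0.20  0.81* 0.37
P16  0.52* 0.28  0.10
P17  0.06  0.17  0.85*
P18  0.70* 0.62  0.12"""

# stimuli x factors grid-rounded factor scores
_FACTOR_SCORES = """\
LRAQ -2  0 -2
LRAV -2  1  2
LRAL -1  1 -1
LRAS -4 -2  0
LRRQ -1  2 -3
LRRV  0  4  4
LRRL -1  5  1
LRRS -4 -3  1
LSAQ  1 -2 -4
LSAV  1 -1  2
LSAL  4  0  2
LSAS -1 -4 -1
LSRQ  2 -1 -2
LSRV  3  2  3
LSRL  3  3  1
LSRS -3 -3 -1
SRAQ  0  0 -4
SRAV  0  2  3
SRAL  0  1  0
SRAS -5 -2  0
SRRQ  0  1 -3
SRRV  0  3  5
SRRL  1  4  0
SRRS -3 -3  0
SSAQ  3 -1 -5
SSAV  2  0  3
SSAL  5  0  1
SSAS -3 -4 -2
SSRQ  1 -1 -3
SSRV  2  0  4
SSRL  4  3  0
SSRS -2 -5 -1"""


def io_grid() -> QGrid:
    """The study's 32-slot forced grid over ranks -5 ... +5."""
    return _GRID


def io_design() -> VariableDesign:
    """The 2 x 2 x 2 x 4 interactive-objects stimulus design (balanced)."""
    rows = {
        var: [codes[s[i]] for s in _STIMULI]
        for i, (var, codes) in enumerate(_LEVEL_CODES.items())
    }
    return VariableDesign(_STIMULI, pd.DataFrame(rows, index=_STIMULI))


def _parse(block: str, columns: list[str], dtype=float) -> pd.DataFrame:
    rows = [line.split() for line in block.splitlines()]
    return pd.DataFrame(
        [[dtype(x.rstrip("*")) for x in r[1:]] for r in rows],
        index=[r[0] for r in rows], columns=columns,
    )


def participant_weights() -> pd.DataFrame:
    """Published per-participant dominance weights (PD), 18 x 4."""
    return _parse(_WEIGHTS, ["Size", "Texture", "Contour", "Behavior"])


def factor_loadings() -> pd.DataFrame:
    """Published rotated loadings of the three-factor solution, 18 x 3."""
    return _parse(_LOADINGS, ["F1", "F2", "F3"])


def factor_flags() -> pd.Series:
    """Defining-sort assignment as published (asterisked loadings)."""
    flags = {}
    for line in _LOADINGS.splitlines():
        parts = line.split()
        starred = [j for j, x in enumerate(parts[1:]) if x.endswith("*")]
        flags[parts[0]] = f"F{starred[0] + 1}" if starred else None
    return pd.Series(flags, name="factor")


def factor_grid_scores() -> pd.DataFrame:
    """Published grid-rounded factor scores, 32 stimuli x 3 factors."""
    return _parse(_FACTOR_SCORES, ["F1", "F2", "F3"], dtype=int)
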