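"""Synthetic Q-sort generator with known cluster structure.

The generator emulates the latent decision model the protocol is built to
recover: each participant belongs to a cluster with its own *attention
weights* across variables (dominance) and *level utilities* within each
variable (preference).  A participant's latent utility for a stimulus is

    u(s) = sum_v attention_v * utility_v(level_v(s)) + Normal(0, noise_sd)

and the forced sort assigns the grid's rank multiset by descending
utility, so the forced distribution is always exact while noise perturbs
only the order.  Ground-truth cluster labels are returned alongside the
dataset, which makes cluster-recovery and dominance-recovery claims
testable end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import QSortDataset, VariableDesign, read_qsort
from .grid import QGrid
from . import worked_example

__all__ = ["ClusterSpec", "SyntheticSpec", "generate", "packaged_fixture"]


@dataclass
class ClusterSpec:
    """One latent cluster: attention across variables, utilities within.

    ``attention`` maps variable -> non-negative weight (normalized to sum
    to 1); ``utilities`` maps variable -> {level: utility}.
    """

    attention: dict[str, float]
    utilities: dict[str, dict[str, float]]

    def normalized_attention(self, variables: list[str]) -> dict[str, float]:
        w = np.array([float(self.attention.get(v, 0.0)) for v in variables])
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("attention weights must be non-negative, sum > 0")
        w = w / w.sum()
        return dict(zip(variables, w))


@dataclass
class SyntheticSpec:
    """A complete stated world for one synthetic study."""

    design: VariableDesign
    grid: QGrid
    clusters: list[ClusterSpec]
    cluster_sizes: list[int]
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.clusters) != len(self.cluster_sizes):
            raise ValueError("clusters and cluster_sizes differ in length")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.grid.n_stimuli != len(self.design.stimulus_ids):
            raise ValueError("grid size does not match the design")


def _cluster_utilities(spec: SyntheticSpec, cluster: ClusterSpec) -> np.ndarray:
    variables = spec.design.variables
    attention = cluster.normalized_attention(variables)
    u = np.zeros(len(spec.design.stimulus_ids))
    for v in variables:
        table = cluster.utilities.get(v, {})
        levels = spec.design.level_of(v)
        missing = set(levels) - set(table)
        if missing and table:
            raise ValueError(f"cluster utilities for {v!r} miss levels {missing}")
        vals = np.array([float(table.get(lv, 0.0)) for lv in levels])
        u = u + attention[v] * vals
    return u


def _force_into_grid(utility: np.ndarray, grid: QGrid) -> np.ndarray:
    """Descending utility receives the descending grid multiset.

    Ties are broken by stimulus position (ID order), keeping generation
    deterministic.
    """
    order = np.argsort(-utility, kind="stable")
    ranks = np.empty(len(utility), dtype=int)
    ranks[order] = grid.multiset()[::-1]
    return ranks


def generate(spec: SyntheticSpec) -> tuple[QSortDataset, pd.Series]:
    """Draw a dataset from the stated world; returns (data, true labels)."""
    rng = np.random.default_rng(spec.seed)
    columns, labels, pids = [], [], []
    p = 0
    for c, (cluster, size) in enumerate(zip(spec.clusters, spec.cluster_sizes)):
        base = _cluster_utilities(spec, cluster)
        for _ in range(size):
            p += 1
            pid = f"P{p:02d}"
            noise = rng.normal(0.0, spec.noise_sd, size=base.shape) \
                if spec.noise_sd > 0 else 0.0
            columns.append(_force_into_grid(base + noise, spec.grid))
            labels.append(f"C{c + 1}")
            pids.append(pid)
    data = QSortDataset(
        list(spec.design.stimulus_ids), pids,
        np.column_stack(columns), spec.grid,
    )
    return data, pd.Series(labels, index=pids, name="cluster")


# ---------------------------------------------------------------------------
# packaged fixture: the interactive-objects study's structure
# ---------------------------------------------------------------------------

# Stand-in cluster parameters, chosen once from the study's qualitative
# description (cluster 1 attends to texture and behavior and prefers rough;
# cluster 2 attends to behavior and contour and prefers smooth/round;
# cluster 3 is behavior-dominated and dislikes quiescent objects).
_STANDIN_CLUSTERS = [
    ClusterSpec(
        attention={"Size": 0.09, "Texture": 0.41, "Contour": 0.04,
                   "Behavior": 0.46},
        utilities={
            "Size": {"Large": 0.0, "Small": 1.0},
            "Texture": {"Rough": 1.0, "Smooth": -1.0},
            "Contour": {"Angular": 0.0, "Round": 1.0},
            "Behavior": {"Quiescent": 0.2, "Vibrate": 0.6, "Light": 1.0,
                         "Sound": -1.0},
        },
    ),
    ClusterSpec(
        attention={"Size": 0.04, "Texture": 0.25, "Contour": 0.21,
                   "Behavior": 0.50},
        utilities={
            "Size": {"Large": 0.0, "Small": 0.5},
            "Texture": {"Rough": -1.0, "Smooth": 1.0},
            "Contour": {"Angular": 0.0, "Round": 1.0},
            "Behavior": {"Quiescent": -0.2, "Vibrate": 1.0, "Light": 0.8,
                         "Sound": -1.0},
        },
    ),
    ClusterSpec(
        attention={"Size": 0.05, "Texture": 0.02, "Contour": 0.15,
                   "Behavior": 0.78},
        utilities={
            "Size": {"Large": 0.0, "Small": 0.3},
            "Texture": {"Rough": 0.3, "Smooth": -0.3},
            "Contour": {"Angular": -0.5, "Round": 0.5},
            "Behavior": {"Quiescent": -1.0, "Vibrate": 1.0, "Light": 0.3,
                         "Sound": 0.2},
        },
    ),
]


def packaged_fixture(data_path: str | Path | None = None
                     ) -> tuple[QSortDataset, VariableDesign, bool]:
    """The 32-stimulus interactive-objects design with sort data.

    Returns ``(data, design, is_synthetic)``.  The design and grid are the
    study's published ones.  If a real sort matrix CSV is supplied (or
    found at the conventional ``data.csv`` location next to the caller's
    working directory) it is loaded; otherwise a synthetic stand-in with
    matching structure — 18 participants in three clusters of 8, 6 and 4,
    utility noise SD 0.35, seed 0 — is generated and marked synthetic.
    """
    design = worked_example.io_design()
    grid = worked_example.io_grid()
    if data_path is not None and Path(data_path).exists():
        data = read_qsort(data_path, grid=grid)
        return data, design, False
    spec = SyntheticSpec(
        design=design, grid=grid, clusters=_STANDIN_CLUSTERS,
        cluster_sizes=[8, 6, 4], noise_sd=0.35, seed=0,
    )
    data, _ = generate(spec)
    return data, design, True
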