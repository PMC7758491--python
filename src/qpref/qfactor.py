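"""By-person factor analysis of Q-sorts.

Q-factor analysis transposes the usual factor-analytic question: it
correlates *participants* (their whole rank columns) and extracts
components from that participant correlation matrix, so each factor is a
cluster of people who sorted the stimuli similarly.  The pipeline is

1. Pearson correlations between participants' sorts;
2. principal components of that matrix, varimax-rotated (Kaiser
   row-normalization) and sign-oriented;
3. automatic flagging of each factor's defining sorts — a participant is
   flagged on their strongest factor when the loading is significant
   (|loading| > 1.96/sqrt(n_stimuli)) and its square exceeds the sum of
   the squared loadings on every other factor;
4. factor scores per stimulus: the flagged sorts averaged with weights
   loading/(1 - loading^2), standardized to z-scores and, separately,
   rounded back into the forced grid by descending z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import QSortDataset
from .grid import QGrid

__all__ = [
    "QFactorAnalysis",
    "FactorSolution",
    "varimax",
    "participant_correlations",
    "flag_loadings",
    "criteria_report",
    "CriteriaReport",
]

#: default loading-significance threshold multiplier (two-sided 5% level
#: for a correlation based on n_stimuli observations)
SIG_Z = 1.96


def participant_correlations(data: QSortDataset) -> pd.DataFrame:
    """Pearson correlations between participants' rank columns."""
    if data.n_participants < 2:
        raise ValueError("need at least 2 participants")
    # a valid forced sort can never be constant, so variance is positive
    assert np.all(data.ranks.std(axis=0) > 0)
    R = np.corrcoef(data.ranks, rowvar=False)
    return pd.DataFrame(R, index=data.participant_ids, columns=data.participant_ids)


def varimax(loadings: np.ndarray, normalize: bool = True,
            tol: float = 1e-6, max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation with Kaiser row-normalization.

    Maximizes the variance of squared loadings within columns; rows are
    scaled to unit communality during rotation (Kaiser) and scaled back
    afterwards.  Raises on non-convergence.
    """
    L = np.asarray(loadings, dtype=float).copy()
    n, k = L.shape
    if k < 2:
        return L
    h = np.sqrt((L ** 2).sum(axis=1)) if normalize else np.ones(n)
    h[h == 0] = 1.0
    L = L / h[:, None]
    # classical pairwise (planar) rotations: for each column pair the
    # criterion-maximizing angle has a closed form
    for _ in range(max_iter):
        total_rotation = 0.0
        for j in range(k - 1):
            for l in range(j + 1, k):
                x, y = L[:, j], L[:, l]
                u = x * x - y * y
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                num = 2.0 * (u @ v) - 2.0 * A * B / n
                den = (u @ u) - (v @ v) - (A * A - B * B) / n
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) > 1e-12:
                    c, s = np.cos(phi), np.sin(phi)
                    L[:, j], L[:, l] = x * c + y * s, y * c - x * s
                total_rotation += abs(phi)
        if total_rotation < tol:
            break
    else:
        raise RuntimeError(
            f"varimax did not converge in {max_iter} iterations "
            f"(last sweep rotated {total_rotation:.3g} rad)"
        )
    return L * h[:, None]


def flag_loadings(loadings: pd.DataFrame, n_stimuli: int,
                  threshold: float | None = None) -> pd.Series:
    """Assign each participant to at most one defining factor.

    Participant p is flagged on their max-|loading| factor k iff
    |loading_pk| exceeds the significance threshold (default
    1.96/sqrt(n_stimuli)) and loading_pk^2 exceeds the sum of squared
    loadings on all other factors; otherwise the participant is unflagged
    (None).
    """
    if threshold is None:
        threshold = SIG_Z / np.sqrt(n_stimuli)
    flags = {}
    for pid, row in loadings.iterrows():
        k = row.abs().idxmax()
        lk = row[k]
        rest = float((row.drop(k) ** 2).sum())
        flags[pid] = k if (abs(lk) > threshold and lk ** 2 > rest) else None
    return pd.Series(flags, name="factor")


def _grid_round(z: pd.Series, grid: QGrid) -> pd.Series:
    """Assign the grid's rank multiset to stimuli by descending score.

    Ties are broken by position in the index (stimulus ID order), keeping
    the mapping deterministic.
    """
    order = np.argsort(-z.to_numpy(), kind="stable")
    ranks_desc = grid.multiset()[::-1]
    out = np.empty(len(z), dtype=int)
    out[order] = ranks_desc
    return pd.Series(out, index=z.index)


@dataclass
class FactorSolution:
    """Results of a by-person factor analysis.

    Attributes
    ----------
    loadings : DataFrame (participants x factors)
        Rotated, sign-oriented loadings in correlation units.
    flags : Series participant -> factor label or None
    eigenvalues : Series per factor (sums of squared loadings).
    explained_variance : Series per factor (eigenvalue / n_participants).
    zscores : DataFrame (stimuli x factors)
        Continuous factor scores, standardized per factor.
    grid_scores : DataFrame (stimuli x factors)
        z-scores rounded back into the forced grid multiset.
    """

    data: QSortDataset
    loadings: pd.DataFrame
    flags: pd.Series
    eigenvalues: pd.Series
    explained_variance: pd.Series
    zscores: pd.DataFrame
    grid_scores: pd.DataFrame
    rotation: str

    @property
    def factor_names(self) -> list[str]:
        return list(self.loadings.columns)

    def communalities(self) -> pd.Series:
        return (self.loadings ** 2).sum(axis=1)

    def n_flagged(self) -> pd.Series:
        return pd.Series(
            {f: int((self.flags == f).sum()) for f in self.factor_names}
        )

    def summary(self) -> str:
        tab = self.loadings.round(2).astype(str)
        for pid in tab.index:
            f = self.flags[pid]
            if f is not None:
                tab.loc[pid, f] += "*"
        lines = [
            f"By-person factor analysis ({self.rotation} rotation), "
            f"{len(self.factor_names)} factors",
            "",
            tab.to_string(),
            "",
            "Eigenvalue          "
            + "  ".join(f"{v:5.1f}" for v in self.eigenvalues),
            "Explained variance  "
            + "  ".join(f"{v:5.0%}" for v in self.explained_variance),
            f"Cumulative variance {self.explained_variance.sum():.0%}",
            f"Flagged sorts       "
            + "  ".join(f"{self.n_flagged()[f]:5d}" for f in self.factor_names),
        ]
        return "\n".join(lines)


class QFactorAnalysis:
    """Model object: by-person factor analysis of one Q-sort dataset.

    ``QFactorAnalysis(data).fit(n_factors=3)`` returns a
    :class:`FactorSolution`.
    """

    def __init__(self, data: QSortDataset):
        self.data = data
        self.correlations = participant_correlations(data)

    def unrotated_eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the participant correlation matrix, descending."""
        vals = np.linalg.eigvalsh(self.correlations.to_numpy())[::-1]
        return np.clip(vals, 0.0, None)

    def _principal_loadings(self, n_factors: int) -> np.ndarray:
        R = self.correlations.to_numpy()
        vals, vecs = np.linalg.eigh(R)
        order = np.argsort(vals)[::-1][:n_factors]
        return vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))

    def fit(self, n_factors: int, rotate: str = "varimax",
            flag_threshold: float | None = None,
            on_empty_factor: str = "raise") -> FactorSolution:
        n_p = self.data.n_participants
        if not 1 <= n_factors < n_p:
            raise ValueError(f"n_factors must be in [1, {n_p - 1}]")
        if rotate not in ("varimax", "none"):
            raise ValueError("rotate must be 'varimax' or 'none'")
        L = self._principal_loadings(n_factors)
        if rotate == "varimax":
            L = varimax(L)
        # deterministic sign orientation: each factor's loading sum >= 0
        signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
        L = L * signs
        # order factors by explained variance, descending
        ssq = (L ** 2).sum(axis=0)
        L = L[:, np.argsort(-ssq)]

        names = [f"F{k + 1}" for k in range(n_factors)]
        loadings = pd.DataFrame(L, index=self.data.participant_ids, columns=names)
        eigenvalues = (loadings ** 2).sum(axis=0)
        explained = eigenvalues / n_p
        flags = flag_loadings(loadings, self.data.n_stimuli, flag_threshold)
        zscores, grid_scores = self._factor_scores(loadings, flags,
                                                   on_empty_factor)
        return FactorSolution(
            data=self.data, loadings=loadings, flags=flags,
            eigenvalues=eigenvalues, explained_variance=explained,
            zscores=zscores, grid_scores=grid_scores, rotation=rotate,
        )

    def _factor_scores(self, loadings: pd.DataFrame, flags: pd.Series,
                       on_empty_factor: str = "raise"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
        frame = self.data.to_frame()
        z_cols, g_cols = {}, {}
        for f in loadings.columns:
            defining = [p for p in loadings.index if flags[p] == f]
            if not defining:
                if on_empty_factor == "nan":
                    warnings.warn(
                        f"factor {f} has no flagged participants; its scores "
                        "are undefined (NaN)",
                        UserWarning, stacklevel=3,
                    )
                    z_cols[f] = pd.Series(np.nan, index=frame.index)
                    g_cols[f] = pd.Series(np.nan, index=frame.index)
                    continue
                raise ValueError(
                    f"factor {f} has no flagged participants; its scores are "
                    "undefined — reduce n_factors or adjust the flag threshold"
                )
            if len(defining) < 2:
                warnings.warn(
                    f"factor {f} has a single flagged participant; factor "
                    "scores reproduce that sort exactly",
                    UserWarning, stacklevel=3,
                )
            # |loading| = 1 (perfectly correlated defining sorts) would give
            # an infinite weight; clip just inside the unit interval
            lam = np.clip(loadings.loc[defining, f].to_numpy(), -1 + 1e-9, 1 - 1e-9)
            w = lam / (1.0 - lam ** 2)
            avg = frame[defining].to_numpy() @ (w / w.sum())
            z = (avg - avg.mean()) / avg.std()
            z_cols[f] = pd.Series(z, index=frame.index)
            g_cols[f] = _grid_round(z_cols[f], self.data.grid)
        return pd.DataFrame(z_cols), pd.DataFrame(g_cols)


@dataclass
class CriteriaReport:
    """Factor-count diagnostics over candidate solutions."""

    scree: np.ndarray  # unrotated eigenvalues, descending
    kaiser_count: int  # eigenvalues > 1
    cumulative_variance: pd.Series  # per candidate solution size
    flagged_counts: dict[int, pd.Series]  # solution size -> flags per factor
    factors_with_two_flags: pd.Series  # per solution size
    humphrey: dict[int, pd.Series]  # solution size -> rule indicator per factor

    def to_text(self) -> str:
        lines = ["Q-factor extraction criteria", "=" * 32, ""]
        lines.append("Scree (unrotated eigenvalues):")
        lines.append("  " + "  ".join(f"{v:.2f}" for v in self.scree))
        lines.append(f"Kaiser-Guttman count (eigenvalue > 1): {self.kaiser_count}")
        lines.append("")
        for m in self.cumulative_variance.index:
            lines.append(f"--- {m}-factor solution ---")
            lines.append(
                f"  cumulative variance: {self.cumulative_variance[m]:.0%}"
            )
            flags = self.flagged_counts[m]
            lines.append(
                "  flagged sorts per factor: "
                + ", ".join(f"{f}={flags[f]}" for f in flags.index)
            )
            lines.append(
                f"  factors with >=2 flagged sorts: {self.factors_with_two_flags[m]}"
            )
            hum = self.humphrey[m]
            lines.append(
                "  Humphrey's rule satisfied: "
                + ", ".join(f"{f}={'yes' if hum[f] else 'no'}" for f in hum.index)
            )
            lines.append("")
        return "\n".join(lines)


def criteria_report(data: QSortDataset, max_factors: int) -> CriteriaReport:
    """Diagnostics for choosing the number of factors (Qfact.txt-style).

    Reports the scree series, the Kaiser-Guttman count, and — for each
    candidate solution from 1 to ``max_factors`` — the cumulative variance,
    flagged sorts per factor, the number of factors retaining at least two
    defining sorts, and Humphrey's rule (the product of a factor's two
    largest absolute loadings exceeds twice the standard error
    2/sqrt(n_stimuli)).
    """
    fa = QFactorAnalysis(data)
    scree = fa.unrotated_eigenvalues()
    kaiser = int((scree > 1.0).sum())
    max_factors = min(max_factors, data.n_participants - 1)
    cumvar, flagged, two_flags, humphrey = {}, {}, {}, {}
    hum_threshold = 2.0 / np.sqrt(data.n_stimuli)
    for m in range(1, max_factors + 1):
        cumvar[m] = float(scree[:m].sum() / data.n_participants)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sol = fa.fit(m, on_empty_factor="nan")
        loadings, flags = sol.loadings, sol.flags
        counts = pd.Series(
            {f: int((flags == f).sum()) for f in loadings.columns}
        )
        flagged[m] = counts
        two_flags[m] = int((counts >= 2).sum())
        hum = {}
        for f in loadings.columns:
            top2 = loadings[f].abs().nlargest(2).to_numpy()
            hum[f] = bool(np.prod(top2) > hum_threshold)
        humphrey[m] = pd.Series(hum)
    return CriteriaReport(
        scree=scree, kaiser_count=kaiser,
        cumulative_variance=pd.Series(cumvar),
        flagged_counts=flagged,
        factors_with_two_flags=pd.Series(two_flags),
        humphrey=humphrey,
    )
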