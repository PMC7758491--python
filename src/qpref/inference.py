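"""Statistical models of the five-analysis preference/dominance protocol.

* Analysis 1 — overall preference: every participant's ranks pooled into
  one ordered-probit model on the stimulus-level indicators (the forced
  grid removes all subject-level location/scale variation, so no random
  effects are needed), with per-variable Wald chi-square tests and
  likelihood-ratio diagnostics of the proportional-odds (nominal) and
  constant-scale assumptions.
* Analysis 2 — overall dominance: per-participant dominance weights
  compared across variables by OLS and one-way ANOVA.
* Analysis 3 — individual differences: one-way ANOVAs of each factor's
  stimulus scores by each variable's levels.
* Analysis 4 — preference x cluster: ordered probit on the stacked
  per-factor score profiles with variable-by-factor interactions.
* Analysis 5 — dominance x cluster: OLS of the flagged participants'
  weights with variable-by-factor interactions.

Treatment coding throughout, with each variable's reference level being
the first level listed in the design; the reference cluster is the first
factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .data import QSortDataset, VariableDesign
from .ordinal import ConvergenceError, CumulativeLinkModel, CumulativeLinkResults

__all__ = [
    "PreferenceModelResults",
    "fit_ordered_probit",
    "wald_variable_test",
    "lr_variable_test",
    "nominal_test",
    "scale_test",
    "weights_anova",
    "factor_score_anova",
    "preference_by_factor_model",
]


def _level_dummies(levels: pd.Series, variable: str, order: list[str]
                   ) -> pd.DataFrame:
    """Treatment-coded indicators dropping the first (reference) level."""
    cols = {}
    for lv in order[1:]:
        cols[f"{variable}{lv}"] = (levels == lv).astype(float).to_numpy()
    return pd.DataFrame(cols)


def _design_matrix(design: VariableDesign, stimulus_ids: list[str]
                   ) -> pd.DataFrame:
    aligned = design.aligned_to(stimulus_ids)
    parts = [
        _level_dummies(aligned.level_of(v), v, aligned.levels[v])
        for v in aligned.variables
    ]
    X = pd.concat(parts, axis=1)
    X.index = pd.Index(stimulus_ids)
    return X


@dataclass
class PreferenceModelResults:
    """An ordered-probit preference fit plus the term bookkeeping.

    Wraps :class:`CumulativeLinkResults` with the map from design
    variables to their coefficient blocks, so per-variable tests can be
    run without re-deriving term names.
    """

    results: CumulativeLinkResults
    design: VariableDesign
    terms: dict[str, list[str]]  # variable -> coefficient names
    observations: pd.DataFrame  # long-format data behind the fit

    @property
    def llf(self) -> float:
        return self.results.llf

    def coefficient_table(self) -> pd.DataFrame:
        return self.results.coefficient_table()

    def summary(self) -> str:
        return self.results.summary()


def fit_ordered_probit(data: QSortDataset, design: VariableDesign
                       ) -> PreferenceModelResults:
    """Analysis 1: pooled ordered-probit model of overall preference.

    Pools every participant's rank of every stimulus (n_stimuli x
    n_participants observations) and regresses the ordinal rank on the
    stimulus level indicators.
    """
    X_stim = _design_matrix(design, data.stimulus_ids)
    n_s, n_p = data.n_stimuli, data.n_participants
    long = pd.DataFrame(
        {
            "rank": data.ranks.T.ravel(),  # participant-major
            "participant": np.repeat(data.participant_ids, n_s),
            "stimulus": np.tile(data.stimulus_ids, n_p),
        }
    )
    X = pd.concat([X_stim] * n_p, ignore_index=True)
    model = CumulativeLinkModel(long["rank"].to_numpy(), exog=X, link="probit")
    res = model.fit()
    aligned = design.aligned_to(data.stimulus_ids)
    terms = {
        v: [f"{v}{lv}" for lv in aligned.levels[v][1:]] for v in aligned.variables
    }
    return PreferenceModelResults(res, design, terms, pd.concat([long, X], axis=1))


def wald_variable_test(fit: PreferenceModelResults,
                       variable: str | None = None) -> pd.DataFrame:
    """Per-variable joint Wald chi-square tests of the coefficient blocks."""
    variables = [variable] if variable is not None else list(fit.terms)
    rows = []
    for v in variables:
        if v not in fit.terms:
            raise KeyError(f"unknown variable {v!r}")
        W, df, p = fit.results.wald_test(fit.terms[v])
        rows.append({"variable": v, "df": df, "statistic": W, "p": p})
    return pd.DataFrame(rows)


def _refit_without(fit: PreferenceModelResults, variable: str,
                   move_to: str) -> tuple[float, int]:
    """Refit with `variable` moved to the nominal or scale component."""
    X = fit.observations[[c for cols in fit.terms.values() for c in cols]]
    block = fit.terms[variable]
    keep = X.drop(columns=block) if move_to == "nominal" else X
    extra = X[block]
    kwargs = {"nominal_exog": extra} if move_to == "nominal" else {
        "scale_exog": extra
    }
    model = CumulativeLinkModel(
        fit.observations["rank"].to_numpy(), exog=keep,
        link=fit.results.model.link, **kwargs,
    )
    # warm start from the base fit: thresholds and retained betas
    base = fit.results
    start = np.zeros(model.k_params)
    start[: model.k_theta] = base.params[: base.model.k_theta]
    base_beta = base.params_series
    off = model.k_theta + model.k_gamma
    for i, name in enumerate(keep.columns):
        start[off + i] = base_beta[name]
    ext = model.fit(start_params=start)
    added = (
        len(block) * (model.n_cat - 2) if move_to == "nominal" else len(block)
    )
    return ext.llf, added


def _assumption_test(fit: PreferenceModelResults, kind: str,
                     variable: str | None) -> pd.DataFrame:
    variables = [variable] if variable is not None else list(fit.terms)
    rows = []
    for v in variables:
        try:
            llf_ext, df = _refit_without(fit, v, kind)
            lrt = max(2.0 * (llf_ext - fit.llf), 0.0)
            rows.append(
                {"variable": v, "df": df, "statistic": lrt,
                 "p": float(stats.chi2.sf(lrt, df)), "converged": True}
            )
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            rows.append(
                {"variable": v, "df": np.nan, "statistic": np.nan,
                 "p": np.nan, "converged": False, "note": str(exc)}
            )
    return pd.DataFrame(rows)


def nominal_test(fit: PreferenceModelResults,
                 variable: str | None = None) -> pd.DataFrame:
    """Likelihood-ratio test of the proportional-odds assumption.

    Each variable's coefficients are allowed to differ across response
    thresholds; the LRT compares that relaxed fit to the base model.
    """
    return _assumption_test(fit, "nominal", variable)


def scale_test(fit: PreferenceModelResults,
               variable: str | None = None) -> pd.DataFrame:
    """Likelihood-ratio test of the constant-scale assumption.

    Each variable is allowed a multiplicative effect on the latent-scale
    dispersion; the LRT compares that relaxed fit to the base model.
    """
    return _assumption_test(fit, "scale", variable)


def lr_variable_test(fit: PreferenceModelResults,
                     variable: str | None = None) -> pd.DataFrame:
    """Drop-one likelihood-ratio tests per variable (Wald alternative)."""
    variables = [variable] if variable is not None else list(fit.terms)
    X = fit.observations[[c for cols in fit.terms.values() for c in cols]]
    rows = []
    for v in variables:
        sub = X.drop(columns=fit.terms[v])
        res = CumulativeLinkModel(
            fit.observations["rank"].to_numpy(), exog=sub,
            link=fit.results.model.link,
        ).fit()
        lrt = max(2.0 * (fit.llf - res.llf), 0.0)
        df = len(fit.terms[v])
        rows.append(
            {"variable": v, "df": df, "statistic": lrt,
             "p": float(stats.chi2.sf(lrt, df))}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Analyses 2 & 5: linear models of dominance weights
# ---------------------------------------------------------------------------


def _weights_long(weights: pd.DataFrame, factors: pd.Series | None
                  ) -> pd.DataFrame:
    long = weights.stack().rename("weight").reset_index()
    long.columns = ["unit", "variable", "weight"]
    long["variable"] = pd.Categorical(
        long["variable"], categories=list(weights.columns)
    )
    if factors is not None:
        long["factor"] = pd.Categorical(
            [factors[u] for u in long["unit"]],
            categories=sorted({f for f in factors if f is not None}),
        )
    return long


def weights_anova(weights: pd.DataFrame, factors: pd.Series | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS + ANOVA of dominance weights across variables (Analyses 2 & 5).

    Parameters
    ----------
    weights : DataFrame, units x variables
        One dominance weight per (participant, variable); column order
        fixes the treatment coding (first column = reference).
    factors : Series, optional
        Cluster label per unit.  When given, only units with a non-null
        label are kept (the flagged participants) and the model gains
        factor main effects and variable-by-factor interactions
        (reference cluster: first factor label).

    Returns
    -------
    (coefficients, anova) : tuple of DataFrame
        Coefficient table (term, estimate, se, t, p) and the ANOVA table
        (term, df, sum_sq, mean_sq, F, p).
    """
    if factors is not None:
        keep = [u for u in weights.index if factors.get(u) is not None]
        if not keep:
            raise ValueError("no flagged units to model")
        labels = sorted({factors[u] for u in keep})
        counts = {f: sum(factors[u] == f for u in keep) for f in labels}
        empty = [f for f, c in counts.items() if c == 0]
        if empty:
            raise ValueError(f"factors without flagged units: {empty}")
        long = _weights_long(weights.loc[keep], factors)
        model = smf.ols("weight ~ variable * factor", long)
    else:
        long = _weights_long(weights, None)
        model = smf.ols("weight ~ variable", long)
    res = model.fit()
    coef = pd.DataFrame(
        {"term": res.params.index, "estimate": res.params.values,
         "se": res.bse.values, "t": res.tvalues.values,
         "p": res.pvalues.values}
    )
    # readable term labels: variable[T.Texture] -> Texture, etc.
    coef["term"] = (
        coef["term"]
        .str.replace(r"(variable|factor)\[T\.([^\]]+)\]", r"\2", regex=True)
        .str.replace(":", "*", regex=False)
    )
    anova = sm.stats.anova_lm(res).reset_index(names="term")
    anova.columns = ["term", "df", "sum_sq", "mean_sq", "F", "p"]
    anova["term"] = anova["term"].str.replace(":", "*", regex=False)
    return coef, anova


# ---------------------------------------------------------------------------
# Analysis 3: factor-score ANOVA
# ---------------------------------------------------------------------------


def factor_score_anova(scores: pd.DataFrame, design: VariableDesign
                       ) -> pd.DataFrame:
    """One-way ANOVAs of each factor's stimulus scores by each variable.

    For every (factor, variable) pair the factor's per-stimulus scores are
    grouped by the variable's levels; degenerate groupings with zero
    residual variance get ``F = inf`` and are flagged.
    """
    aligned = design.aligned_to(list(scores.index))
    rows = []
    for f in scores.columns:
        y = scores[f].to_numpy(dtype=float)
        for v in aligned.variables:
            levels = aligned.level_of(v)
            groups = [
                y[(levels == lv).to_numpy()] for lv in aligned.levels[v]
            ]
            df1 = len(groups) - 1
            df2 = len(y) - len(groups)
            resid_ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
            if resid_ss == 0.0:
                F, p, degenerate = np.inf, 0.0, True
            else:
                F, p = stats.f_oneway(*groups)
                degenerate = False
            rows.append(
                {"factor": f, "variable": v, "df1": df1, "df2": df2,
                 "F": float(F), "p": float(p), "degenerate": degenerate}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Analysis 4: preference-by-cluster cumulative link model
# ---------------------------------------------------------------------------


def preference_by_factor_model(profiles: pd.DataFrame, design: VariableDesign
                               ) -> tuple[PreferenceModelResults, pd.DataFrame]:
    """Ordered probit of stacked factor profiles with factor interactions.

    ``profiles`` holds one ordinal score per stimulus per factor (stimuli
    x factors; grid-rounded factor scores).  The stacked observations
    (n_stimuli x n_factors rows) are modeled with factor main effects,
    variable main effects and every variable-by-factor interaction; the
    returned table carries the per-interaction joint Wald tests (df =
    (levels-1) x (factors-1)).
    """
    factor_names = list(profiles.columns)
    if len(factor_names) < 2:
        raise ValueError("need at least 2 factors for an interaction model")
    stim = list(profiles.index)
    X_stim = _design_matrix(design, stim)
    aligned = design.aligned_to(stim)

    blocks, y = [], []
    for f in factor_names:
        part = X_stim.copy()
        for g in factor_names[1:]:
            part[f"Factor{g[1:]}" if g.startswith("F") else g] = float(f == g)
        blocks.append(part)
        y.append(profiles[f].to_numpy())
    X = pd.concat(blocks, ignore_index=True)
    y = np.concatenate(y)

    fnames = [c for c in X.columns if c not in X_stim.columns]
    inter_terms: dict[str, list[str]] = {}
    for v in aligned.variables:
        cols = []
        for lv in aligned.levels[v][1:]:
            for fn in fnames:
                name = f"{fn}:{v}{lv}"
                X[name] = X[fn] * X[f"{v}{lv}"]
                cols.append(name)
        inter_terms[f"Factor*{v}"] = cols

    model = CumulativeLinkModel(y, exog=X, link="probit")
    res = model.fit()
    terms = {
        v: [f"{v}{lv}" for lv in aligned.levels[v][1:]] for v in aligned.variables
    }
    terms.update(inter_terms)
    terms["Factor"] = fnames
    fit = PreferenceModelResults(
        res, design, terms,
        pd.concat([pd.DataFrame({"rank": y}), X.reset_index(drop=True)], axis=1),
    )
    wald = pd.DataFrame(
        [
            {"variable": k, "df": d, "statistic": W, "p": p}
            for k in inter_terms
            for W, d, p in [res.wald_test(inter_terms[k])]
        ]
    )
    return fit, wald
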