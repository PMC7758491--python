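"""Cumulative link models for forced-rank responses.

An ordinal response with categories ``c_0 < ... < c_{J-1}`` is modeled
through a latent continuous scale:

    P(Y <= c_j | x) = F( (theta_j + x_nom' gamma_j - x' beta) / exp(z' zeta) )

with strictly increasing thresholds ``theta``, location effects ``beta``
(larger beta -> higher categories), optional *nominal* effects ``gamma_j``
that let a predictor shift each threshold separately (relaxing the
proportional-odds assumption), and optional *scale* effects ``zeta`` that
let a predictor change the dispersion of the latent scale.  ``F`` is the
standard normal CDF (probit) or the logistic CDF.

The base model (no nominal/scale terms) is the ordered probit; the
extended fits exist to support likelihood-ratio tests of the
proportional-odds and constant-scale assumptions, mirroring the
``clm`` / ``nominal_test`` / ``scale_test`` workflow familiar from R's
``ordinal`` package.

Fitting is maximum likelihood with analytic gradients (BFGS plus a Newton
polish); the covariance of the estimates is the inverse observed
information, obtained by finite differences of the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve

__all__ = ["CumulativeLinkModel", "CumulativeLinkResults", "ConvergenceError"]

_LINKS = {
    "probit": (stats.norm.cdf, stats.norm.pdf),
    "logit": (stats.logistic.cdf, stats.logistic.pdf),
}


class ConvergenceError(RuntimeError):
    """Optimization failed to reach a stationary point."""


def _as_matrix(x, n, what):
    if x is None:
        return np.empty((n, 0)), []
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != n:
        raise ValueError(f"{what} has {arr.shape[0]} rows, expected {n}")
    return arr, [f"{what}{i + 1}" for i in range(arr.shape[1])]


class CumulativeLinkModel:
    """Ordinal regression on a latent continuous scale.

    Parameters
    ----------
    endog : array-like
        Ordinal responses; categories are the sorted unique values.
    exog : array-like or DataFrame, optional
        Location design matrix (treatment-coded indicators, no intercept).
    nominal_exog : array-like or DataFrame, optional
        Columns given threshold-specific coefficients.
    scale_exog : array-like or DataFrame, optional
        Columns entering the log-scale of the latent distribution.
    link : {"probit", "logit"}
    """

    def __init__(self, endog, exog=None, nominal_exog=None, scale_exog=None,
                 link: str = "probit"):
        endog = np.asarray(endog)
        self.categories = np.unique(endog)
        if len(self.categories) < 3:
            raise ValueError("need at least 3 ordered response categories")
        lookup = {v: i for i, v in enumerate(self.categories.tolist())}
        self.codes = np.array([lookup[v] for v in endog.tolist()])
        self.nobs = len(self.codes)
        self.n_cat = len(self.categories)
        if link not in _LINKS:
            raise ValueError(f"unknown link {link!r}")
        self.link = link
        self._cdf, self._pdf = _LINKS[link]
        self.exog, self.exog_names = _as_matrix(exog, self.nobs, "x")
        self.nominal_exog, self.nominal_names = _as_matrix(
            nominal_exog, self.nobs, "nom"
        )
        self.scale_exog, self.scale_names = _as_matrix(scale_exog, self.nobs, "sc")

    # -- parameter packing --------------------------------------------------

    @property
    def k_theta(self) -> int:
        return self.n_cat - 1

    @property
    def k_gamma(self) -> int:
        return self.nominal_exog.shape[1] * self.k_theta

    @property
    def k_beta(self) -> int:
        return self.exog.shape[1]

    @property
    def k_zeta(self) -> int:
        return self.scale_exog.shape[1]

    @property
    def k_params(self) -> int:
        return self.k_theta + self.k_gamma + self.k_beta + self.k_zeta

    @property
    def param_names(self) -> list[str]:
        cats = self.categories
        names = [f"{cats[j]}|{cats[j + 1]}" for j in range(self.k_theta)]
        for nm in self.nominal_names:
            names += [f"{nm}.{cats[j]}|{cats[j + 1]}" for j in range(self.k_theta)]
        names += list(self.exog_names)
        names += [f"scale.{nm}" for nm in self.scale_names]
        return names

    def _unpack(self, params):
        kt, kg, kb = self.k_theta, self.k_gamma, self.k_beta
        theta = params[:kt]
        gamma = params[kt:kt + kg].reshape(self.nominal_exog.shape[1], kt)
        beta = params[kt + kg:kt + kg + kb]
        zeta = params[kt + kg + kb:]
        return theta, gamma, beta, zeta

    # -- likelihood ---------------------------------------------------------

    def _eta_parts(self, params):
        theta, gamma, beta, zeta = self._unpack(params)
        c = self.codes
        xb = self.exog @ beta if self.k_beta else np.zeros(self.nobs)
        log_sigma = self.scale_exog @ zeta if self.k_zeta else np.zeros(self.nobs)
        sigma = np.exp(log_sigma)

        has_upper = c < self.n_cat - 1
        has_lower = c > 0
        ju = np.where(has_upper, c, 0)
        jl = np.where(has_lower, c - 1, 0)

        def threshold(jidx):
            t = theta[jidx]
            if self.nominal_exog.shape[1]:
                t = t + np.einsum("ik,ik->i", self.nominal_exog, gamma[:, jidx].T)
            return t

        eta_u = (threshold(ju) - xb) / sigma
        eta_l = (threshold(jl) - xb) / sigma
        return eta_u, eta_l, has_upper, has_lower, ju, jl, sigma

    def loglike(self, params) -> float:
        eta_u, eta_l, has_u, has_l, *_ = self._eta_parts(params)
        Fu = np.where(has_u, self._cdf(eta_u), 1.0)
        Fl = np.where(has_l, self._cdf(eta_l), 0.0)
        p = np.clip(Fu - Fl, 1e-300, None)
        return float(np.log(p).sum())

    def score(self, params) -> np.ndarray:
        """Analytic gradient of the log-likelihood."""
        eta_u, eta_l, has_u, has_l, ju, jl, sigma = self._eta_parts(params)
        Fu = np.where(has_u, self._cdf(eta_u), 1.0)
        Fl = np.where(has_l, self._cdf(eta_l), 0.0)
        p = np.clip(Fu - Fl, 1e-300, None)
        du = np.where(has_u, self._pdf(np.where(has_u, eta_u, 0.0)), 0.0) / p
        dl = np.where(has_l, self._pdf(np.where(has_l, eta_l, 0.0)), 0.0) / p

        kt = self.k_theta
        grad = np.zeros(self.k_params)
        inv_sigma = 1.0 / sigma
        # thresholds
        np.add.at(grad, ju[has_u], (du * inv_sigma)[has_u])
        np.add.at(grad, jl[has_l], -(dl * inv_sigma)[has_l])
        # nominal coefficients
        q = self.nominal_exog.shape[1]
        if q:
            g = grad[kt:kt + self.k_gamma].reshape(q, kt)
            for k in range(q):
                xk = self.nominal_exog[:, k]
                np.add.at(g[k], ju[has_u], (du * xk * inv_sigma)[has_u])
                np.add.at(g[k], jl[has_l], -(dl * xk * inv_sigma)[has_l])
            grad[kt:kt + self.k_gamma] = g.ravel()
        # location
        if self.k_beta:
            w = (du - dl) * inv_sigma
            grad[kt + self.k_gamma:kt + self.k_gamma + self.k_beta] = -(
                self.exog.T @ w
            )
        # scale
        if self.k_zeta:
            su = np.where(has_u, du * np.where(has_u, eta_u, 0.0), 0.0)
            sl = np.where(has_l, dl * np.where(has_l, eta_l, 0.0), 0.0)
            grad[-self.k_zeta:] = -(self.scale_exog.T @ (su - sl))
        return grad

    # -- fitting ------------------------------------------------------------

    def start_params(self) -> np.ndarray:
        counts = np.bincount(self.codes, minlength=self.n_cat)
        cum = np.cumsum(counts)[:-1] / self.nobs
        cum = np.clip(cum, 1e-4, 1 - 1e-4)
        theta0 = (
            stats.norm.ppf(cum) if self.link == "probit" else stats.logistic.ppf(cum)
        )
        return np.concatenate(
            [theta0, np.zeros(self.k_params - self.k_theta)]
        )

    def _hessian_fd(self, params, eps: float = 1e-5) -> np.ndarray:
        """Observed information via central differences of the gradient."""
        k = len(params)
        H = np.zeros((k, k))
        for i in range(k):
            step = np.zeros(k)
            step[i] = eps * max(1.0, abs(params[i]))
            H[i] = (self.score(params + step) - self.score(params - step)) / (
                2 * step[i]
            )
        return -(H + H.T) / 2.0  # symmetrized negative Hessian of ll

    def fit(self, start_params=None, gtol: float = 1e-7, maxiter: int = 500
            ) -> "CumulativeLinkResults":
        x0 = np.asarray(start_params, float) if start_params is not None \
            else self.start_params()

        def neg(params):
            return -self.loglike(params), -self.score(params)

        res = optimize.minimize(
            neg, x0, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        params = res.x
        # Newton polish toward a tight stationary point
        for _ in range(25):
            g = self.score(params)
            if np.abs(g).max() < 1e-8:
                break
            H = self._hessian_fd(params)
            # lstsq tolerates the near-singular Hessians of nearly
            # separated extended models; the line search guards the step
            step, *_ = np.linalg.lstsq(H, g, rcond=None)
            ll0 = self.loglike(params)
            scale_step = 1.0
            for _ in range(30):
                cand = params + scale_step * step
                if self.loglike(cand) >= ll0 - 1e-12:
                    params = cand
                    break
                scale_step /= 2.0
            else:
                break
        grad_norm = float(np.abs(self.score(params)).max())
        if grad_norm > 1e-4:
            raise ConvergenceError(
                f"gradient sup-norm {grad_norm:.2e} after {res.nit} BFGS "
                f"iterations and Newton polish; status={res.status} "
                f"({res.message})"
            )
        theta = self._unpack(params)[0]
        if self.nominal_exog.shape[1] == 0 and np.any(np.diff(theta) <= 0):
            raise ConvergenceError(f"thresholds not increasing: {theta}")
        H = self._hessian_fd(params)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((len(params), len(params)), np.nan)
        return CumulativeLinkResults(
            model=self, params=params, cov_params=cov,
            llf=self.loglike(params), grad_norm=grad_norm,
            converged=grad_norm <= 1e-6, n_iter=int(res.nit),
        )


@dataclass
class CumulativeLinkResults:
    """MLE results for a cumulative link model."""

    model: CumulativeLinkModel
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    grad_norm: float
    converged: bool
    n_iter: int
    _names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self._names = self.model.param_names

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self._names)

    @property
    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self._names)

    @property
    def zvalues(self) -> pd.Series:
        return self.params_series / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues)), index=self._names
        )

    @property
    def df_model(self) -> int:
        return self.model.k_params

    def coefficient_table(self, include_thresholds: bool = False) -> pd.DataFrame:
        """Tidy table of estimates, SEs, z statistics and p-values."""
        tab = pd.DataFrame(
            {"term": self._names, "estimate": self.params,
             "se": self.bse.values, "z": self.zvalues.values,
             "p": self.pvalues.values}
        )
        if not include_thresholds:
            kt = self.model.k_theta
            tab = tab.iloc[kt + self.model.k_gamma:].reset_index(drop=True)
        return tab

    def wald_test(self, terms: list[str]) -> tuple[float, int, float]:
        """Joint Wald chi-square test that the named coefficients are zero."""
        idx = [self._names.index(t) for t in terms]
        b = self.params[idx]
        V = self.cov_params[np.ix_(idx, idx)]
        try:
            W = float(b @ solve(V, b, assume_a="sym"))
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular covariance block for terms {terms}"
            ) from None
        df = len(idx)
        return W, df, float(stats.chi2.sf(W, df))

    def summary(self) -> str:
        lines = [
            "Cumulative link model ({} link)".format(self.model.link),
            f"  observations: {self.model.nobs}   categories: {self.model.n_cat}",
            f"  log-likelihood: {self.llf:.3f}   parameters: {self.df_model}",
            f"  converged: {self.converged} (|grad| {self.grad_norm:.2e})",
            "",
            self.coefficient_table(include_thresholds=True)
            .to_string(index=False, float_format=lambda v: f"{v:8.4f}"),
        ]
        return "\n".join(lines)
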