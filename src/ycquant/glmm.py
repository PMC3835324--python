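"""Random-intercept logistic regression by maximum likelihood.

Binary outcomes measured on many structures within few animals are
correlated within animal; the standard remedy is a mixed-effects logistic
model with a Gaussian random intercept per animal:

    y_ij | u_i ~ Bernoulli(expit(x_ij' b + u_i)),   u_i ~ N(0, sigma^2)

The marginal likelihood integrates each cluster's contribution over u_i;
the integral is one-dimensional and is evaluated here with Gauss-Hermite
quadrature (fixed nodes, default 25), then maximised over (b, log sigma)
with L-BFGS-B.  Standard errors come from the inverse of a central-
difference Hessian of the negative log-likelihood at the optimum; fixed-
effect p-values are Wald z tests, the convention of mixed-model software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = ["MixedLogit", "MixedLogitResults", "SeparationError"]


class SeparationError(RuntimeError):
    """Outcome classes are (quasi-)separated; the MLE is not identified."""


def _loglike(theta: np.ndarray, suff: list[tuple], nodes: np.ndarray, weights: np.ndarray) -> float:
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = math.exp(log_sigma)
    total = 0.0
    # u = sqrt(2)*sigma*t integrates N(0, sigma^2) against exp(-t^2) GH weights
    u = math.sqrt(2.0) * sigma * nodes  # (q,)
    logw = np.log(weights) - 0.5 * math.log(math.pi)
    for Xu, n_v, s_v in suff:
        # sufficient statistics per distinct design row:
        # log p(y | u) = sum_v [s_v (eta_v+u) - n_v log(1+e^{eta_v+u})]
        lin = (Xu @ beta)[:, None] + u[None, :]  # (v, q)
        ll = (s_v[:, None] * lin - n_v[:, None] * np.logaddexp(0.0, lin)).sum(axis=0)
        total += special.logsumexp(ll + logw)
    return total


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


@dataclass
class MixedLogitResults:
    """Fitted random-intercept logistic model."""

    params: np.ndarray  # fixed effects (log-odds scale)
    bse: np.ndarray
    sigma: float  # random-intercept SD
    loglike: float
    n_obs: int
    n_groups: int
    exog_names: list[str]
    converged: bool

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def summary(self) -> str:
        lines = [
            "Mixed-effects logistic regression (random intercept, Gauss-Hermite ML)",
            f"  observations: {self.n_obs}   groups: {self.n_groups}   "
            f"log-likelihood: {self.loglike:.3f}",
            f"  random-intercept SD: {self.sigma:.4f}",
            f"  {'term':<16}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>10}",
        ]
        for name, b, se, z, p in zip(self.exog_names, self.params, self.bse,
                                     self.zvalues, self.pvalues):
            lines.append(f"  {name:<16}{b:>10.4f}{se:>10.4f}{z:>8.2f}{p:>10.4g}")
        return "\n".join(lines)


class MixedLogit:
    """Random-intercept logistic model for clustered binary outcomes.

    Parameters
    ----------
    endog : (n,) 0/1 outcomes.
    exog : (n, p) design matrix including the intercept column.
    groups : (n,) cluster labels (one random intercept per unique label).
    exog_names : column names for reporting.
    n_quad : number of Gauss-Hermite nodes.
    """

    def __init__(self, endog, exog, groups, exog_names=None, n_quad: int = 25):
        self.y = np.asarray(endog, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise ValueError("endog/exog length mismatch")
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        self.group_idx = [np.flatnonzero(groups == g) for g in uniq]
        self.n_groups = uniq.size
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(self.X.shape[1])
        ]
        nodes, weights = special.roots_hermite(n_quad)
        self._nodes, self._weights = nodes, weights
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        if len(set(self.y)) < 2:
            raise SeparationError("all outcomes identical; model not identified")
        # per-cluster sufficient statistics over distinct design rows
        self._suff = []
        for idx in self.group_idx:
            Xu, inv = np.unique(self.X[idx], axis=0, return_inverse=True)
            self._suff.append(
                (Xu, np.bincount(inv).astype(float), np.bincount(inv, weights=self.y[idx]))
            )

    def fit(self) -> MixedLogitResults:
        p = self.X.shape[1]

        def nll(theta):
            return -_loglike(theta, self._suff, self._nodes, self._weights)

        x0 = np.zeros(p + 1)
        x0[0] = math.log(max(self.y.mean(), 1e-3) / max(1 - self.y.mean(), 1e-3))
        x0[-1] = math.log(0.5)
        bounds = [(-20.0, 20.0)] * p + [(-8.0, 3.0)]
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        beta = res.x[:p]
        if np.any(np.abs(beta) > 15.0):
            raise SeparationError(
                "fixed-effect estimate diverged (|coef| > 15): outcomes are quasi-separated"
            )
        H = _numerical_hessian(nll, res.x)
        try:
            cov = np.linalg.inv(H)
            bse = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)
        if not np.all(np.isfinite(bse)) or np.any(bse == 0):
            raise SeparationError("singular information matrix; standard errors undefined")
        return MixedLogitResults(
            params=beta,
            bse=bse,
            sigma=math.exp(res.x[-1]),
            loglike=-res.fun,
            n_obs=self.y.size,
            n_groups=self.n_groups,
            exog_names=self.exog_names,
            converged=bool(res.success),
        )
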