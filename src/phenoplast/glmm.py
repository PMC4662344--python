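"""Binomial GLMM (logit link) with one random intercept, via the Laplace
approximation.

Used for the breeder-density trend: occupied nest boxes out of boxes
available, per farm-year, with a farm random intercept. Because the random
effects are independent across groups, the Laplace-approximate marginal
likelihood factorises by group; the inner mode search is a vectorised Newton
iteration over all group effects simultaneously, nested inside a quasi-Newton
search over the fixed effects and log random-effect standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

#: Linear predictors beyond this magnitude indicate (quasi-)complete
#: separation: fitted probabilities are numerically 0/1.
SEPARATION_ETA = 30.0


@dataclass
class FittedBinomialGLMM:
    beta: pd.Series
    se: pd.Series
    var_group: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    group_modes: pd.Series

    def ztable(self) -> pd.DataFrame:
        z = self.beta / self.se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "z": z, "p": p}
        )


def _laplace_negloglik(
    params: np.ndarray,
    X: np.ndarray,
    succ: np.ndarray,
    trials: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    const: float,
) -> tuple[float, np.ndarray]:
    beta = params[:-1]
    sigma2 = float(np.exp(2.0 * params[-1]))
    offset = X @ beta
    b = np.zeros(n_groups)
    # Newton iterations for the per-group conditional modes (vectorised)
    for _ in range(50):
        eta = offset + b[codes]
        mu = special.expit(eta)
        w = trials * mu * (1.0 - mu)
        score = np.bincount(codes, weights=succ - trials * mu, minlength=n_groups)
        score -= b / sigma2
        info = np.bincount(codes, weights=w, minlength=n_groups) + 1.0 / sigma2
        step = score / info
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = offset + b[codes]
    if np.max(np.abs(eta)) > SEPARATION_ETA:
        raise FloatingPointError("separation")
    mu = special.expit(eta)
    ll_cond = float(np.sum(succ * eta - trials * np.log1p(np.exp(eta)))) + const
    w = trials * mu * (1.0 - mu)
    curv = np.bincount(codes, weights=w, minlength=n_groups) + 1.0 / sigma2
    ll = (
        ll_cond
        - 0.5 * float(b @ b) / sigma2
        - 0.5 * n_groups * np.log(sigma2)
        - 0.5 * float(np.sum(np.log(curv)))
    )
    return -ll, b


def fit_binomial_glmm(
    data: pd.DataFrame,
    successes: str,
    trials: str,
    fixed: Sequence[str],
    group: str,
) -> FittedBinomialGLMM:
    """Laplace-approximate ML fit of a logit-link binomial mixed model.

    Parameters
    ----------
    successes, trials
        Column names for the binomial numerator and denominator
        (``trials >= successes >= 0`` rowwise).
    fixed
        Numeric fixed-effect columns (an intercept is always included).
    group
        Grouping factor for the single random intercept.
    """
    cols = [successes, trials, group, *fixed]
    sub = data[cols].dropna().reset_index(drop=True)
    succ = sub[successes].to_numpy(dtype=float)
    tri = sub[trials].to_numpy(dtype=float)
    if np.any(succ < 0) or np.any(tri < succ):
        raise ValueError("need trials >= successes >= 0 in every row")
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in fixed]
    )
    names = ["Intercept"] + list(fixed)
    codes, levels = pd.factorize(sub[group], sort=True)
    n_groups = len(levels)
    const = float(
        np.sum(
            special.gammaln(tri + 1)
            - special.gammaln(succ + 1)
            - special.gammaln(tri - succ + 1)
        )
    )

    def objective(params: np.ndarray) -> float:
        try:
            nll, _ = _laplace_negloglik(params, X, succ, tri, codes, n_groups, const)
        except FloatingPointError:
            return np.inf
        return nll

    x0 = np.zeros(X.shape[1] + 1)
    x0[0] = special.logit(np.clip(np.sum(succ) / np.sum(tri), 1e-6, 1 - 1e-6))
    x0[-1] = np.log(0.5)
    res = optimize.minimize(
        objective, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500}
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(
            "binomial GLMM failed: likelihood diverged (possible complete separation)"
        )
    nll, b_modes = _laplace_negloglik(res.x, X, succ, tri, codes, n_groups, const)
    # a fixed-effect linear predictor beyond ~15 means fitted probabilities
    # are numerically 0/1: (quasi-)complete separation
    if np.max(np.abs(X @ res.x[:-1])) > 15.0:
        raise RuntimeError("complete separation detected in binomial GLMM")

    # SEs from the numerical Hessian of the Laplace marginal likelihood
    k = len(res.x)
    step = 1e-5 * np.maximum(1.0, np.abs(res.x))
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = res.x.copy(); pp[i] += step[i]; pp[j] += step[j]
            pm = res.x.copy(); pm[i] += step[i]; pm[j] -= step[j]
            mp = res.x.copy(); mp[i] -= step[i]; mp[j] += step[j]
            mm = res.x.copy(); mm[i] -= step[i]; mm[j] -= step[j]
            H[i, j] = H[j, i] = (
                objective(pp) - objective(pm) - objective(mp) + objective(mm)
            ) / (4 * step[i] * step[j])
    try:
        cov = np.linalg.inv(H)
        se_beta = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
    except np.linalg.LinAlgError:
        se_beta = np.full(k - 1, np.nan)

    return FittedBinomialGLMM(
        beta=pd.Series(res.x[:-1], index=names),
        se=pd.Series(se_beta, index=names),
        var_group=float(np.exp(2.0 * res.x[-1])),
        loglik=-float(nll),
        n_obs=len(sub),
        n_groups=n_groups,
        converged=bool(res.success),
        group_modes=pd.Series(b_modes, index=levels),
    )
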