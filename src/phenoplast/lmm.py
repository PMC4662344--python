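"""Linear mixed models with crossed random intercepts and correlated slopes.

The engine fits

    y = X beta + sum_k Z_k u_k + e,     u_k ~ N(0, Sigma_k (x) I),  e ~ N(0, sigma^2 I)

by profiled maximum likelihood or REML. Each random term contributes either a
scalar intercept variance or a 2x2 intercept/slope covariance per level of its
grouping factor. Following the standard relative-covariance-factor approach,
Sigma_k = sigma^2 * Lambda_k Lambda_k', and the criterion is profiled over
beta and sigma^2 so the optimiser only searches the (bounded) Cholesky
entries of the Lambda_k blocks. Crossed factors are handled generically via
sparse indicator blocks, so year, farm and individual effects can coexist.

All heavy per-iteration work reduces to one Cholesky factorisation of the
q x q system matrix M = I + Lambda' Z'Z Lambda, where q is the total number
of random-effect columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

logger = logging.getLogger(__name__)

#: Seed for the restart jitter used when the first optimisation fails.
RESTART_SEED = 20230401
#: Relative variance below which a component is reported as exactly zero.
BOUNDARY_TOL = 1e-6

DfMethod = Literal["satterthwaite", "residual"]


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomTerm:
    """A random term: intercept per level of ``factor``, optionally with a
    correlated random slope on the (numeric) covariate ``slope``."""

    factor: str
    slope: str | None = None

    @property
    def dim(self) -> int:
        return 1 if self.slope is None else 2

    @property
    def label(self) -> str:
        return self.factor if self.slope is None else f"{self.factor}:{self.slope}"


@dataclass(frozen=True)
class ModelSpec:
    """Response, fixed terms and random terms of one mixed model.

    Fixed terms are column names, ``a:b`` products, or ``a*b`` shorthand for
    ``a + b + a:b``; an intercept is always included. All referenced columns
    must be numeric (encode categories as indicators first).
    """

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[RandomTerm, ...] = ()
    reml: bool = True

    def __init__(
        self,
        response: str,
        fixed: Sequence[str] = (),
        random: Sequence[RandomTerm | str] = (),
        reml: bool = True,
    ):
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "fixed", tuple(expand_terms(fixed)))
        object.__setattr__(self, "random", tuple(_coerce_random(random)))
        object.__setattr__(self, "reml", reml)

    def drop_fixed(self, term: str) -> "ModelSpec":
        if term not in self.fixed:
            raise ValueError(f"term {term!r} not in model")
        return ModelSpec(
            self.response,
            tuple(t for t in self.fixed if t != term),
            self.random,
            self.reml,
        )

    def with_reml(self, reml: bool) -> "ModelSpec":
        return ModelSpec(self.response, self.fixed, self.random, reml)

    def columns(self) -> list[str]:
        cols: list[str] = [self.response]
        for t in self.fixed:
            cols.extend(t.split(":"))
        for rt in self.random:
            cols.append(rt.factor)
            if rt.slope is not None:
                cols.append(rt.slope)
        seen: list[str] = []
        for c in cols:
            if c not in ("1",) and c not in seen:
                seen.append(c)
        return seen


def expand_terms(terms: Iterable[str]) -> list[str]:
    """Expand ``a*b`` into ``a, b, a:b``; drop ``1``; keep first occurrence."""
    out: list[str] = []
    for raw in terms:
        raw = raw.strip()
        if raw in ("", "1"):
            continue
        if "*" in raw:
            parts = [p.strip() for p in raw.split("*")]
            expanded = parts + [":".join(parts)]
        else:
            expanded = [raw]
        for t in expanded:
            if t not in out:
                out.append(t)
    return out


def _coerce_random(random: Sequence[RandomTerm | str]) -> list[RandomTerm]:
    out: list[RandomTerm] = []
    for r in random:
        if isinstance(r, RandomTerm):
            out.append(r)
        elif isinstance(r, str):
            # "factor" or "factor:slope(cov)" compact syntax
            if ":slope(" in r and r.endswith(")"):
                fac, cov = r.split(":slope(", 1)
                out.append(RandomTerm(fac, cov[:-1]))
            else:
                out.append(RandomTerm(r))
        else:
            raise TypeError(f"not a random term: {r!r}")
    return out


def standardize(x: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Centre and scale to unit sample (n-1) standard deviation.

    Returns ``(z, mean, sd)`` so the transform can be inverted when reporting
    effects on the original scale.
    """
    x = np.asarray(x, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant covariate")
    return (x - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    term: RandomTerm
    levels: np.ndarray
    offset: int

    @property
    def dim(self) -> int:
        return self.term.dim

    @property
    def n_cols(self) -> int:
        return self.dim * len(self.levels)


class Design:
    """Precomputed design matrices and cross-products for one model/data pair."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        cols = spec.columns()
        missing_cols = [c for c in cols if c not in data.columns]
        if missing_cols:
            raise KeyError(f"model references missing column(s): {missing_cols}")
        sub = data[cols]
        keep = ~sub.isna().any(axis=1)
        self.n_dropped = int((~keep).sum())
        if self.n_dropped:
            logger.info(
                "dropped %d of %d rows with missing model variables",
                self.n_dropped,
                len(sub),
            )
        sub = sub.loc[keep]
        self.data = sub.reset_index(drop=True)
        self.spec = spec
        self.y = self.data[spec.response].to_numpy(dtype=float)
        self.n = len(self.y)

        self.fixed_names = ["Intercept"] + list(spec.fixed)
        Xcols = [np.ones(self.n)]
        for term in spec.fixed:
            Xcols.append(self._term_column(term))
        self.X = np.column_stack(Xcols)
        self.p = self.X.shape[1]
        if self.n <= self.p:
            raise ValueError(f"n_obs={self.n} must exceed n fixed parameters={self.p}")
        self._check_rank()

        self.blocks: list[_Block] = []
        offset = 0
        zparts = []
        for rt in spec.random:
            codes, levels = pd.factorize(self.data[rt.factor], sort=True)
            if len(levels) < 2:
                raise ValueError(f"grouping factor {rt.factor!r} needs >= 2 levels")
            block = _Block(term=rt, levels=np.asarray(levels), offset=offset)
            self.blocks.append(block)
            zparts.append(self._z_block(rt, codes, len(levels)))
            offset += block.n_cols
        self.q = offset
        if self.blocks:
            Z = sparse.hstack(zparts, format="csr")
            self.Z = Z
            self.ZtZ = np.asarray((Z.T @ Z).todense())
            self.ZtX = np.asarray(Z.T @ self.X)
            self.Zty = np.asarray(Z.T @ self.y)
        else:
            self.Z = None
            self.ZtZ = np.zeros((0, 0))
            self.ZtX = np.zeros((0, self.p))
            self.Zty = np.zeros(0)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self._build_theta_pattern()

    # -- helpers ----------------------------------------------------------

    def _term_column(self, term: str) -> np.ndarray:
        parts = term.split(":")
        col = np.ones(self.n)
        for p_ in parts:
            values = self.data[p_]
            if not pd.api.types.is_numeric_dtype(values):
                raise TypeError(
                    f"fixed-term column {p_!r} is not numeric; encode it first"
                )
            col = col * values.to_numpy(dtype=float)
        return col

    def _check_rank(self) -> None:
        _, R = np.linalg.qr(self.X)
        d = np.abs(np.diag(R))
        bad = d < max(self.n, self.p) * np.finfo(float).eps * (d.max() if d.size else 1.0)
        if bad.any():
            names = [self.fixed_names[i] for i in np.flatnonzero(bad)]
            raise np.linalg.LinAlgError(
                f"fixed design is rank deficient; collinear term(s): {names}"
            )

    def _z_block(self, rt: RandomTerm, codes: np.ndarray, n_levels: int):
        rows = np.arange(self.n)
        if rt.slope is None:
            return sparse.csr_matrix(
                (np.ones(self.n), (rows, codes)), shape=(self.n, n_levels)
            )
        slope = self.data[rt.slope].to_numpy(dtype=float)
        # columns interleaved per level: [lvl0_int, lvl0_slope, lvl1_int, ...]
        r = np.repeat(rows, 2)
        c = np.empty(2 * self.n, dtype=int)
        c[0::2] = 2 * codes
        c[1::2] = 2 * codes + 1
        d = np.empty(2 * self.n)
        d[0::2] = 1.0
        d[1::2] = slope
        return sparse.csr_matrix((d, (r, c)), shape=(self.n, 2 * n_levels))

    def _build_theta_pattern(self) -> None:
        """Sparse pattern of Lambda plus the map from theta to its data."""
        rows, cols, tmap = [], [], []
        bounds: list[tuple[float | None, float | None]] = []
        theta0: list[float] = []
        t_index = 0
        self.theta_slices: list[slice] = []
        for block in self.blocks:
            if block.dim == 1:
                self.theta_slices.append(slice(t_index, t_index + 1))
                for lvl in range(len(block.levels)):
                    j = block.offset + lvl
                    rows.append(j)
                    cols.append(j)
                    tmap.append(t_index)
                bounds.append((0.0, None))
                theta0.append(1.0)
                t_index += 1
            else:
                # per-level 2x2 lower-triangular block [[a, 0], [b, c]]
                self.theta_slices.append(slice(t_index, t_index + 3))
                for lvl in range(len(block.levels)):
                    j = block.offset + 2 * lvl
                    rows.extend([j, j + 1, j + 1])
                    cols.extend([j, j, j + 1])
                    tmap.extend([t_index, t_index + 1, t_index + 2])
                bounds.extend([(0.0, None), (None, None), (0.0, None)])
                theta0.extend([1.0, 0.0, 1.0])
                t_index += 3
        self.n_theta = t_index
        self.theta_bounds = bounds
        self.theta0 = np.asarray(theta0)
        self._lam_rows = np.asarray(rows, dtype=int)
        self._lam_cols = np.asarray(cols, dtype=int)
        self._lam_tmap = np.asarray(tmap, dtype=int)
        # positions of Lambda entries governed by each theta coordinate,
        # used by the analytic gradient
        self._pattern = [
            (self._lam_rows[self._lam_tmap == i], self._lam_cols[self._lam_tmap == i])
            for i in range(t_index)
        ]

    def lambda_matrix(self, theta: np.ndarray):
        """Relative Cholesky factor Lambda; dense below ~500 columns (sparse
        construction overhead dominates small problems)."""
        data = np.asarray(theta, dtype=float)[self._lam_tmap]
        if self.q <= 500:
            lam = np.zeros((self.q, self.q))
            lam[self._lam_rows, self._lam_cols] = data
            return lam
        return sparse.csr_matrix(
            (data, (self._lam_rows, self._lam_cols)), shape=(self.q, self.q)
        )


def build_design(data: pd.DataFrame, spec: ModelSpec) -> Design:
    """Validate and assemble the fixed design and per-term random blocks."""
    return Design(data, spec)


# ---------------------------------------------------------------------------
# Profiled criterion
# ---------------------------------------------------------------------------

_LOG2PI = float(np.log(2.0 * np.pi))


def _profile(design: Design, theta: np.ndarray) -> SimpleNamespace:
    """GLS solve + determinants at a given theta (sigma^2 and beta profiled)."""
    n, p = design.n, design.p
    if design.q:
        Lam = design.lambda_matrix(theta)
        LtZtZ = Lam.T @ design.ZtZ  # q x q dense
        A = np.asarray((Lam.T @ LtZtZ.T).T)  # Lambda' Z'Z Lambda
        M = A + np.eye(design.q)
        L = np.linalg.cholesky(M)
        cZX = solve_triangular(L, np.asarray(Lam.T @ design.ZtX), lower=True)
        cZy = solve_triangular(L, np.asarray(Lam.T @ design.Zty), lower=True)
        XtVX = design.XtX - cZX.T @ cZX
        XtVy = design.Xty - cZX.T @ cZy
        ytVy = design.yty - cZy @ cZy
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(L))))
    else:
        L = cZy = None
        XtVX = design.XtX
        XtVy = design.Xty
        ytVy = design.yty
        logdet_M = 0.0
    cX = cho_factor(XtVX, lower=True)
    beta = cho_solve(cX, XtVy)
    logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(cX[0]))))
    r2 = max(float(ytVy - beta @ XtVy), 1e-300)
    dev_ml = logdet_M + n * (1.0 + _LOG2PI + np.log(r2 / n))
    dev_reml = (
        logdet_M + logdet_XtVX + (n - p) * (1.0 + _LOG2PI + np.log(r2 / (n - p)))
    )
    return SimpleNamespace(
        beta=beta,
        r2=r2,
        XtVX=XtVX,
        cX=cX,
        L=L,
        dev_ml=dev_ml,
        dev_reml=dev_reml,
        logdet_M=logdet_M,
        logdet_XtVX=logdet_XtVX,
        theta=np.asarray(theta, dtype=float),
    )


def restricted_loglik(design: Design, theta: np.ndarray, sigma2: float) -> float:
    """Exact (unprofiled-in-sigma^2) REML log-likelihood at given parameters."""
    prof = _profile(design, theta)
    n, p = design.n, design.p
    return -0.5 * (
        prof.logdet_M
        + prof.logdet_XtVX
        + (n - p) * (np.log(sigma2) + _LOG2PI)
        + prof.r2 / sigma2
    )


def _dev_and_grad(
    design: Design, theta: np.ndarray, reml: bool
) -> tuple[float, np.ndarray]:
    """Profiled deviance and its analytic gradient with respect to theta.

    With V0 = I + Z Lambda Lambda' Z' and P the REML projection, the
    derivative of the deviance along one Cholesky coordinate theta_i is

        tr(B dV0_i) - c * (w' dA_i w) / r2,   B = Z'PZ (REML) or Z'V0^-1 Z (ML)

    with c = n - p (REML) or n (ML). Because each dLambda_i touches only the
    per-level 2x2 diagonal blocks, only those blocks of B are ever needed;
    they come from one triangular solve against the system Cholesky factor,
    so the gradient costs roughly one extra factorisation, independent of the
    number of theta coordinates.
    """
    prof = _profile(design, theta)
    dev = prof.dev_reml if reml else prof.dev_ml
    n, p = design.n, design.p
    Lam = design.lambda_matrix(theta)
    T1 = np.asarray(Lam.T @ design.ZtZ)  # Lambda' Z'Z
    S = solve_triangular(prof.L, T1, lower=True)  # L^-1 Lambda' Z'Z
    cZX = solve_triangular(prof.L, np.asarray(Lam.T @ design.ZtX), lower=True)
    cZy = solve_triangular(prof.L, np.asarray(Lam.T @ design.Zty), lower=True)
    ZtV0iX = design.ZtX - S.T @ cZX
    ZtV0iy = design.Zty - S.T @ cZy
    w = ZtV0iy - ZtV0iX @ prof.beta
    if reml:
        F = cho_solve(prof.cX, ZtV0iX.T)  # p x q
        c_scale = float(n - p)
    else:
        F = None
        c_scale = float(n)

    def b_entries(r: np.ndarray, c: np.ndarray) -> np.ndarray:
        vals = design.ZtZ[r, c] - np.einsum("ij,ij->j", S[:, r], S[:, c])
        if F is not None:
            vals = vals - np.einsum("jk,kj->j", ZtV0iX[r, :], F[:, c])
        return vals

    grad = np.empty(design.n_theta)
    inv_r2 = c_scale / prof.r2
    for block, sl in zip(design.blocks, design.theta_slices):
        off, nlev = block.offset, len(block.levels)
        if block.dim == 1:
            j = off + np.arange(nlev)
            t0 = theta[sl.start]
            Bjj = b_entries(j, j)
            wj = w[j]
            grad[sl.start] = 2.0 * t0 * (Bjj.sum() - inv_r2 * float(wj @ wj))
        else:
            j = off + 2 * np.arange(nlev)
            a, b, cc = theta[sl]
            B11 = b_entries(j, j)
            B12 = b_entries(j, j + 1)
            B22 = b_entries(j + 1, j + 1)
            w1, w2 = w[j], w[j + 1]
            lt1 = a * w1 + b * w2  # (Lambda' w) at intercept columns
            grad[sl.start] = 2.0 * (
                float((B11 * a + B12 * b).sum()) - inv_r2 * float(w1 @ lt1)
            )
            grad[sl.start + 1] = 2.0 * (
                float((B12 * a + B22 * b).sum()) - inv_r2 * float(w2 @ lt1)
            )
            grad[sl.start + 2] = 2.0 * cc * (
                float(B22.sum()) - inv_r2 * float(w2 @ w2)
            )
    return dev, grad


def _optimize_theta(design: Design, reml: bool) -> tuple[np.ndarray, bool, str]:
    """Minimise the profiled deviance by L-BFGS-B with analytic gradients.

    L-BFGS-B can stall at a bound corner with a stale Hessian approximation;
    re-starting from the incumbent (which resets the approximation) is cheap
    and reliably escapes, so every solve is polished by restarts until the
    criterion stops improving. Jittered restarts (seeded) cover outright
    failures.
    """

    def objective(theta: np.ndarray):
        try:
            dev, grad = _dev_and_grad(design, theta, reml)
        except (np.linalg.LinAlgError, ValueError):
            return np.inf, np.zeros(design.n_theta)
        if not np.isfinite(dev) or not np.all(np.isfinite(grad)):
            return np.inf, np.zeros(design.n_theta)
        return dev, grad

    def run(x0: np.ndarray):
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=design.theta_bounds,
            options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 500, "maxcor": 20},
        )
        for _ in range(6):
            again = optimize.minimize(
                objective,
                res.x,
                jac=True,
                method="L-BFGS-B",
                bounds=design.theta_bounds,
                options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 500, "maxcor": 20},
            )
            if not np.isfinite(again.fun) or again.fun > res.fun - 1e-8:
                if np.isfinite(again.fun) and again.fun < res.fun:
                    res = again
                break
            res = again
        return res

    def escape_zero_saddles(res):
        # A zero Cholesky diagonal is a stationary point of the criterion
        # (the gradient is proportional to theta there), so the optimiser can
        # park a variance at zero even when lifting it would improve the fit.
        # Probe each zeroed diagonal (and all jointly) at a small positive
        # value and re-optimise from any probe that lowers the criterion.
        for _ in range(3):
            zeros = [
                i
                for i, (lo, _) in enumerate(design.theta_bounds)
                if lo == 0.0 and res.x[i] < 1e-4
            ]
            if not zeros:
                return res
            probes = []
            for val in (0.3, 0.05):
                joint = res.x.copy()
                joint[zeros] = val
                probes.append(joint)
                for i in zeros:
                    single = res.x.copy()
                    single[i] = val
                    probes.append(single)
            improved = None
            for x in probes:
                if objective(x)[0] < res.fun - 1e-10:
                    cand = run(x)
                    if cand.fun < res.fun - 1e-10:
                        improved = cand
                        break
            if improved is None:
                return res
            res = improved
        return res

    best = run(design.theta0)
    # slope terms create interacting Cholesky blocks whose surface can hold
    # spurious corner optima; a second, half-scale start covers them
    if any(b.dim == 2 for b in design.blocks):
        second = run(0.5 * design.theta0)
        if np.isfinite(second.fun) and (
            not np.isfinite(best.fun) or second.fun < best.fun
        ):
            best = second
    if np.isfinite(best.fun):
        best = escape_zero_saddles(best)
        return best.x, True, ""
    rng = np.random.default_rng(RESTART_SEED)
    for attempt in range(5):
        x0 = design.theta0 + rng.uniform(-0.5, 0.5, size=design.n_theta)
        x0 = np.clip(x0, [b[0] if b[0] is not None else -np.inf for b in design.theta_bounds], np.inf)
        res = run(x0)
        if np.isfinite(res.fun) and (not np.isfinite(best.fun) or res.fun < best.fun):
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(
            "mixed-model optimisation failed to converge after 5 restarts; "
            f"last message: {best.message}"
        )
    return best.x, True, str(best.message)


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------


@dataclass
class VarComp:
    """Variance of one random term (with covariance for slope terms)."""

    term: str
    var_intercept: float
    var_slope: float | None = None
    cov: float | None = None
    boundary: bool = False

    @property
    def corr(self) -> float | None:
        if self.var_slope is None or self.cov is None:
            return None
        denom = np.sqrt(self.var_intercept * self.var_slope)
        return float(self.cov / denom) if denom > 0 else 0.0


@dataclass
class FittedLMM:
    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    vcov_fixed: pd.DataFrame
    varcomps: list[VarComp]
    sigma2: float
    loglik_ml: float
    loglik_reml: float
    blups: dict[str, pd.DataFrame]
    n_obs: int
    n_params: int
    converged: bool
    boundary: bool
    n_dropped: int
    theta_: np.ndarray = field(repr=False)
    design_: Design = field(repr=False)
    satt_df_: np.ndarray | None = field(default=None, repr=False)

    @property
    def loglik(self) -> float:
        return self.loglik_reml if self.spec.reml else self.loglik_ml

    @property
    def df_residual(self) -> int:
        return self.n_obs - len(self.beta)

    def tvalues(self) -> pd.Series:
        return self.beta / self.se

    def fixed_table(self, df_method: DfMethod = "satterthwaite") -> pd.DataFrame:
        """Per-term estimate, SE, df, t and p, in the layout of a coefficient
        table (df by Satterthwaite's approximation unless overridden)."""
        rows = []
        for i, name in enumerate(self.beta.index):
            if df_method == "satterthwaite" and self.spec.random:
                df = satterthwaite_df(self, i)
            else:
                df = float(self.df_residual)
            t = float(self.beta.iloc[i] / self.se.iloc[i])
            p = 2.0 * float(stats.t.sf(abs(t), df))
            rows.append(
                {
                    "term": name,
                    "estimate": float(self.beta.iloc[i]),
                    "se": float(self.se.iloc[i]),
                    "df": df,
                    "t": t,
                    "p": p,
                }
            )
        return pd.DataFrame(rows).set_index("term")

    def summary(self) -> str:
        lines = [
            f"Linear mixed model ({'REML' if self.spec.reml else 'ML'}), "
            f"n = {self.n_obs}, parameters = {self.n_params}",
            f"logLik(ML) = {self.loglik_ml:.3f}   logLik(REML) = {self.loglik_reml:.3f}",
            "",
            self.fixed_table().to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            "Random effects:",
        ]
        for vc in self.varcomps:
            extra = ""
            if vc.var_slope is not None:
                extra = f", slope var {vc.var_slope:.4g}, corr {vc.corr:.3f}"
            flag = " (boundary)" if vc.boundary else ""
            lines.append(f"  {vc.term}: intercept var {vc.var_intercept:.4g}{extra}{flag}")
        lines.append(f"  residual var {self.sigma2:.4g}")
        return "\n".join(lines)


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> FittedLMM:
    """Fit the model by profiled REML (default) or ML.

    Variance components are estimated on the bounded Cholesky scale so a
    component can converge exactly to zero; such fits are returned as valid
    with ``boundary=True`` on the affected term.
    """
    design = build_design(data, spec)
    if design.q:
        theta, converged, message = _optimize_theta(design, spec.reml)
    else:
        theta, converged, message = np.zeros(0), True, "ols"
    prof = _profile(design, theta)
    n, p = design.n, design.p
    sigma2 = prof.r2 / (n - p) if spec.reml else prof.r2 / n
    vcov = cho_solve(prof.cX, np.eye(p)) * sigma2
    se = np.sqrt(np.diag(vcov))
    names = design.fixed_names

    varcomps: list[VarComp] = []
    boundary_any = False
    for block, sl in zip(design.blocks, design.theta_slices):
        t = theta[sl]
        if block.dim == 1:
            var = sigma2 * t[0] ** 2
            at_boundary = t[0] ** 2 < BOUNDARY_TOL
            if at_boundary:
                var = 0.0
            varcomps.append(
                VarComp(block.term.label, var_intercept=var, boundary=at_boundary)
            )
        else:
            a, b, c = t
            vi = sigma2 * a**2
            vs = sigma2 * (b**2 + c**2)
            cv = sigma2 * a * b
            at_boundary = min(a**2, b**2 + c**2) < BOUNDARY_TOL
            varcomps.append(
                VarComp(
                    block.term.label,
                    var_intercept=0.0 if a**2 < BOUNDARY_TOL else vi,
                    var_slope=0.0 if b**2 + c**2 < BOUNDARY_TOL else vs,
                    cov=cv,
                    boundary=at_boundary,
                )
            )
        boundary_any = boundary_any or at_boundary

    blups: dict[str, pd.DataFrame] = {}
    if design.q:
        Lam = design.lambda_matrix(theta)
        resid_proj = design.Zty - design.ZtX @ prof.beta
        w = np.asarray(Lam.T @ resid_proj)
        u = np.asarray(Lam @ cho_solve((prof.L, True), w))
        for block in design.blocks:
            if block.dim == 1:
                vals = u[block.offset : block.offset + block.n_cols]
                blups[block.term.label] = pd.DataFrame(
                    {"level": block.levels, "intercept": vals}
                ).set_index("level")
            else:
                vals = u[block.offset : block.offset + block.n_cols].reshape(-1, 2)
                blups[block.term.label] = pd.DataFrame(
                    {
                        "level": block.levels,
                        "intercept": vals[:, 0],
                        "slope": vals[:, 1],
                    }
                ).set_index("level")

    return FittedLMM(
        spec=spec,
        beta=pd.Series(prof.beta, index=names),
        se=pd.Series(se, index=names),
        vcov_fixed=pd.DataFrame(vcov, index=names, columns=names),
        varcomps=varcomps,
        sigma2=float(sigma2),
        loglik_ml=-0.5 * prof.dev_ml,
        loglik_reml=-0.5 * prof.dev_reml,
        blups=blups,
        n_obs=n,
        n_params=p + design.n_theta + 1,
        converged=converged,
        boundary=boundary_any,
        n_dropped=design.n_dropped,
        theta_=np.asarray(theta, dtype=float),
        design_=design,
    )


def extract_blups(fit: FittedLMM, factor: str) -> pd.DataFrame:
    """Per-level conditional modes (intercept and, if present, slope
    deviations) for a grouping factor of the fitted model."""
    for vc_label, table in fit.blups.items():
        if vc_label == factor or vc_label.split(":")[0] == factor:
            return table.copy()
    raise KeyError(f"no random term for factor {factor!r} in this model")


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float
    note: str = ""


def _is_nested(full: ModelSpec, reduced: ModelSpec) -> bool:
    if not set(reduced.fixed) <= set(full.fixed):
        return False
    full_random = {(rt.factor, rt.slope) for rt in full.random}
    full_factors = {rt.factor for rt in full.random}
    for rt in reduced.random:
        if (rt.factor, rt.slope) in full_random:
            continue
        if rt.slope is None and rt.factor in full_factors:
            continue  # intercept-only is nested inside intercept+slope
        return False
    return True


def loglik_ratio_test(
    full: FittedLMM,
    reduced: FittedLMM,
    scope: Literal["fixed", "random"] = "random",
    boundary_mixture: bool = False,
) -> LRTResult:
    """Chi-square LRT of two nested fits.

    Fixed-effect comparisons use the ML log-likelihoods (fit both models with
    ``reml=False``); random-structure comparisons use REML log-likelihoods and
    require identical fixed effects. The degrees of freedom equal the
    parameter-count difference (a correlated random slope adds 2: slope
    variance plus intercept-slope covariance). ``boundary_mixture`` switches
    to an equal-weight chi-square mixture with df and df-1, the conservative
    correction for a variance tested on its boundary (off by default).
    """
    if not _is_nested(full.spec, reduced.spec):
        raise ValueError("models are not nested")
    if scope == "fixed":
        if full.spec.reml or reduced.spec.reml:
            warnings.warn(
                "fixed-effect LRT should compare ML fits; refit with reml=False",
                stacklevel=2,
            )
        ll_full, ll_red = full.loglik_ml, reduced.loglik_ml
    else:
        if set(full.spec.fixed) != set(reduced.spec.fixed):
            raise ValueError("random-effect LRT requires identical fixed effects")
        ll_full, ll_red = full.loglik_reml, reduced.loglik_reml
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than reduced model")
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    note = ""
    if df == 0:
        return LRTResult(stat, 0, 1.0, "identical parameter counts")
    if boundary_mixture and scope == "random":
        p = 0.5 * (stats.chi2.sf(stat, df) + stats.chi2.sf(stat, max(df - 1, 1e-8)))
        note = "50:50 chi-square boundary mixture"
    else:
        p = float(stats.chi2.sf(stat, df))
        if scope == "random":
            note = "naive chi-square reference (boundary-conservative)"
    return LRTResult(stat, df, float(p), note)


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------


def _satterthwaite_all(fit: FittedLMM) -> np.ndarray:
    """Satterthwaite df for every fixed effect of a fit, in one pass.

    The observed REML information over the variance parameters
    (theta, log sigma^2) is evaluated numerically once; the delta-method
    gradients of all coefficient variances are obtained together because each
    perturbed profile yields the whole vcov diagonal.
    """
    design = fit.design_
    resid_df = float(design.n - design.p)
    if not design.q:
        return np.full(design.p, resid_df)
    phi_hat = np.concatenate([fit.theta_, [np.log(fit.sigma2)]])
    k = len(phi_hat)

    def neg_restricted(phi: np.ndarray) -> float:
        return -restricted_loglik(design, phi[:-1], float(np.exp(phi[-1])))

    def contrast_vars(phi: np.ndarray) -> np.ndarray:
        prof = _profile(design, phi[:-1])
        vcov = cho_solve(prof.cX, np.eye(design.p)) * float(np.exp(phi[-1]))
        return np.diag(vcov).copy()

    lower = np.array(
        [b[0] if b[0] is not None else -np.inf for b in design.theta_bounds] + [-np.inf]
    )
    step = 1e-4 * np.maximum(1.0, np.abs(phi_hat))

    def _perturb(i: int, sign: int) -> np.ndarray:
        phi = phi_hat.copy()
        phi[i] += sign * step[i]
        phi[i] = max(phi[i], lower[i])
        return phi

    # gradients of all contrast variances (one-sided at an active bound)
    grad = np.zeros((k, design.p))
    for i in range(k):
        hi, lo = _perturb(i, +1), _perturb(i, -1)
        denom = hi[i] - lo[i]
        if denom > 0:
            grad[i] = (contrast_vars(hi) - contrast_vars(lo)) / denom

    # observed information: numerical Hessian of the negative REML loglik
    H = np.zeros((k, k))
    f0 = neg_restricted(phi_hat)
    for i in range(k):
        H[i, i] = (
            neg_restricted(_perturb(i, +1))
            - 2 * f0
            + neg_restricted(_perturb(i, -1))
        ) / step[i] ** 2
        for j in range(i + 1, k):
            vals = []
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                phi = phi_hat.copy()
                phi[i] += si * step[i]
                phi[j] += sj * step[j]
                vals.append(neg_restricted(phi))
            H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                4 * step[i] * step[j]
            )

    v_hat = contrast_vars(phi_hat)
    try:
        cov_grad = np.linalg.solve(H, grad)
        var_v = np.einsum("ij,ij->j", grad, cov_grad)
    except np.linalg.LinAlgError:
        var_v = np.full(design.p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * v_hat**2 / var_v
    bad = ~np.isfinite(df) | (df < 1.0) | (var_v <= 0)
    if bad.any():
        warnings.warn(
            "singular or unstable information in Satterthwaite approximation; "
            "falling back to residual df for some coefficients",
            stacklevel=2,
        )
        df = np.where(bad, resid_df, df)
    return df


def satterthwaite_df(fit: FittedLMM, contrast: int) -> float:
    """Approximate denominator df for one fixed-effect t-statistic.

    df = 2 v^2 / Var(v), with v the estimated variance of the contrast and
    Var(v) from the delta method over the REML variance-parameter estimates.
    Falls back to the residual df (n - p) with a warning when the information
    matrix is singular. Results are cached on the fit.
    """
    if fit.satt_df_ is None:
        fit.satt_df_ = _satterthwaite_all(fit)
    return float(fit.satt_df_[contrast])


# ---------------------------------------------------------------------------
# Backward elimination
# ---------------------------------------------------------------------------


def _removable(terms: Sequence[str]) -> list[str]:
    """Fixed terms not protected by marginality (no retained higher-order
    interaction contains them)."""
    out = []
    for t in terms:
        t_parts = set(t.split(":"))
        protected = any(
            t != other and t_parts < set(other.split(":")) for other in terms
        )
        if not protected:
            out.append(t)
    return out


def backward_eliminate(
    data: pd.DataFrame,
    full_spec: ModelSpec,
    alpha: float = 0.05,
    df_method: DfMethod = "satterthwaite",
) -> tuple[FittedLMM, pd.DataFrame]:
    """Sequentially remove the least-significant removable fixed term.

    Each removal is confirmed with an ML likelihood-ratio test against the
    previous model; a term whose removal the LRT rejects is locked into the
    model. Stops when every remaining (removable) term has p < alpha. Returns
    the final (REML, if requested) fit plus a trace of every step.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    spec = full_spec
    locked: set[str] = set()
    trace_rows: list[dict] = []
    step = 0
    current_ml: FittedLMM | None = None  # ML fit of the current spec, reused
    while True:
        fit = fit_lmm(data, spec)
        table = fit.fixed_table(df_method=df_method)
        candidates = [
            t for t in _removable(spec.fixed) if t not in locked
        ]
        if not candidates:
            break
        pvals = table.loc[candidates, "p"]
        worst = str(pvals.idxmax())
        if pvals.max() < alpha:
            break
        reduced_spec = spec.drop_fixed(worst)
        if current_ml is None:
            current_ml = fit_lmm(data, spec.with_reml(False))
        full_ml = current_ml
        red_ml = fit_lmm(data, reduced_spec.with_reml(False))
        lrt = loglik_ratio_test(full_ml, red_ml, scope="fixed")
        step += 1
        accepted = lrt.p >= alpha
        trace_rows.append(
            {
                "step": step,
                "term": worst,
                "wald_p": float(pvals.max()),
                "lrt_stat": lrt.statistic,
                "lrt_df": lrt.df,
                "lrt_p": lrt.p,
                "removed": accepted,
            }
        )
        if accepted:
            logger.info("eliminated term %r (LRT p=%.3g)", worst, lrt.p)
            spec = reduced_spec
            current_ml = red_ml
        else:
            locked.add(worst)
    final = fit_lmm(data, spec)
    trace = pd.DataFrame(
        trace_rows,
        columns=["step", "term", "wald_p", "lrt_stat", "lrt_df", "lrt_p", "removed"],
    )
    return final, trace
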