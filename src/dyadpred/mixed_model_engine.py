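"""Two-level linear mixed models (clients nested in therapists) by ML.

The model is ``y = X beta + Z u + e`` with a single random intercept per
grouping unit, ``u ~ N(0, tau00 I)`` and ``e ~ N(0, sigma2 I)``.  The
likelihood is maximized by profiling ``beta`` and ``sigma2`` out in closed
form and optimizing the single variance ratio ``lambda = tau00 / sigma2``
numerically — this makes a fit cheap enough for exhaustive model search
and leave-one-out cross-validation.

Writing ``W = I + lambda Z Z'`` (block diagonal over groups), the inverse
per group of size ``m`` is ``I − lambda/(1 + lambda m) 11'``, so every
profiled quantity reduces to group sums; no per-group matrix factorization
is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .terms import ModelSpec, ModelTerm

_LOG_LAMBDA_BOUNDS = (-15.0, 15.0)


class RankDeficiencyError(np.linalg.LinAlgError):
    """Fixed-effect design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """Likelihood optimization failed; message carries the trace."""


@dataclass
class Design:
    """Numeric design for one candidate model."""

    y: np.ndarray
    X: np.ndarray
    groups: np.ndarray  # integer codes, 0..n_groups-1
    group_labels: tuple
    columns: tuple[str, ...]  # fixed-effect column names, intercept first
    spec: ModelSpec | None = None

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass
class FitResult:
    """One fitted model: coefficients, inference, variance components."""

    sigma2: float = float("nan")
    tau00: float = float("nan")
    beta: np.ndarray | None = None
    se: np.ndarray | None = None
    df: int | None = None
    tvalues: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    columns: tuple[str, ...] = ()
    loglik: float = float("nan")
    aic: float = float("nan")
    var_fixed: float = float("nan")
    r2_marginal: float = float("nan")
    converged: bool = True
    n_obs: int = 0
    n_groups: int = 0
    estimation: str = "ML"
    spec: ModelSpec | None = None
    group_effects: dict = field(default_factory=dict)  # label -> BLUP intercept

    @property
    def icc(self) -> float:
        return icc(self)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": list(self.columns),
            "estimate": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "df": self.df,
            "statistic": self.tvalues,
            "p": self.pvalues,
        })

    def to_jsonable(self) -> dict:
        def arr(a):
            return None if a is None else [float(v) for v in a]
        return {
            "columns": list(self.columns),
            "beta": arr(self.beta), "se": arr(self.se),
            "ci_low": arr(self.ci_low), "ci_high": arr(self.ci_high),
            "df": self.df,
            "tvalues": arr(self.tvalues), "pvalues": arr(self.pvalues),
            "sigma2": float(self.sigma2), "tau00": float(self.tau00),
            "icc": float(self.icc),
            "loglik": float(self.loglik), "aic": float(self.aic),
            "var_fixed": float(self.var_fixed),
            "r2_marginal": float(self.r2_marginal),
            "converged": bool(self.converged),
            "n_obs": self.n_obs, "n_groups": self.n_groups,
            "estimation": self.estimation,
            "spec": self.spec.describe() if self.spec else None,
            "group_effects": {str(k): float(v)
                              for k, v in self.group_effects.items()},
        }


@dataclass
class DiagnosticsReport:
    """Residual-assumption checks on a fitted model (alpha = 0.05)."""

    normality_stat: float
    normality_p: float
    heteroscedasticity_stat: float
    heteroscedasticity_p: float
    alpha: float = 0.05

    @property
    def normality_ok(self) -> bool:
        return self.normality_p >= self.alpha

    @property
    def homoscedasticity_ok(self) -> bool:
        return self.heteroscedasticity_p >= self.alpha

    def to_jsonable(self) -> dict:
        return {"normality_stat": self.normality_stat,
                "normality_p": self.normality_p,
                "normality_ok": self.normality_ok,
                "heteroscedasticity_stat": self.heteroscedasticity_stat,
                "heteroscedasticity_p": self.heteroscedasticity_p,
                "homoscedasticity_ok": self.homoscedasticity_ok,
                "alpha": self.alpha}


# ----------------------------------------------------------------------
# design construction
# ----------------------------------------------------------------------

def term_column(term: ModelTerm, frame: pd.DataFrame) -> np.ndarray:
    for v in term.variables:
        if v not in frame.columns:
            raise KeyError(f"unknown variable {v!r} in term {term.name}")
    cols = [frame[v].to_numpy(dtype=float) for v in term.variables]
    if term.kind == "linear":
        return cols[0]
    if term.kind == "quadratic":
        return cols[0] ** 2
    return cols[0] * cols[1]


def build_design(frame: pd.DataFrame, spec: ModelSpec,
                 group_col: str = "therapist_id") -> Design:
    """Build (y, X, groups) for ``spec`` from a client-level frame.

    Columns are ordered intercept first, then terms in canonical order.
    Missing cells anywhere in the used columns are an error (impute first).
    """
    if spec.outcome not in frame.columns:
        raise KeyError(f"outcome {spec.outcome!r} not in frame")
    y = frame[spec.outcome].to_numpy(dtype=float)
    cols = [np.ones(len(frame))]
    names = ["(Intercept)"]
    for term in spec.terms:
        cols.append(term_column(term, frame))
        names.append(term.name)
    X = np.column_stack(cols)
    if np.isnan(y).any() or np.isnan(X).any():
        bad = [n for n, c in zip(names, X.T) if np.isnan(c).any()]
        if np.isnan(y).any():
            bad = [spec.outcome] + bad
        raise ValueError("missing cells in design "
                         f"({', '.join(bad)}); impute before fitting")
    labels, codes = np.unique(frame[group_col].to_numpy(), return_inverse=True)
    return Design(y=y, X=X, groups=codes.astype(np.intp),
                  group_labels=tuple(labels), columns=tuple(names), spec=spec)


# ----------------------------------------------------------------------
# likelihood machinery
# ----------------------------------------------------------------------

class _Profile:
    """Precomputed sufficient statistics for profiling over lambda."""

    def __init__(self, design: Design):
        y, X, g = design.y, design.X, design.groups
        self.y, self.X, self.g = y, X, g
        self.n, self.p = X.shape
        self.G = design.n_groups
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.S = np.zeros((self.G, self.p))
        np.add.at(self.S, g, X)
        self.sy = np.bincount(g, weights=y, minlength=self.G)
        self.ng = np.bincount(g, minlength=self.G).astype(float)
        self.design = design

    def solve(self, lam: float):
        """GLS at fixed lambda: returns (beta, A, sigma2_ml, loglik)."""
        c = lam / (1.0 + lam * self.ng)  # per-group shrinkage weight
        A = self.XtX - (self.S.T * c) @ self.S
        b = self.Xty - self.S.T @ (c * self.sy)
        beta = np.linalg.solve(A, b)
        # quadratic form via residuals (stable at extreme lambda)
        e = self.y - self.X @ beta
        se_g = np.bincount(self.g, weights=e, minlength=self.G)
        quad = float(e @ e) - float(np.sum(c * se_g ** 2))
        quad = max(quad, 1e-300)
        sigma2 = quad / self.n
        logdet = float(np.sum(np.log1p(lam * self.ng)))
        ll = -0.5 * (self.n * math.log(2.0 * math.pi * sigma2) + logdet + self.n)
        return beta, A, sigma2, ll


def loglik_at(design: Design, beta: np.ndarray, tau00: float,
              sigma2: float) -> float:
    """Exact Gaussian log-likelihood at fixed parameters.

    Uses the same grouped algebra as the fitter; equals direct evaluation of
    the multivariate normal density with covariance ``sigma2 I + tau00 ZZ'``.
    """
    e = design.y - design.X @ beta
    lam = tau00 / sigma2
    ng = np.bincount(design.groups, minlength=design.n_groups).astype(float)
    se_g = np.bincount(design.groups, weights=e, minlength=design.n_groups)
    c = lam / (1.0 + lam * ng)
    quad = (float(e @ e) - float(np.sum(c * se_g ** 2))) / sigma2
    logdet = design.n_obs * math.log(sigma2) + float(np.sum(np.log1p(lam * ng)))
    return -0.5 * (design.n_obs * math.log(2.0 * math.pi) + logdet + quad)


def fit_lmm(design: Design) -> FitResult:
    """Maximum-likelihood fit of the random-intercept model."""
    n, p = design.X.shape
    if n <= p:
        raise ValueError(f"too few observations (n={n}) for {p} fixed effects")
    if design.n_groups < 2:
        raise ValueError("need at least 2 groups")

    # rank check with column identification
    q, r = np.linalg.qr(design.X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    if (diag < tol).any():
        bad = [design.columns[i] for i in np.flatnonzero(diag < tol)]
        raise RankDeficiencyError(
            f"rank-deficient design; collinear column(s): {', '.join(bad)}")

    prof = _Profile(design)

    def nll(u: float) -> float:
        try:
            return -prof.solve(math.exp(u))[3]
        except np.linalg.LinAlgError:
            return np.inf

    res = optimize.minimize_scalar(nll, bounds=_LOG_LAMBDA_BOUNDS,
                                   method="bounded",
                                   options={"xatol": 1e-10})
    ll_boundary = prof.solve(0.0)[3]
    if not res.success and not np.isfinite(ll_boundary):
        raise ConvergenceError(f"lambda optimization failed: {res}")
    # prefer the tau00 = 0 boundary on (near-)ties: flat profiles collapse
    # to the simpler model
    if ll_boundary >= -res.fun - 1e-8:
        lam = 0.0
        ll = ll_boundary
    else:
        lam = math.exp(res.x)
        ll = -res.fun
    beta, A, sigma2, _ = prof.solve(lam)
    tau00 = lam * sigma2

    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    dof = n - p - 1
    if dof >= 1:
        tvals = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        tcrit = stats.t.ppf(0.975, dof)
    else:  # degenerate tiny fit (prediction-only use, e.g. LOOCV folds)
        tvals = np.full_like(beta, np.nan)
        pvals = np.full_like(beta, np.nan)
        tcrit = np.nan

    # conditional group intercepts (BLUPs)
    e = design.y - design.X @ beta
    se_g = np.bincount(design.groups, weights=e, minlength=design.n_groups)
    u = lam * se_g / (1.0 + lam * prof.ng)
    xb = design.X @ beta
    var_fixed = float(np.var(xb))  # population variance (denominator n)

    fit = FitResult(
        sigma2=float(sigma2), tau00=float(tau00),
        beta=beta, se=se, df=dof, tvalues=tvals, pvalues=pvals,
        ci_low=beta - tcrit * se, ci_high=beta + tcrit * se,
        columns=design.columns, loglik=float(ll),
        var_fixed=var_fixed,
        converged=bool(np.isfinite(ll)),
        n_obs=n, n_groups=design.n_groups, estimation="ML", spec=design.spec,
        group_effects=dict(zip(design.group_labels, map(float, u))))
    fit.aic = aic(fit)
    fit.r2_marginal = marginal_r2(fit)
    return fit


# ----------------------------------------------------------------------
# derived quantities
# ----------------------------------------------------------------------

def aic(fit: FitResult) -> float:
    """AIC = −2·loglik + 2·k, k = #fixed effects (incl. intercept) + 2."""
    if fit.estimation != "ML":
        raise ValueError("AIC comparison requires ML estimation, not "
                         f"{fit.estimation}")
    k = len(fit.columns) + 2
    return -2.0 * fit.loglik + 2.0 * k


def marginal_r2(fit: FitResult, design: Design | None = None) -> float:
    """Nakagawa–Schielzeth marginal R²: var(Xb)/(var(Xb)+tau00+sigma2)."""
    if design is not None:
        xb = design.X @ fit.beta
        var_f = float(np.var(xb))
    else:
        var_f = fit.var_fixed
    denom = var_f + fit.tau00 + fit.sigma2
    return var_f / denom if denom > 0 else 0.0


def icc(fit: FitResult | float, sigma2: float | None = None) -> float:
    """Intraclass correlation tau00/(tau00+sigma2)."""
    if isinstance(fit, FitResult):
        tau00, sigma2 = fit.tau00, fit.sigma2
    else:
        tau00 = float(fit)
    total = tau00 + sigma2
    return tau00 / total if total > 0 else 0.0


def predict(fit: FitResult, new_frame: pd.DataFrame,
            mode: str = "fixed_only",
            group_col: str = "therapist_id") -> np.ndarray:
    """Predict for new rows.

    ``fixed_only`` returns X beta-hat; ``with_group_effects`` adds each
    row's conditional therapist intercept when the therapist was present in
    the fit, falling back to the fixed-only prediction otherwise.
    """
    if mode not in ("fixed_only", "with_group_effects"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    if fit.spec is None:
        raise ValueError("fit carries no model spec; cannot rebuild design")
    cols = [np.ones(len(new_frame))]
    for term in fit.spec.terms:
        cols.append(term_column(term, new_frame))
    X = np.column_stack(cols)
    pred = X @ fit.beta
    if mode == "with_group_effects":
        if group_col not in new_frame.columns:
            raise KeyError(f"{group_col!r} required for with_group_effects")
        u = np.array([fit.group_effects.get(g, 0.0)
                      for g in new_frame[group_col]])
        pred = pred + u
    return pred


def residual_diagnostics(fit: FitResult, design: Design) -> DiagnosticsReport:
    """Shapiro–Wilk normality + Breusch–Pagan-type heteroscedasticity test.

    Both are computed on conditional residuals (fixed effects + BLUPs
    subtracted); the heteroscedasticity LM statistic regresses squared
    residuals on the fitted values.
    """
    from statsmodels.stats.diagnostic import het_breuschpagan

    u = np.array([fit.group_effects.get(g, 0.0)
                  for g in np.asarray(design.group_labels)[design.groups]])
    fitted = design.X @ fit.beta + u
    resid = design.y - fitted
    if resid.shape[0] < 8:
        raise ValueError("normality test requires at least 8 residuals")
    if np.ptp(resid) == 0:
        raise ValueError("constant residuals; diagnostics are undefined")
    w_stat, w_p = stats.shapiro(resid)
    exog = np.column_stack([np.ones_like(fitted), fitted])
    lm_stat, lm_p, _, _ = het_breuschpagan(resid, exog)
    return DiagnosticsReport(normality_stat=float(w_stat),
                             normality_p=float(w_p),
                             heteroscedasticity_stat=float(lm_stat),
                             heteroscedasticity_p=float(lm_p))
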