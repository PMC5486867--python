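"""Maximum-likelihood estimation of LMMs with crossed, independent random effects.

The model is

    y = X beta + Z gamma + eps,   gamma ~ N(0, sigma^2 Lambda Lambda'),
                                  eps   ~ N(0, sigma^2 I),

where ``Lambda`` is diagonal: every random-effects block (a grouping factor
crossed with a covariate, e.g. per-subject intercepts or per-subject
frequency slopes) has a single relative standard deviation ``theta_b >= 0``
shared by its columns.  Variance components are independent — no
correlation parameters.

Estimation profiles ``beta`` and ``sigma^2`` out of the marginal Gaussian
likelihood.  For fixed ``theta`` the penalized least-squares system

    [ L'Z'Z L + I   L'Z'X ] [u]   [L'Z'y]
    [ X'Z L         X'X   ] [b] = [X'y  ]

is solved through a sparse LU factorization of ``A = L'Z'Z L + I`` and a
dense Schur complement for ``b``; the profiled deviance is

    -2 logLik(theta) = log|A| + n (1 + log(2 pi r^2 / n)),

with ``r^2`` the penalized residual sum of squares.  A derivative-free
bound-constrained optimizer (Powell) minimizes this over ``theta >= 0``;
boundary estimates are legitimate and flagged, not removed.

The parameter count used for AIC/BIC is
``df = #fixed effects + #variance components + 1`` (the residual variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

from .design import DesignMatrices, ZBlock

__all__ = [
    "FittedLMM",
    "FitReport",
    "ConvergenceError",
    "profiled_deviance",
    "fit_lmm",
    "information_criteria",
    "wald_tests",
]

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the best state seen so far."""

    def __init__(self, message: str, best_theta=None, best_deviance=None):
        super().__init__(message)
        self.best_theta = best_theta
        self.best_deviance = best_deviance


@dataclass
class FittedLMM:
    """A converged LMM fit.

    ``theta`` holds relative standard deviations (random-effect SD divided
    by the residual SD), one per block; ``variance_components`` the
    corresponding variances ``(theta * sigma)^2`` keyed by block name.
    ``conditional_modes`` are the BLUPs of the random effects at the
    estimated parameters.  ``fitted + residuals == y`` exactly.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    term_names: list[str]
    theta: np.ndarray
    sigma2: float
    variance_components: dict[str, float]
    conditional_modes: dict[str, np.ndarray]
    loglik: float
    df: int
    n: int
    fitted: np.ndarray
    residuals: np.ndarray
    vcov_beta: np.ndarray
    converged: bool
    boundary: np.ndarray
    design: DesignMatrices
    reml: bool = False
    n_deviance_evals: int = 0

    @property
    def aic(self) -> float:
        return information_criteria(self.loglik, self.df, self.n)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self.loglik, self.df, self.n)[1]

    def coef_table(self) -> pd.DataFrame:
        return wald_tests(self)


@dataclass
class FitReport:
    """Goodness-of-fit table: one row per model (label, df, AIC, BIC, logLik)."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_fits(cls, labels, fits) -> "FitReport":
        recs = [
            {
                "label": lab,
                "df": f.df,
                "AIC": f.aic,
                "BIC": f.bic,
                "logLik": f.loglik,
            }
            for lab, f in zip(labels, fits)
        ]
        df = pd.DataFrame(recs).sort_values(["AIC", "df"]).reset_index(drop=True)
        return cls(rows=df)


class _PLSWorkspace:
    """Cross-products precomputed once per design; theta-dependent pieces
    are cheap rescalings, so one deviance evaluation costs a single sparse
    factorization."""

    def __init__(self, design: DesignMatrices):
        self.design = design
        self.n = design.n
        X, y = design.X, design.y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        if design.Z is not None:
            Z = design.Z.tocsc()
            self.ZtZ = (Z.T @ Z).tocsc()
            self.ZtX = Z.T @ X
            if sparse.issparse(self.ZtX):
                self.ZtX = self.ZtX.toarray()
            self.Zty = Z.T @ y
            self.q = Z.shape[1]
            scale_index = np.empty(self.q, dtype=np.intp)
            for b_i, blk in enumerate(design.blocks):
                scale_index[blk.start:blk.stop] = b_i
            self.scale_index = scale_index
        else:
            self.q = 0

    def solve(self, theta: np.ndarray):
        """Solve the penalized LS system at ``theta``.

        Returns (beta, u, r2, logdet, S) where S is the fixed-effects
        Schur complement X' V*^{-1} X.
        """
        if self.q == 0:
            S = self.XtX
            beta = np.linalg.solve(S, self.Xty)
            r2 = self.yty - beta @ self.Xty
            return beta, np.zeros(0), max(r2, 0.0), 0.0, S
        s = np.asarray(theta, dtype=float)[self.scale_index]
        D = sparse.diags(s)
        A = (D @ self.ZtZ @ D + sparse.identity(self.q, format="csc")).tocsc()
        lu = splu(A)
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        CX = s[:, None] * self.ZtX
        c = s * self.Zty
        AinvCX = lu.solve(np.ascontiguousarray(CX))
        Ainvc = lu.solve(c)
        S = self.XtX - CX.T @ AinvCX
        rhs = self.Xty - CX.T @ Ainvc
        try:
            beta = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            # degenerate boundary (residual variance ~ 0, huge theta)
            beta = np.linalg.pinv(S) @ rhs
        u = Ainvc - AinvCX @ beta
        # r^2 = |y - Xb - Z Lambda u|^2 + |u|^2 via cross-products
        r2 = (
            self.yty
            - 2.0 * beta @ self.Xty
            - u @ c
            + u @ (CX @ beta)
            + beta @ (self.XtX @ beta)
        )
        return beta, u, max(float(r2), np.finfo(float).tiny), logdet, S


def profiled_deviance(theta, design: DesignMatrices, _work: _PLSWorkspace | None = None,
                      reml: bool = False) -> float:
    """-2 times the profiled log-likelihood at relative SDs ``theta``."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if np.any(theta < 0):
        raise ValueError("theta must be nonnegative")
    work = _work if _work is not None else _PLSWorkspace(design)
    if theta.size != len(design.blocks):
        raise ValueError(
            f"theta has {theta.size} entries but the design has "
            f"{len(design.blocks)} blocks"
        )
    _, _, r2, logdet, S = work.solve(theta)
    n = work.n
    if reml:
        p = design.X.shape[1]
        sign, logdetS = np.linalg.slogdet(S)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular fixed-effects system")
        nmp = n - p
        return logdet + logdetS + nmp * (1.0 + _LOG2PI + np.log(r2 / nmp))
    return logdet + n * (1.0 + _LOG2PI + np.log(r2 / n))


def fit_lmm(
    design: DesignMatrices,
    reml: bool = False,
    theta0: np.ndarray | None = None,
    maxiter: int = 200,
    xtol: float = 1e-8,
    ftol: float = 1e-12,
) -> FittedLMM:
    """Fit the LMM by minimizing the profiled deviance over ``theta >= 0``.

    All components start at relative SD 1.  Powell handles the bound at
    zero; estimates pinned there are reported with ``boundary`` flags.
    """
    work = _PLSWorkspace(design)
    k = len(design.blocks)
    n, p = design.n, design.X.shape[1]
    if n <= p + k + 1:
        raise ValueError("more parameters than observations")

    n_evals = 0
    if k > 0:
        def objective(th):
            nonlocal n_evals
            n_evals += 1
            return profiled_deviance(np.maximum(th, 0.0), design, work, reml=reml)

        start = np.ones(k) if theta0 is None else np.asarray(theta0, dtype=float)
        res = optimize.minimize(
            objective,
            start,
            method="Powell",
            bounds=[(0.0, None)] * k,
            options={"maxiter": maxiter, "xtol": xtol, "ftol": ftol},
        )
        if not res.success and "maximum" in (res.message or "").lower():
            raise ConvergenceError(
                f"optimizer did not converge: {res.message}",
                best_theta=res.x, best_deviance=res.fun,
            )
        theta = np.maximum(res.x, 0.0)
        converged = bool(res.success)
    else:
        theta = np.zeros(0)
        converged = True

    beta, u, r2, logdet, S = work.solve(theta)
    denom = (n - p) if reml else n
    sigma2 = r2 / denom
    deviance = profiled_deviance(theta, design, work, reml=reml) if k else (
        n * (1.0 + _LOG2PI + np.log(r2 / n)) if not reml else np.nan
    )
    loglik = -0.5 * deviance

    try:
        vcov = sigma2 * np.linalg.inv(S)
    except np.linalg.LinAlgError:
        vcov = sigma2 * np.linalg.pinv(S)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))

    modes: dict[str, np.ndarray] = {}
    varcomps: dict[str, float] = {}
    if k:
        gamma = theta[work.scale_index] * u
        for b_i, blk in enumerate(design.blocks):
            modes[blk.name] = gamma[blk.start:blk.stop]
            varcomps[blk.name] = float((theta[b_i] ** 2) * sigma2)
        fitted = design.X @ beta + design.Z @ gamma
    else:
        fitted = design.X @ beta
    residuals = design.y - fitted

    return FittedLMM(
        beta=beta,
        se=se,
        t=tvals,
        term_names=list(design.x_names),
        theta=theta,
        sigma2=float(sigma2),
        variance_components=varcomps,
        conditional_modes=modes,
        loglik=float(loglik),
        df=p + k + 1,
        n=n,
        fitted=fitted,
        residuals=residuals,
        vcov_beta=vcov,
        converged=converged,
        boundary=theta < 1e-6,
        design=design,
        reml=reml,
        n_deviance_evals=n_evals,
    )


def information_criteria(loglik: float, df: int, n: int) -> tuple[float, float]:
    """AIC = -2 logLik + 2 df;  BIC = -2 logLik + df ln n."""
    if df < 0 or n < 1:
        raise ValueError("df must be >= 0 and n >= 1")
    aic = -2.0 * loglik + 2.0 * df
    bic = -2.0 * loglik + df * np.log(n)
    return float(aic), float(bic)


def wald_tests(fit: FittedLMM, criterion: float = 1.96) -> pd.DataFrame:
    """Coefficient table with t statistics and the two-tailed |t| >= 1.96 flag.

    With hundreds of subjects and thousands of observations the t statistic
    is effectively a z statistic, so no degrees-of-freedom approximation is
    attempted.
    """
    return pd.DataFrame(
        {
            "term": fit.term_names,
            "estimate": fit.beta,
            "se": fit.se,
            "t": fit.t,
            "significant": np.abs(fit.t) >= criterion,
        }
    )
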