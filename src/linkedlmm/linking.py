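"""Linked linear mixed models.

A first LMM for fixation location is decomposed, observation by
observation, into its predictions (fixed plus random parts) and its
conditional residuals:

    x = xhat + eps_x.

The second LMM, for log fixation duration, then receives second-order
orthogonal polynomials of ``xhat`` and/or ``eps_x`` as extra fixed-effect
columns.  Because the decomposition is exact and the two parts are
(empirically) uncorrelated, the linked model separates effects of the
*intended* fixation location from effects of oculomotor error — the route
by which the inverted-optimal-viewing-position effect can be attributed to
mislocated fixations.

The module provides sequential fitting, model comparison across link
modes, a block-coordinate joint fit of the two models, a parametric
bootstrap assessing the stability of the link coefficients, and the
covariate-removal experiment that shifts a covariate's contribution from
the prediction path to the residual path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    DesignMatrices,
    FixedTerm,
    ModelSpec,
    build_design,
)
from .lmm import FitReport, FittedLMM, fit_lmm, profiled_deviance, _PLSWorkspace

__all__ = [
    "LINK_MODES",
    "Decomposition",
    "LinkedFit",
    "JointFit",
    "ReliabilityResult",
    "decompose",
    "fit_linked_sequential",
    "compare_models",
    "joint_fit",
    "reliability_simulation",
    "covariate_removal_shift",
    "link_coefficient_table",
]

LINK_MODES = ("none", "observed", "predicted", "residual", "both")

#: data columns created for the decomposition legs
_MODE_COLUMNS = {
    "none": [],
    "observed": ["rel_loc"],
    "predicted": ["xhat"],
    "residual": ["resid_loc"],
    "both": ["xhat", "resid_loc"],
}


@dataclass
class Decomposition:
    """Exact split of the first model's response into prediction and residual."""

    xhat: np.ndarray
    resid: np.ndarray
    rho: float

    @property
    def x(self) -> np.ndarray:
        return self.xhat + self.resid


@dataclass
class LinkedFit:
    """Sequentially fitted pair of models.

    ``fit1`` is ``None`` for modes that never touch the first model
    (``none`` and ``observed``).
    """

    mode: str
    fit1: FittedLMM | None
    fit2: FittedLMM
    decomposition: Decomposition | None
    link_columns: list[str]

    def link_table(self) -> pd.DataFrame:
        return link_coefficient_table(self)


@dataclass
class JointFit:
    fit1: FittedLMM
    fit2: FittedLMM
    joint_loglik: float
    sequential_loglik: float
    n_outer: int
    trace: list[float]


@dataclass
class ReliabilityResult:
    n_requested: int
    n_completed: int
    n_failed: int
    seed: int
    summary: pd.DataFrame
    draws: pd.DataFrame


def decompose(fit1: FittedLMM) -> Decomposition:
    """Split the fitted first model into predictions and residuals.

    The identity ``xhat + eps_x == x`` holds to machine precision because
    the residuals are defined as the complement of the fitted values.  The
    correlation between the two parts is reported as a diagnostic; it is
    near zero whenever the model carries an intercept.
    """
    xhat = fit1.fitted
    resid = fit1.residuals
    if np.std(xhat) > 0 and np.std(resid) > 0:
        rho = float(np.corrcoef(xhat, resid)[0, 1])
    else:
        rho = np.nan
    return Decomposition(xhat=xhat, resid=resid, rho=rho)


def _augmented_spec(spec2: ModelSpec, mode: str) -> ModelSpec:
    """Append degree-2 polynomial link terms for ``mode`` to a base spec."""
    base = [t for t in spec2.fixed
            if not (t.degree > 1 and t.name in ("rel_loc", "xhat", "resid_loc"))]
    fixed = base + [FixedTerm(c, degree=2) for c in _MODE_COLUMNS[mode]]
    return ModelSpec(
        response=spec2.response,
        fixed=fixed,
        random=spec2.random,
        label=f"{spec2.label or 'model2'}/{mode}",
    )


def _data_frame(table) -> pd.DataFrame:
    return table.data if hasattr(table, "data") else table


def fit_linked_sequential(
    table,
    spec1: ModelSpec | None,
    spec2: ModelSpec,
    mode: str = "both",
    fit1: FittedLMM | None = None,
    **fit_options,
) -> LinkedFit:
    """Fit the two models sequentially.

    ``spec2`` is the base duration model (no location terms); the link
    columns implied by ``mode`` are appended as second-order orthogonal
    polynomials.  For modes ``none`` and ``observed`` the first model is
    never fitted, so those fits are identical whether or not a first model
    exists.  A pre-fitted first model may be passed to avoid refitting.
    """
    if mode not in LINK_MODES:
        raise ValueError(f"unknown link mode {mode!r}; expected one of {LINK_MODES}")
    df = _data_frame(table).copy()

    decomp = None
    if mode in ("predicted", "residual", "both"):
        if fit1 is None:
            if spec1 is None:
                raise ValueError(f"mode {mode!r} requires a first-model spec")
            fit1 = fit_lmm(build_design(spec1, df), **fit_options)
        decomp = decompose(fit1)
        df["xhat"] = decomp.xhat
        df["resid_loc"] = decomp.resid
    else:
        fit1 = None

    for col in _MODE_COLUMNS[mode]:
        if np.std(df[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"link covariate {col!r} has zero variance")

    spec2_aug = _augmented_spec(spec2, mode)
    fit2 = fit_lmm(build_design(spec2_aug, df), **fit_options)
    link_cols = _MODE_COLUMNS[mode]
    return LinkedFit(mode=mode, fit1=fit1, fit2=fit2,
                     decomposition=decomp, link_columns=link_cols)


def link_coefficient_table(linked: LinkedFit) -> pd.DataFrame:
    """Linear and quadratic link coefficients on both scales.

    The model is fitted on data-dependent orthonormal bases; for
    comparison across data sets the coefficients are also mapped back to
    raw monomial scale (coefficients of v and v^2) with delta-method
    standard errors.
    """
    fit = linked.fit2
    rows = []
    for col in linked.link_columns:
        pb = fit.design.poly_bases[col]
        idx = [fit.term_names.index(f"{col}^{k}") for k in (1, 2)]
        b = fit.beta[idx]
        covb = fit.vcov_beta[np.ix_(idx, idx)]
        raw = pb.raw_map @ b                      # [const, lin, quad]
        cov_raw = pb.raw_map @ covb @ pb.raw_map.T
        for order, j in (("linear", 1), ("quadratic", 2)):
            est_b = b[j - 1]
            se_b = float(np.sqrt(covb[j - 1, j - 1]))
            est_r = raw[j]
            se_r = float(np.sqrt(cov_raw[j, j]))
            rows.append(
                {
                    "variable": col,
                    "order": order,
                    "estimate": est_b,
                    "se": se_b,
                    "t": est_b / se_b,
                    "raw_estimate": est_r,
                    "raw_se": se_r,
                    "raw_t": est_r / se_r,
                    "significant": abs(est_b / se_b) >= 1.96,
                }
            )
    return pd.DataFrame(rows)


def compare_models(
    table,
    spec1: ModelSpec | None,
    spec2: ModelSpec,
    modes=("none", "observed", "predicted", "residual", "both"),
    **fit_options,
) -> FitReport:
    """Goodness-of-fit comparison across link modes (df, AIC, BIC, logLik).

    The first model is fitted once and shared by all decomposition-based
    modes.  Rows are sorted by AIC ascending, ties broken by df.
    """
    if not modes:
        raise ValueError("need at least one mode")
    bad = [m for m in modes if m not in LINK_MODES]
    if bad:
        raise ValueError(f"unknown mode(s) {bad}; expected members of {LINK_MODES}")
    fit1 = None
    if any(m in ("predicted", "residual", "both") for m in modes):
        if spec1 is None:
            raise ValueError("decomposition modes require a first-model spec")
        fit1 = fit_lmm(build_design(spec1, _data_frame(table)), **fit_options)
    fits, labels = [], []
    for m in modes:
        lf = fit_linked_sequential(table, spec1, spec2, mode=m, fit1=fit1,
                                   **fit_options)
        fits.append(lf.fit2)
        labels.append(m)
    return FitReport.from_fits(labels, fits)


def _joint_objective_parts(
    theta1: np.ndarray,
    work1: _PLSWorkspace,
    df: pd.DataFrame,
    spec2_aug: ModelSpec,
    theta2: np.ndarray,
) -> float:
    """Joint profiled log-likelihood at model-1 ``theta1`` and fixed
    model-2 ``theta2``; model-1 coefficients and modes are the penalized
    least-squares solution at ``theta1`` (plug-in block update)."""
    d1 = work1.design
    n1 = work1.n
    beta, u, r2, logdet, _ = work1.solve(np.maximum(theta1, 0.0))
    dev1 = logdet + n1 * (1.0 + np.log(2.0 * np.pi) + np.log(r2 / n1))
    gamma = np.maximum(theta1, 0.0)[work1.scale_index] * u if work1.q else None
    fitted = d1.X @ beta + (d1.Z @ gamma if gamma is not None else 0.0)
    df = df.copy()
    df["xhat"] = fitted
    df["resid_loc"] = d1.y - fitted
    design2 = build_design(spec2_aug, df)
    dev2 = profiled_deviance(theta2, design2)
    return -0.5 * (dev1 + dev2)


def joint_fit(
    table,
    spec1: ModelSpec,
    spec2: ModelSpec,
    max_outer: int = 8,
    tol: float = 1e-6,
    **fit_options,
) -> JointFit:
    """Joint estimation of the linked pair by block-coordinate ascent.

    Linking makes the pair a single nonlinear mixed model.  Starting from
    the sequential solution, the ascent alternates (a) re-optimizing the
    first model's variance parameters against the *joint* profiled
    log-likelihood (the second model's variance parameters held fixed, its
    coefficients re-profiled on the updated decomposition) and (b) a full
    refit of the second model on the updated decomposition.  Every step is
    accepted only if the joint log-likelihood improves, so the result can
    never fall below the sequential plug-in value.
    """
    from scipy import optimize

    df = _data_frame(table).copy()
    seq = fit_linked_sequential(df, spec1, spec2, mode="both", **fit_options)
    spec2_aug = _augmented_spec(spec2, "both")
    fit1, fit2 = seq.fit1, seq.fit2
    design1 = fit1.design
    work1 = _PLSWorkspace(design1)

    joint_ll = fit1.loglik + fit2.loglik
    seq_ll = joint_ll
    trace = [joint_ll]
    theta1 = fit1.theta.copy()

    for _ in range(max_outer):
        theta2 = fit2.theta.copy()

        def neg_joint(th1):
            return -_joint_objective_parts(th1, work1, df, spec2_aug, theta2)

        res = optimize.minimize(
            neg_joint, theta1, method="Powell",
            bounds=[(0.0, None)] * theta1.size,
            options={"maxiter": 2, "xtol": 1e-6, "ftol": 1e-9},
        )
        cand_theta1 = np.maximum(res.x, 0.0)
        # rebuild the decomposition at the candidate and refit model 2 fully
        beta, u, *_ = work1.solve(cand_theta1)
        gamma = cand_theta1[work1.scale_index] * u if work1.q else None
        fitted = design1.X @ beta + (design1.Z @ gamma if gamma is not None else 0.0)
        df_cand = df.copy()
        df_cand["xhat"] = fitted
        df_cand["resid_loc"] = design1.y - fitted
        cand_fit2 = fit_lmm(build_design(spec2_aug, df_cand), theta0=theta2,
                            **fit_options)
        dev1 = profiled_deviance(cand_theta1, design1, work1)
        cand_ll = -0.5 * dev1 + cand_fit2.loglik
        if cand_ll > joint_ll + tol:
            theta1 = cand_theta1
            fit2 = cand_fit2
            joint_ll = cand_ll
            trace.append(joint_ll)
        else:
            break

    if not np.array_equal(theta1, fit1.theta):
        fit1 = _refit_at_theta(design1, theta1)
    if joint_ll < seq_ll - 1e-8:
        raise RuntimeError(
            f"joint log-likelihood {joint_ll:.6f} fell below the sequential "
            f"value {seq_ll:.6f}; trace: {trace}"
        )
    return JointFit(fit1=fit1, fit2=fit2, joint_loglik=float(joint_ll),
                    sequential_loglik=float(seq_ll),
                    n_outer=len(trace) - 1, trace=trace)


def _refit_at_theta(design: DesignMatrices, theta: np.ndarray) -> FittedLMM:
    """Evaluate the model at fixed theta (no optimization)."""
    work = _PLSWorkspace(design)
    beta, u, r2, logdet, S = work.solve(theta)
    n, p = design.n, design.X.shape[1]
    sigma2 = r2 / n
    dev = logdet + n * (1.0 + np.log(2.0 * np.pi) + np.log(r2 / n))
    vcov = sigma2 * np.linalg.inv(S)
    se = np.sqrt(np.diag(vcov))
    modes, varcomps = {}, {}
    if work.q:
        gamma = theta[work.scale_index] * u
        for b_i, blk in enumerate(design.blocks):
            modes[blk.name] = gamma[blk.start:blk.stop]
            varcomps[blk.name] = float((theta[b_i] ** 2) * sigma2)
        fitted = design.X @ beta + design.Z @ gamma
    else:
        fitted = design.X @ beta
    return FittedLMM(
        beta=beta, se=se, t=beta / se, term_names=list(design.x_names),
        theta=np.asarray(theta, float), sigma2=float(sigma2),
        variance_components=varcomps, conditional_modes=modes,
        loglik=float(-0.5 * dev), df=p + len(design.blocks) + 1, n=n,
        fitted=fitted, residuals=design.y - fitted, vcov_beta=vcov,
        converged=True, boundary=np.asarray(theta) < 1e-6, design=design,
    )


def simulate_response(fit1: FittedLMM, rng: np.random.Generator,
                      conditional: bool = False) -> np.ndarray:
    """Draw a new response vector from the first model's estimated
    distribution.

    Parametric bootstrap by default: both the random effects and the
    residuals are resampled from their estimated Gaussian distributions.
    With ``conditional=True`` the original conditional modes are kept and
    only residual noise is redrawn.
    """
    return fit1.design.X @ fit1.beta + _draw_random_part(fit1, rng,
                                                         conditional)


def _draw_random_part(fit: FittedLMM, rng: np.random.Generator,
                      conditional: bool) -> np.ndarray:
    """Random-effect contribution plus residual noise, freshly drawn."""
    design = fit.design
    out = np.zeros(design.n)
    if design.Z is not None:
        if conditional:
            gamma = np.concatenate(
                [fit.conditional_modes[blk.name] for blk in design.blocks]
            )
        else:
            sds = np.sqrt(np.maximum(
                [fit.variance_components[blk.name] for blk in design.blocks],
                0.0,
            ))
            gamma = np.concatenate(
                [rng.normal(0.0, sds[i], blk.n_levels)
                 for i, blk in enumerate(design.blocks)]
            )
        out = out + design.Z @ gamma
    return out + rng.normal(0.0, np.sqrt(fit.sigma2), design.n)


def _raw_link_functions(linked: LinkedFit) -> dict[str, np.ndarray]:
    """Raw-scale polynomial coefficients [c0, c1, c2] per link leg."""
    fit = linked.fit2
    out = {}
    for col in linked.link_columns:
        pb = fit.design.poly_bases[col]
        idx = [fit.term_names.index(f"{col}^{k}") for k in (1, 2)]
        out[col] = pb.raw_map @ fit.beta[idx]
    return out


def reliability_simulation(
    fit1: FittedLMM,
    spec2: ModelSpec,
    table,
    n_reps: int,
    seed: int,
    conditional: bool = False,
    **fit_options,
) -> ReliabilityResult:
    """Parametric bootstrap of the linked pair, assessing the stability of
    the link coefficients.

    Each replicate (a) samples a fresh location vector from the first
    model's estimated distribution and refits the first model on it,
    (b) decomposes it into new predictions and residuals, (c) simulates
    log durations from the fitted second model driven by that new
    decomposition (word-property effects, the estimated link polynomials
    on raw scale, resampled random effects and residual noise), and
    (d) refits the linked duration model.  Resampling only the location
    side would decouple the new residuals from the observed durations and
    drive every link coefficient to zero, which is not the procedure being
    assessed: the question is whether the *pair* reproduces its own
    estimates.  With ``conditional=True`` the original conditional modes
    are kept on both sides and only residual noise is redrawn.

    Reported per link coefficient: mean, SD and the fraction of
    replicates significant at |t| >= 1.96.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    df = _data_frame(table).copy()
    design1 = fit1.design

    orig = fit_linked_sequential(df, None, spec2, mode="both", fit1=fit1,
                                 **fit_options)
    fit2 = orig.fit2
    design2 = fit2.design
    link_raw = _raw_link_functions(orig)
    link_cols = {f"{c}^{k}" for c in orig.link_columns for k in (1, 2)}
    base_idx = [j for j, n in enumerate(fit2.term_names) if n not in link_cols]
    base_eta = design2.X[:, base_idx] @ fit2.beta[base_idx]
    response = spec2.response

    records = []
    n_failed = 0
    theta2 = None  # warm start for the second model across replicates
    for rep in range(n_reps):
        x_star = simulate_response(fit1, rng, conditional=conditional)
        try:
            d1 = DesignMatrices(
                y=x_star, X=design1.X, x_names=design1.x_names, Z=design1.Z,
                blocks=design1.blocks, n=design1.n,
                poly_bases=design1.poly_bases,
            )
            refit1 = fit_lmm(d1, theta0=fit1.theta, **fit_options)
            xhat_star = refit1.fitted
            eps_star = refit1.residuals
            eta2 = base_eta.copy()
            for col, v in (("xhat", xhat_star), ("resid_loc", eps_star)):
                c = link_raw[col]
                eta2 = eta2 + c[0] + c[1] * v + c[2] * v * v
            t_star = eta2 + _draw_random_part(fit2, rng, conditional)
            dfr = df.copy()
            dfr["rel_loc"] = x_star
            dfr[response] = t_star
            linked = fit_linked_sequential(dfr, None, spec2, mode="both",
                                           fit1=refit1, theta0=theta2,
                                           **fit_options)
            theta2 = linked.fit2.theta
            tab = linked.link_table()
            tab.insert(0, "replicate", rep)
            records.append(tab)
        except Exception:
            n_failed += 1
    if not records:
        raise RuntimeError("all replicates failed")
    draws = pd.concat(records, ignore_index=True)
    summary = (
        draws.groupby(["variable", "order"], sort=False)
        .agg(
            mean=("raw_estimate", "mean"),
            sd=("raw_estimate", "std"),
            mean_basis=("estimate", "mean"),
            sd_basis=("estimate", "std"),
            frac_significant=("significant", "mean"),
        )
        .reset_index()
    )
    return ReliabilityResult(
        n_requested=n_reps,
        n_completed=len(records),
        n_failed=n_failed,
        seed=seed,
        summary=summary,
        draws=draws,
    )


def covariate_removal_shift(
    table,
    spec1: ModelSpec,
    spec2: ModelSpec,
    drop: str,
    **fit_options,
) -> tuple[LinkedFit, LinkedFit]:
    """Linked fits with and without one first-model covariate.

    Removing a covariate from the first model moves its contribution from
    the predictions to the residuals; if the covariate truly drives the
    second outcome, the residual-path link coefficients shift.
    Returns ``(full, reduced)``.
    """
    names = [t.name for t in spec1.fixed]
    if drop not in names:
        raise ValueError(f"covariate {drop!r} not in the first model ({names})")
    remaining = [t for t in spec1.fixed if t.name != drop and t.by != drop]
    if not remaining:
        raise ValueError("cannot drop the only covariate of the first model")
    spec1_red = ModelSpec(
        response=spec1.response,
        fixed=remaining,
        random=spec1.random,
        label=f"{spec1.label or 'model1'}-without-{drop}",
    )
    full = fit_linked_sequential(table, spec1, spec2, mode="both", **fit_options)
    reduced = fit_linked_sequential(table, spec1_red, spec2, mode="both",
                                    **fit_options)
    return full, reduced
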