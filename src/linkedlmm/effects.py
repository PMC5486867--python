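"""Partial effects: adjusted responses for effect visualization.

A fitted mixed model explains the response as intercept + fixed-term
contributions + random-block contributions + residuals.  For plotting one
effect against its covariate, the observed response is adjusted by
*removing* every contribution that is not of interest (remef-style): the
result still carries observation-level scatter but only the kept effects'
structure.  Adjusted values live on the model scale (log duration);
``backtransform=True`` exponentiates them to milliseconds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .lmm import FittedLMM

__all__ = ["partial_effects", "effect_curve"]


def _term_contributions(fit: FittedLMM) -> dict[str, np.ndarray]:
    X = fit.design.X
    return {
        name: X[:, j] * fit.beta[j]
        for j, name in enumerate(fit.term_names)
        if name != "(Intercept)"
    }


def partial_effects(
    fit: FittedLMM,
    keep_fixed: list[str] | None = None,
    keep_random: list[str] | None = None,
    keep_residuals: bool = True,
    backtransform: bool = False,
) -> np.ndarray:
    """Observed response minus every contribution not kept.

    ``keep_fixed`` names fixed-effect columns (e.g. ``"log_freq_n_c"`` or
    ``"rel_loc^2"``), ``keep_random`` names random blocks (e.g.
    ``"subject"`` or ``"subject:log_freq_n_c"``).  The intercept is always
    kept.  Keeping everything (and residuals) returns the response
    unchanged.
    """
    keep_fixed = list(keep_fixed or [])
    keep_random = list(keep_random or [])

    fixed = _term_contributions(fit)
    unknown = [t for t in keep_fixed if t not in fixed]
    if unknown:
        raise ValueError(
            f"unknown fixed term(s) {unknown}; valid names: {sorted(fixed)}"
        )
    unknown = [b for b in keep_random if b not in fit.conditional_modes]
    if unknown:
        raise ValueError(
            f"unknown random block(s) {unknown}; valid names: "
            f"{sorted(fit.conditional_modes)}"
        )

    adjusted = fit.design.y.astype(float).copy()
    for name, contrib in fixed.items():
        if name not in keep_fixed:
            adjusted -= contrib
    if fit.design.Z is not None:
        for blk in fit.design.blocks:
            if blk.name not in keep_random:
                sub = fit.design.Z[:, blk.start:blk.stop]
                adjusted -= sub @ fit.conditional_modes[blk.name]
    if not keep_residuals:
        adjusted -= fit.residuals
    return np.exp(adjusted) if backtransform else adjusted


def effect_curve(
    fit: FittedLMM,
    term: str,
    grid,
    level: float = 0.95,
    backtransform: bool = False,
) -> pd.DataFrame:
    """Predicted response over a covariate grid for one polynomial term.

    Evaluates intercept + the term's polynomial contribution on the model
    scale, with pointwise confidence bands from the fixed-effects
    covariance of the involved coefficients (variance-component
    uncertainty is ignored).  Grid points outside the fitted covariate
    range trigger a warning, not an error.
    """
    if term not in fit.design.poly_bases:
        raise ValueError(
            f"{term!r} is not a fitted polynomial term; available: "
            f"{sorted(fit.design.poly_bases)}"
        )
    pb = fit.design.poly_bases[term]
    grid = np.asarray(grid, dtype=float)
    if grid.min() < pb.vmin or grid.max() > pb.vmax:
        warnings.warn(
            f"grid extends beyond the fitted range of {term!r} "
            f"[{pb.vmin:.3g}, {pb.vmax:.3g}]; extrapolating",
            stacklevel=2,
        )
    idx = [fit.term_names.index("(Intercept)")]
    idx += [fit.term_names.index(f"{term}^{k}") for k in range(1, pb.degree + 1)]
    B = pb.evaluate(grid)
    design_rows = np.column_stack([np.ones(len(grid)), B])
    coefs = fit.beta[idx]
    cov = fit.vcov_beta[np.ix_(idx, idx)]
    pred = design_rows @ coefs
    se = np.sqrt(np.einsum("ij,jk,ik->i", design_rows, cov, design_rows))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    out = pd.DataFrame(
        {
            "grid": grid,
            "predicted": pred,
            "lower": pred - z * se,
            "upper": pred + z * se,
        }
    )
    if backtransform:
        for c in ("predicted", "lower", "upper"):
            out[c] = np.exp(out[c])
    return out
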