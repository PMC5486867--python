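"""Design-matrix construction for crossed random-effects models.

A :class:`ModelSpec` declares the response, the fixed-effect terms
(continuous mains, treatment-coded interactions, orthogonal polynomials)
and the random-effects structure (per grouping factor: which covariates get
an independent variance component).  :func:`build_design` turns a spec plus
a fixation table into the dense fixed matrix ``X``, the sparse random
matrix ``Z`` and the block-to-parameter map the fitter consumes.

Column order is deterministic: intercept, mains in declaration order,
interactions, then polynomial bases — so coefficient tables are
reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "FixedTerm",
    "RandomTerm",
    "ModelSpec",
    "ZBlock",
    "DesignMatrices",
    "PolyBasis",
    "orthogonal_poly",
    "encode_contrast",
    "build_design",
    "preset_location_spec",
    "preset_duration_spec",
    "LOCATION_MAIN_EFFECTS",
    "DURATION_MAIN_EFFECTS",
]

#: Table-2-style location model: skipping plus oculomotor and word properties
LOCATION_MAIN_EFFECTS = [
    "skip", "log2_launch_c",
    "inv_len_nm1_c", "logit_pred_nm1_c", "log_freq_nm1_c",
    "inv_len_n_c", "logit_pred_n_c", "log_freq_n_c",
]

#: Table-4-style duration model: properties of words n-1, n, n+1
DURATION_MAIN_EFFECTS = [
    "inv_len_nm1_c", "logit_pred_nm1_c", "log_freq_nm1_c",
    "inv_len_n_c", "logit_pred_n_c", "log_freq_n_c",
    "inv_len_np1_c", "logit_pred_np1_c", "log_freq_np1_c",
]


@dataclass
class FixedTerm:
    """One fixed-effect term.

    ``degree`` > 1 expands the covariate into an orthogonal polynomial
    basis; ``by`` names a 0/1 contrast column whose elementwise product
    with the covariate forms an interaction column.
    """

    name: str
    degree: int = 1
    by: str | None = None

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.by is not None and self.degree > 1:
            raise ValueError("interaction terms with polynomials are not supported")


@dataclass
class RandomTerm:
    """Variance components for one grouping factor.

    ``covariates`` lists the columns receiving an independent (diagonal)
    variance component; ``"1"`` denotes the varying intercept.
    """

    factor: str
    covariates: list[str] = field(default_factory=lambda: ["1"])


@dataclass
class ModelSpec:
    response: str
    fixed: list[FixedTerm]
    random: list[RandomTerm]
    label: str = ""

    def term_columns(self) -> list[str]:
        """Fixed-effect column names in build order (excluding intercept)."""
        names: list[str] = []
        for t in self.fixed:
            if t.by is None and t.degree == 1:
                names.append(t.name)
        for t in self.fixed:
            if t.by is not None:
                names.append(f"{t.by}:{t.name}")
        for t in self.fixed:
            if t.by is None and t.degree > 1:
                names.extend(f"{t.name}^{k}" for k in range(1, t.degree + 1))
        return names


@dataclass
class ZBlock:
    """One random-effects block: a grouping factor crossed with a covariate."""

    name: str
    factor: str
    covariate: str  # "1" for intercepts
    start: int
    stop: int
    n_levels: int


@dataclass
class PolyBasis:
    """Orthonormal polynomial basis with its raw-monomial representation.

    ``raw_map`` has shape (degree+1, degree): column k of the basis equals
    ``[1, v, v^2, ...] @ raw_map[:, k]``, which lets fitted basis
    coefficients be mapped back to ordinary polynomial coefficients and the
    basis be evaluated on new grids.
    """

    degree: int
    raw_map: np.ndarray
    vmin: float = -np.inf
    vmax: float = np.inf

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        W = np.vander(grid, self.degree + 1, increasing=True)
        return W @ self.raw_map

    def to_raw_coefficients(self, coefs: np.ndarray) -> np.ndarray:
        """Map basis coefficients to raw monomial coefficients [c0, c1, ...]."""
        return self.raw_map @ np.asarray(coefs, dtype=float)


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    Z: sparse.csc_matrix | None
    blocks: list[ZBlock]
    n: int
    poly_bases: dict[str, PolyBasis] = field(default_factory=dict)

    @property
    def n_theta(self) -> int:
        return len(self.blocks)


def orthogonal_poly(values, degree: int):
    """Orthonormal polynomial basis over the realized values.

    Columns are mutually orthogonal, unit norm and orthogonal to the
    constant; column k spans degree-k polynomial space and the sign is
    fixed so the linear column increases with the input.

    Returns ``(basis, PolyBasis)``.
    """
    v = np.asarray(values, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if np.unique(v).size < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct values for degree {degree}"
        )
    # center for conditioning; the span is unchanged
    vc = v - v.mean()
    W = np.vander(vc, degree + 1, increasing=True)
    Q, R = np.linalg.qr(W)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    B = Q[:, 1:]
    # represent in uncentered monomials for evaluation on new grids
    Wraw = np.vander(v, degree + 1, increasing=True)
    raw_map, *_ = np.linalg.lstsq(Wraw, B, rcond=None)
    return B, PolyBasis(degree=degree, raw_map=raw_map,
                        vmin=float(v.min()), vmax=float(v.max()))


def encode_contrast(values, levels, reference):
    """Treatment-code a categorical column: reference -> 0, other -> 1."""
    levels = list(levels)
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among levels {levels}")
    if len(levels) != 2:
        raise ValueError("only two-level treatment contrasts are supported")
    arr = np.asarray(values)
    known = np.isin(arr, levels)
    if not known.all():
        bad = np.unique(arr[~known])
        raise ValueError(f"unknown level(s) {bad.tolist()}; expected {levels}")
    return (arr != reference).astype(float)


def _column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        raise ValueError(f"column {name!r} not in table")
    return df[name].to_numpy(dtype=float)


def build_design(spec: ModelSpec, table) -> DesignMatrices:
    """Assemble y, X and the sparse Z blocks for one model."""
    df = table.data if hasattr(table, "data") else table
    n = len(df)
    y = _column(df, spec.response).copy()

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    poly_bases: dict[str, PolyBasis] = {}

    for t in spec.fixed:
        if t.by is None and t.degree == 1:
            cols.append(_column(df, t.name))
            names.append(t.name)
    for t in spec.fixed:
        if t.by is not None:
            cols.append(_column(df, t.by) * _column(df, t.name))
            names.append(f"{t.by}:{t.name}")
    for t in spec.fixed:
        if t.by is None and t.degree > 1:
            basis, pb = orthogonal_poly(_column(df, t.name), t.degree)
            poly_bases[t.name] = pb
            for k in range(t.degree):
                cols.append(basis[:, k])
                names.append(f"{t.name}^{k + 1}")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved: those whose removal restores full rank
        _, R = np.linalg.qr(X)
        small = np.abs(np.diag(R)) < 1e-8 * max(1.0, np.abs(np.diag(R)).max())
        guilty = [names[i] for i in np.where(small)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {guilty}")

    blocks: list[ZBlock] = []
    zparts: list[sparse.csc_matrix] = []
    offset = 0
    rows = np.arange(n)
    for rt in spec.random:
        codes, levels = pd.factorize(df[rt.factor], sort=True)
        g = len(levels)
        for cov in rt.covariates:
            vals = np.ones(n) if cov == "1" else _column(df, cov)
            zb = sparse.csc_matrix((vals, (rows, codes)), shape=(n, g))
            blocks.append(
                ZBlock(
                    name=f"{rt.factor}:{cov}" if cov != "1" else f"{rt.factor}",
                    factor=rt.factor,
                    covariate=cov,
                    start=offset,
                    stop=offset + g,
                    n_levels=g,
                )
            )
            zparts.append(zb)
            offset += g

    Z = sparse.hstack(zparts, format="csc") if zparts else None
    return DesignMatrices(
        y=y, X=X, x_names=names, Z=Z, blocks=blocks, n=n, poly_bases=poly_bases
    )


def preset_location_spec(full_interactions: bool = True) -> ModelSpec:
    """Fixation-location model: skipping, launch site, and properties of
    words n-1 and n, with skipping interactions and subject variance
    components for every main effect."""
    fixed = [FixedTerm(c) for c in LOCATION_MAIN_EFFECTS]
    if full_interactions:
        fixed += [FixedTerm(c, by="skip") for c in LOCATION_MAIN_EFFECTS[1:]]
    random = [
        RandomTerm("subject", ["1"] + LOCATION_MAIN_EFFECTS),
        RandomTerm("sentence", ["1"]),
        RandomTerm("word", ["1"]),
    ]
    return ModelSpec(response="rel_loc", fixed=fixed, random=random,
                     label="psc-location")


LINK_COLUMNS = {
    "none": [],
    "observed": ["rel_loc"],
    "predicted": ["xhat"],
    "residual": ["resid_loc"],
    "both": ["xhat", "resid_loc"],
}


def preset_duration_spec(link_mode: str = "none") -> ModelSpec:
    """Fixation-duration model: properties of words n-1, n, n+1 plus a
    second-order orthogonal polynomial of the selected location variable.

    ``link_mode`` selects the location covariate(s): ``none``, ``observed``
    (the observed relative location), ``predicted`` / ``residual`` (one leg
    of the first model's decomposition) or ``both``.
    """
    if link_mode not in LINK_COLUMNS:
        raise ValueError(
            f"unknown link mode {link_mode!r}; expected one of {sorted(LINK_COLUMNS)}"
        )
    fixed = [FixedTerm(c) for c in DURATION_MAIN_EFFECTS]
    fixed += [FixedTerm(c, degree=2) for c in LINK_COLUMNS[link_mode]]
    random = [
        RandomTerm("subject", ["1"] + DURATION_MAIN_EFFECTS),
        RandomTerm("sentence", ["1"]),
        RandomTerm("word", ["1"]),
    ]
    return ModelSpec(response="log_dur", fixed=fixed, random=random,
                     label=f"psc-duration/{link_mode}")
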