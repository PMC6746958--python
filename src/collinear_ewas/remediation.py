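"""Remediation strategies for cell-composition collinearity.

Three fixes are implemented and can be compared against the fully
adjusted model: dropping the highest-VIF cell type, replacing the six
proportions with their leading principal components, and residualizing
methylation on the cell proportions before regressing the outcome on the
residuals.  Two of these are exact reparameterizations when used in full
(all six PCs, or residualization on the complete covariate set), so they
cannot change the methylation coefficient — the algebra behind the
observation that structural collinearity has no within-model fix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_fitting import RegressionFit, fit_methylation_model, fit_ols, _design_for_cpg
from .synthetic_cohort import CELL_TYPES

__all__ = [
    "PcaDecomposition",
    "ResidualSet",
    "drop_predictor_refit",
    "pca_cells",
    "pc_substitute_refit",
    "residual_refit",
    "residualize",
]


@dataclass(frozen=True)
class PcaDecomposition:
    loadings: pd.DataFrame            # cell-type by component
    scores: pd.DataFrame              # participant by component
    explained_variance: np.ndarray    # eigenvalues
    explained_variance_ratio: np.ndarray
    centered: bool
    scaled: bool


@dataclass(frozen=True)
class ResidualSet:
    residuals: pd.Series
    removed: tuple[str, ...]
    mode: str


def drop_predictor_refit(cohort: pd.DataFrame, cpg: str, drop: str) -> RegressionFit:
    """Refit the adjusted model with one named cell type removed."""
    if drop not in CELL_TYPES:
        raise ValueError(f"unknown cell type {drop!r}; expected one of {CELL_TYPES}")
    cells = tuple(c for c in CELL_TYPES if c != drop)
    return fit_methylation_model(cohort, cpg, cells=cells)


def pca_cells(cohort: pd.DataFrame, center: bool = True, scale: bool = False) -> PcaDecomposition:
    """Principal components of the six cell proportions (SVD-based).

    Components are ordered by decreasing variance; the sign of each
    component is fixed so that its largest-magnitude loading is positive,
    making results reproducible across linear-algebra backends.
    """
    cells = cohort[list(CELL_TYPES)].astype(float).dropna()
    if cells.shape[0] < 7:
        raise ValueError("PCA of six cell types needs at least 7 complete rows")
    X = cells.to_numpy()
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    if scale:
        sd = X.std(axis=0, ddof=1)
        near_zero = sd < 1e-10 * np.maximum(1.0, np.abs(mu) + np.abs(X).max(axis=0))
        if np.any(near_zero):
            bad = [CELL_TYPES[i] for i in np.flatnonzero(near_zero)]
            raise ValueError(f"cannot scale constant cell column(s) {bad}")
        Xc = Xc / sd
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
    scores = Xc @ vt.T
    var = s**2 / (Xc.shape[0] - 1)
    comp = [f"PC{i + 1}" for i in range(vt.shape[0])]
    return PcaDecomposition(
        loadings=pd.DataFrame(vt.T, index=list(CELL_TYPES), columns=comp),
        scores=pd.DataFrame(scores, index=cells.index, columns=comp),
        explained_variance=var,
        explained_variance_ratio=var / var.sum(),
        centered=center,
        scaled=scale,
    )


def pc_substitute_refit(cohort: pd.DataFrame, cpg: str, k: int,
                        center: bool = True, scale: bool = False) -> RegressionFit:
    """Adjust for the first ``k`` cell-proportion PCs instead of the cells.

    With ``k = 6`` the PC scores span the same column space as the six
    proportions, so the CpG coefficient is identical to the fully adjusted
    model's.
    """
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in 1..6, got {k}")
    pca = pca_cells(cohort, center=center, scale=scale)
    outcome, design = _design_for_cpg(cohort, cpg, ())
    design = design.join(pca.scores.iloc[:, :k])
    return fit_ols(outcome, design)


def residualize(values: pd.Series, covariates: pd.DataFrame, mode: str = "all") -> ResidualSet:
    """Least-squares residuals of ``values`` on ``covariates`` (with intercept)."""
    keep = values.notna() & covariates.notna().all(axis=1)
    y = values[keep].to_numpy(dtype=float)
    X = np.column_stack([np.ones(keep.sum()), covariates[keep].to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = pd.Series(np.nan, index=values.index, name=f"{values.name}_resid")
    resid[keep] = y - X @ beta
    return ResidualSet(residuals=resid, removed=tuple(covariates.columns), mode=mode)


def residual_refit(cohort: pd.DataFrame, cpg: str, mode: str = "each") -> list[RegressionFit]:
    """Regress the outcome on cell-residualized methylation.

    ``mode='each'`` residualizes the CpG on one cell type at a time (six
    fits); ``mode='all'`` residualizes on the six cell types jointly (one
    fit); ``mode='all_plus_demographics'`` additionally removes age and
    sex, which by the Frisch-Waugh-Lovell theorem reproduces the fully
    adjusted model's CpG coefficient exactly.  The outcome model always
    retains age and sex.
    """
    if mode not in ("each", "all", "all_plus_demographics"):
        raise ValueError(f"unknown mode {mode!r}")
    if cpg not in cohort.columns:
        raise KeyError(f"CpG column {cpg!r} not found in cohort")
    outcome = np.log(cohort["bmi"])
    if mode == "each":
        removed_sets = [(c,) for c in CELL_TYPES]
    elif mode == "all":
        removed_sets = [tuple(CELL_TYPES)]
    else:
        removed_sets = [tuple(CELL_TYPES) + ("age", "sex")]

    fits = []
    for removed in removed_sets:
        rs = residualize(cohort[cpg], cohort[list(removed)], mode=mode)
        if float(np.nanstd(rs.residuals.to_numpy())) < 1e-12:
            raise ValueError(
                f"residualizing {cpg!r} on {removed} leaves no variation to fit"
            )
        design = pd.DataFrame({
            f"{cpg}_resid": rs.residuals,
            "age": cohort["age"],
            "sex": cohort["sex"],
        })
        fits.append(fit_ols(outcome, design))
    return fits
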