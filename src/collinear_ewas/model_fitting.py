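"""OLS model families for the methylation-BMI analysis.

Each model regresses log BMI on CpG percent methylation, age and sex,
optionally adding estimated cell proportions as covariates.  Fits are
complete-case per model, so each CpG carries its own sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_cohort import CELL_TYPES

__all__ = [
    "RegressionFit",
    "ModelComparison",
    "fit_ols",
    "fit_methylation_model",
    "detect_sign_reversal",
    "ADJUSTMENTS",
]

#: adjustment label -> cell columns added to the design
ADJUSTMENTS = {
    "none": (),
    "six_cell": CELL_TYPES,
    "five_cell_no_gran": tuple(c for c in CELL_TYPES if c != "gran"),
}


@dataclass(frozen=True)
class RegressionFit:
    """Per-term OLS estimates with classical (t-based) inference.

    ``terms`` has one row per coefficient with columns
    ``term, beta, se, ci_low, ci_high, p``.
    """

    terms: pd.DataFrame
    n_used: int
    r_squared: float
    residual_df: int

    def term(self, name: str) -> pd.Series:
        rows = self.terms[self.terms["term"] == name]
        if rows.empty:
            raise KeyError(f"term {name!r} not in fit (have {list(self.terms['term'])})")
        return rows.iloc[0]

    def beta(self, name: str) -> float:
        return float(self.term(name)["beta"])

    def p_value(self, name: str) -> float:
        return float(self.term(name)["p"])


@dataclass(frozen=True)
class ModelComparison:
    """Sign/significance contrast for one term between two fits."""

    term: str
    beta_a: float
    beta_b: float
    p_a: float
    p_b: float
    alpha: float
    reversal_flag: bool
    significance_change_flag: bool


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns that are linear combinations of earlier ones (QR with pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    return [names[i] for i in sorted(piv[rank:])]


def fit_ols(outcome: pd.Series, design: pd.DataFrame, *, add_intercept: bool = True) -> RegressionFit:
    """Ordinary least squares with 95% t-based confidence intervals.

    Rows with a missing outcome or any missing design value are dropped;
    ``n_used`` reports the remainder.  Exactly collinear designs raise a
    ``ValueError`` naming the aliased columns.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), name="outcome")
    X = design.reset_index(drop=True).astype(float)
    y = y.reset_index(drop=True)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    names = list(X.columns)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
        names = ["const", *names]
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"insufficient complete rows: n={n} for {k} design columns")
    aliased = _find_aliased(X.to_numpy(), names)
    if aliased:
        raise ValueError(f"design is exactly collinear; aliased columns: {aliased}")

    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    ci = res.conf_int(alpha=0.05)
    terms = pd.DataFrame({
        "term": names,
        "beta": res.params,
        "se": res.bse,
        "ci_low": ci[:, 0],
        "ci_high": ci[:, 1],
        "p": res.pvalues,
    })
    return RegressionFit(
        terms=terms.reset_index(drop=True),
        n_used=int(res.nobs),
        r_squared=float(res.rsquared),
        residual_df=int(res.df_resid),
    )


def _design_for_cpg(cohort: pd.DataFrame, cpg: str, cells) -> tuple[pd.Series, pd.DataFrame]:
    if cpg not in cohort.columns:
        raise KeyError(f"CpG column {cpg!r} not found in cohort")
    bmi = cohort["bmi"]
    if (bmi.dropna() <= 0).any():
        raise ValueError("BMI must be strictly positive for the log transform")
    outcome = np.log(bmi)
    cols = [cpg, "age", "sex", *cells]
    return outcome, cohort[cols]


def fit_methylation_model(
    cohort: pd.DataFrame,
    cpg: str,
    adjustment: str = "none",
    *,
    cells=None,
) -> RegressionFit:
    """Fit log(BMI) ~ CpG% + age + sex [+ cell proportions].

    ``adjustment`` is one of ``none``, ``six_cell``, ``five_cell_no_gran``;
    alternatively pass an explicit ``cells`` sequence.
    """
    if cells is None:
        if adjustment not in ADJUSTMENTS:
            raise ValueError(
                f"unknown adjustment {adjustment!r}; expected one of {sorted(ADJUSTMENTS)}"
            )
        cells = ADJUSTMENTS[adjustment]
    outcome, design = _design_for_cpg(cohort, cpg, cells)
    return fit_ols(outcome, design)


def detect_sign_reversal(
    fit_a: RegressionFit,
    fit_b: RegressionFit,
    term: str,
    alpha: float = 0.05,
) -> ModelComparison:
    """Flag sign reversal and significance change for ``term`` across fits.

    A coefficient of exactly zero has no sign, so it can never register a
    reversal.
    """
    ta, tb = fit_a.term(term), fit_b.term(term)
    sa, sb = np.sign(ta["beta"]), np.sign(tb["beta"])
    reversal = bool(sa != 0 and sb != 0 and sa != sb)
    sig_change = bool((ta["p"] < alpha) != (tb["p"] < alpha))
    return ModelComparison(
        term=term,
        beta_a=float(ta["beta"]),
        beta_b=float(tb["beta"]),
        p_a=float(ta["p"]),
        p_b=float(tb["p"]),
        alpha=alpha,
        reversal_flag=reversal,
        significance_change_flag=sig_change,
    )
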