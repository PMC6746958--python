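"""Collinearity diagnostics: VIFs, correlation screens, condition indices.

The variance inflation factor of predictor j is 1/(1 - R2_j), where R2_j
comes from regressing predictor j on all other predictors (with
intercept).  Its reciprocal is the tolerance, and (1 - 1/VIF) * 100 is the
percentage of a predictor's variance explained by the others — the scale
on which a VIF of 5 corresponds to 80% shared variance, a common
acceptability cut-off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VifReport",
    "CorrelationMatrix",
    "ScreenReport",
    "compute_vif",
    "pct_variance_explained",
    "correlation_matrix",
    "high_correlation_screen",
    "condition_indices",
]

logger = logging.getLogger(__name__)

_INTERCEPT_NAMES = {"const", "intercept", "(intercept)"}


@dataclass(frozen=True)
class VifReport:
    """Per-predictor VIF, tolerance and percent variance explained."""

    table: pd.DataFrame            # columns: name, vif, tolerance, pct_var_explained
    model_id: str = ""
    warnings: tuple[str, ...] = ()

    def vif(self, name: str) -> float:
        rows = self.table[self.table["name"] == name]
        if rows.empty:
            raise KeyError(f"no VIF for predictor {name!r}")
        return float(rows.iloc[0]["vif"])


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise correlations with p-values and complete-pair counts."""

    method: str
    estimates: pd.DataFrame
    p_values: pd.DataFrame
    n_pairs: pd.DataFrame

    def r(self, a: str, b: str) -> float:
        return float(self.estimates.loc[a, b])


@dataclass(frozen=True)
class ScreenReport:
    """Array-wide |r_s| >= threshold screen of CpGs against cell types."""

    threshold: float
    n_cpgs: int
    counts: dict[str, int]
    fractions: dict[str, float]
    top: dict[str, pd.DataFrame]   # per cell: cpg, r_s sorted by |r_s| desc
    skipped_cells: tuple[str, ...] = ()


def pct_variance_explained(vif: float) -> float:
    """Percent of a predictor's variance explained by the other predictors."""
    if vif < 1.0 - 1e-9:
        raise ValueError(f"VIF must be >= 1, got {vif}")
    vif = max(vif, 1.0)
    return (1.0 - 1.0 / vif) * 100.0


def compute_vif(design: pd.DataFrame, exclude_intercept: bool = True,
                model_id: str = "") -> VifReport:
    """VIFs via auxiliary regressions of each predictor on the others.

    An exactly collinear predictor gets ``vif = inf`` (with a warning
    record) rather than raising, so array-scale sweeps are not aborted.
    Columns named like an intercept are dropped from the report when
    ``exclude_intercept`` is set; the auxiliary regressions always include
    an intercept regardless.
    """
    X = design.astype(float).dropna()
    names = [c for c in X.columns
             if not (exclude_intercept and str(c).lower() in _INTERCEPT_NAMES)]
    if len(names) < 2:
        raise ValueError("VIFs need at least two predictors")
    if X.shape[0] < len(names) + 3:
        raise ValueError("too few complete rows for VIF auxiliary regressions")
    sds = X[names].std(ddof=0)
    if (sds < 1e-12).any():
        bad = list(sds.index[sds < 1e-12])
        raise ValueError(f"constant predictor(s) {bad} have undefined VIF")

    notes: list[str] = []
    records = []
    M = X[names].to_numpy()
    for j, name in enumerate(names):
        y = M[:, j]
        others = np.column_stack([np.ones(len(M)), np.delete(M, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / tss
        if r2 >= 1.0 - 1e-12:
            vif = np.inf
            msg = f"predictor {name!r} is perfectly collinear with the others (VIF = inf)"
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
        else:
            vif = max(1.0 / (1.0 - r2), 1.0)
        tol = 0.0 if np.isinf(vif) else 1.0 / vif
        pct = 100.0 if np.isinf(vif) else pct_variance_explained(vif)
        records.append({"name": name, "vif": vif, "tolerance": tol,
                        "pct_var_explained": pct})
    return VifReport(table=pd.DataFrame(records), model_id=model_id,
                     warnings=tuple(notes))


def _pair_corr(x: np.ndarray, y: np.ndarray, method: str):
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[mask], y[mask]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return np.nan, np.nan, n
    if method == "pearson":
        r, p = stats.pearsonr(xs, ys)
    else:
        r, p = stats.spearmanr(xs, ys)
    return float(r), float(p), n


def correlation_matrix(table: pd.DataFrame, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise-complete Pearson or Spearman correlations.

    Spearman uses average ranks for ties; p-values come from the t
    approximation on r * sqrt((n-2)/(1-r^2)).  A constant column yields
    missing entries with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    cols = list(table.columns)
    k = len(cols)
    est = np.eye(k)
    pv = np.zeros((k, k))
    npairs = np.zeros((k, k), dtype=int)
    data = table.astype(float).to_numpy()
    for i in range(k):
        npairs[i, i] = int(np.isfinite(data[:, i]).sum())
        if np.nanstd(data[:, i]) == 0:
            warnings.warn(f"column {cols[i]!r} is constant; correlations undefined",
                          stacklevel=2)
    for i in range(k):
        for j in range(i + 1, k):
            r, p, n = _pair_corr(data[:, i], data[:, j], method)
            est[i, j] = est[j, i] = r
            pv[i, j] = pv[j, i] = p
            npairs[i, j] = npairs[j, i] = n
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationMatrix(method=method, estimates=mk(est), p_values=mk(pv),
                             n_pairs=mk(npairs))


def high_correlation_screen(
    methylation: pd.DataFrame,
    cells: pd.DataFrame,
    threshold: float = 0.700,
    top_k: int = 10,
    chunk_size: int = 5000,
    min_cell_sd: float = 1e-6,
) -> ScreenReport:
    """Screen a CpG-by-participant matrix against cell proportions.

    For every CpG and cell type the Spearman correlation is computed on
    pairwise-complete participants; CpGs with ``|r_s| >= threshold`` are
    counted per cell type.  Rows are processed in chunks so memory stays
    flat at array scale.  A cell type with (near-)zero variance is skipped
    with a logged notice, mirroring practice when an estimated fraction is
    essentially constant.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    shared = methylation.columns.intersection(cells.index)
    if len(shared) == 0:
        raise ValueError("no participant ids shared between methylation and cells")
    meth = methylation[shared]
    cell_df = cells.loc[shared]

    active, skipped = [], []
    for c in cell_df.columns:
        if float(np.nanstd(cell_df[c].to_numpy())) < min_cell_sd:
            skipped.append(c)
            logger.info("cell type %r has ~zero variance; skipped in screen", c)
        else:
            active.append(c)

    counts = {c: 0 for c in active}
    tops: dict[str, list[tuple[str, float]]] = {c: [] for c in active}
    n_cpgs = meth.shape[0]
    cvals = {c: cell_df[c].to_numpy(dtype=float) for c in active}
    for start in range(0, n_cpgs, chunk_size):
        block = meth.iloc[start:start + chunk_size]
        vals = block.to_numpy(dtype=float)
        ids = list(block.index)
        for row, cpg_id in zip(vals, ids):
            for c in active:
                r, _, n = _pair_corr(row, cvals[c], "spearman")
                if np.isnan(r):
                    continue
                if abs(r) >= threshold:
                    counts[c] += 1
                tops[c].append((cpg_id, r))

    top = {}
    for c in active:
        df = pd.DataFrame(tops[c], columns=["cpg", "r_s"])
        df = df.reindex(df["r_s"].abs().sort_values(ascending=False).index)
        top[c] = df.head(top_k).reset_index(drop=True)
    fractions = {c: counts[c] / n_cpgs for c in active}
    return ScreenReport(threshold=threshold, n_cpgs=n_cpgs, counts=counts,
                        fractions=fractions, top=top,
                        skipped_cells=tuple(skipped))


def condition_indices(design: pd.DataFrame) -> np.ndarray:
    """Condition indices of the column-scaled design, sorted ascending.

    Each column is scaled to unit Euclidean length; the indices are the
    largest singular value divided by each singular value.  Values much
    greater than ~30 flag near-linear dependencies.
    """
    X = design.astype(float).dropna().to_numpy()
    if X.shape[1] < 2:
        raise ValueError("condition indices need at least two columns")
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        bad = [design.columns[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero column(s) {bad} in design")
    s = np.linalg.svd(X / norms, compute_uv=False)
    s = np.where(s <= 0, np.finfo(float).tiny, s)
    return np.sort(s.max() / s)
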