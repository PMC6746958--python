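"""Seeded synthetic cohorts with EWAS-style collinearity structure.

The generator emulates a blood-methylation cohort in which CpG percent
methylation, six Houseman-estimated leukocyte proportions (CD8 T, CD4 T,
NK, B cells, monocytes, granulocytes) and a log-normal BMI outcome are
jointly Gaussian with a prescribed correlation matrix.  The cell-cell
correlation block — which no summary table prints — is completed by a
latent near-compositional construction: the five non-granulocyte cells
share a single latent factor, and granulocytes are (a constant minus the
sum of the other five) plus a small independent remainder, so the six
proportions nearly sum to one and carry the compositional collinearity
that makes cell-type adjustment hazardous.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

__all__ = [
    "CELL_TYPES",
    "CohortSpec",
    "correlated_gaussian_sample",
    "generate_cohort",
    "default_raine_like_spec",
    "build_latent_correlation_matrix",
    "validate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

logger = logging.getLogger(__name__)

#: Houseman leukocyte subtypes, in the column order used throughout.
CELL_TYPES = ("cd8t", "cd4t", "nk", "bcell", "mono", "gran")


# ---------------------------------------------------------------------------
# spec container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Inputs for :func:`generate_cohort`.

    ``correlation_matrix`` is the full target Pearson correlation among
    ``[outcome] + cpg_names + cell_names`` on the latent Gaussian scale
    (outcome = log BMI, methylation in percent, proportions in [0, 1]).
    """

    n_participants: int
    outcome_mean: float
    outcome_sd: float
    cpg_names: tuple[str, ...]
    cpg_means: tuple[float, ...]
    cpg_sds: tuple[float, ...]
    cell_names: tuple[str, ...]
    cell_means: tuple[float, ...]
    cell_sds: tuple[float, ...]
    correlation_matrix: np.ndarray
    missingness_rates: tuple[float, ...]
    seed: int = 0
    age_mean: float = 17.0
    age_sd: float = 0.25
    sex_prob: float = 0.5

    @property
    def variable_names(self) -> list[str]:
        return ["outcome", *self.cpg_names, *self.cell_names]

    def validate(self) -> None:
        k = 1 + len(self.cpg_names) + len(self.cell_names)
        corr = np.asarray(self.correlation_matrix, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(
                f"correlation_matrix shape {corr.shape} does not match "
                f"{k} variables ({self.variable_names})"
            )
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("correlation_matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("correlation_matrix must have a unit diagonal")
        if np.any(np.abs(corr) > 1 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if len(self.cell_names) != 6:
            raise ValueError("exactly six cell types are expected")
        if not all(0.0 < m < 1.0 for m in self.cell_means):
            raise ValueError("cell means must lie in (0, 1)")
        if not all(0.0 <= r < 1.0 for r in self.missingness_rates):
            raise ValueError("missingness rates must lie in [0, 1)")
        if len(self.missingness_rates) != len(self.cpg_names):
            raise ValueError("one missingness rate per CpG is required")
        if self.n_participants < k + 2:
            raise ValueError(
                f"n_participants={self.n_participants} too small for {k} model terms"
            )

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        d["correlation_matrix"] = np.asarray(self.correlation_matrix).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d["correlation_matrix"] = np.asarray(d["correlation_matrix"], dtype=float)
        for key in ("cpg_names", "cpg_means", "cpg_sds", "cell_names",
                    "cell_means", "cell_sds", "missingness_rates"):
            d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# multivariate normal sampling
# ---------------------------------------------------------------------------

def _check_correlation(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"correlation matrix must be square, got shape {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    return corr


def correlated_gaussian_sample(
    n: int,
    means,
    sds,
    corr,
    seed: int,
    *,
    repair: bool = False,
) -> np.ndarray:
    """Draw ``n`` joint Gaussian rows with the given marginal moments.

    Sampling is by Cholesky factorization of ``corr``; a fixed seed gives a
    fixed sample.  A non-positive-definite ``corr`` raises (reporting the
    smallest eigenvalue) unless ``repair=True``, in which case the nearest
    positive-definite correlation matrix is substituted and the Frobenius
    distance moved is logged.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    corr = _check_correlation(corr)
    k = corr.shape[0]
    if means.shape != (k,) or sds.shape != (k,):
        raise ValueError(
            f"dimension mismatch: corr is {k}x{k}, means {means.shape}, sds {sds.shape}"
        )
    if np.any(sds <= 0):
        raise ValueError("all standard deviations must be positive")

    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        smallest = float(np.linalg.eigvalsh(corr)[0])
        if not repair:
            raise ValueError(
                "correlation matrix is not positive definite "
                f"(smallest eigenvalue {smallest:.3e}); pass repair=True to "
                "project to the nearest positive-definite matrix"
            )
        repaired = corr_nearest(corr, threshold=1e-10)
        dist = float(np.linalg.norm(repaired - corr))
        logger.warning(
            "repaired non-positive-definite correlation matrix "
            "(smallest eigenvalue %.3e, Frobenius distance moved %.3e)",
            smallest, dist,
        )
        # corr_nearest can return a boundary matrix; nudge for Cholesky
        repaired = repaired + 1e-10 * np.eye(k)
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        chol = np.linalg.cholesky(repaired)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((int(n), k))
    return means + sds * (z @ chol.T)


# ---------------------------------------------------------------------------
# latent near-compositional correlation construction
# ---------------------------------------------------------------------------

def build_latent_correlation_matrix(
    *,
    cpg_cell_corr=(0.611, 0.553, 0.371, 0.215, -0.402),
    cpg_gran_corr: float = -0.783,
    outcome_gran_corr: float = 0.16,
    outcome_cpg_corr: float = -0.0998,
    adjusted_cov: float = 0.032,
    factor_loading: float = 0.85,
    cell_sds=(0.035, 0.06, 0.018, 0.014, 0.010),
    gran_sd: float = 0.095,
    cpg_attenuation=(0.70, 0.49, 0.735, 1.0, 0.973, 0.98, 0.961, 0.98, 0.98),
    reference_cpg_index: int = 3,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Assemble the full target correlation matrix from a latent model.

    Latent structure (all latents independent standard normal):

    * the five non-granulocyte cells load on one shared factor F with
      loadings ``cpg_cell_corr / factor_loading``;
    * granulocytes are ``constant - sum(other cells) + remainder`` with the
      remainder variance fixed by ``gran_sd``;
    * the reference CpG loads on F, the granulocyte remainder, and an
      idiosyncratic term, reproducing its printed cell correlations exactly;
    * every other CpG is an attenuated copy of the reference CpG's latent
      signal plus its own noise;
    * the outcome loads on F, the granulocyte remainder, and the reference
      CpG's idiosyncratic term, hitting its marginal correlations with
      granulocytes and the reference CpG while keeping the *conditional*
      covariance given the six cells equal to ``adjusted_cov`` — the knob
      that makes the cell-adjusted coefficient flip sign.

    Returns ``(names, correlation_matrix, loadings)`` where names order is
    ``outcome, cpg1..cpg9, cd8t, cd4t, nk, bcell, mono, gran`` and
    ``loadings @ loadings.T == correlation_matrix``.
    """
    r5 = np.asarray(cpg_cell_corr, dtype=float)
    s = np.asarray(cell_sds, dtype=float)
    f = np.asarray(cpg_attenuation, dtype=float)
    b = float(factor_loading)
    S = float(gran_sd)
    n_cpg = len(f)
    if not (0 <= reference_cpg_index < n_cpg):
        raise ValueError("reference_cpg_index out of range")
    if np.any(np.abs(r5) >= b):
        raise ValueError("factor_loading must exceed every |cell correlation|")

    a = r5 / b                                   # cell loadings on F
    A = float(s @ a)
    s_eps2 = S**2 - A**2 - float(np.sum(s**2 * (1 - a**2)))
    if s_eps2 <= 0:
        raise ValueError(
            "granulocyte remainder variance is non-positive; increase gran_sd "
            "or decrease the non-granulocyte cell sds"
        )
    s_eps = np.sqrt(s_eps2)
    u = (cpg_gran_corr * S + b * A) / s_eps      # CpG loading on gran remainder
    v2 = 1.0 - b**2 - u**2
    if v2 <= 0:
        raise ValueError("CpG loadings exceed unit variance; adjust factor_loading")
    v = np.sqrt(v2)
    phi = 1.0 / (1.0 + float(np.sum(a**2 / (1 - a**2))))  # var(F | five cells)
    p = (outcome_cpg_corr - adjusted_cov - u * outcome_gran_corr * S / s_eps) / (
        b * (1 - phi) + u * A / s_eps
    )
    q = (outcome_gran_corr * S + p * A) / s_eps
    w = (adjusted_cov - p * b * phi) / v
    t2 = 1.0 - p**2 - q**2 - w**2
    if t2 <= 0:
        raise ValueError("outcome loadings exceed unit variance; reduce adjusted_cov")

    cpg_names = [f"cpg{j + 1}" for j in range(n_cpg)]
    names = ["outcome", *cpg_names, *CELL_TYPES]
    # latents: F, five cell idios, gran remainder, reference-CpG idio,
    # one idio per other CpG, outcome idio
    n_latent = 1 + 5 + 1 + 1 + (n_cpg - 1) + 1
    L = np.zeros((len(names), n_latent))

    i_cells = 1 + n_cpg
    for i in range(5):
        L[i_cells + i, 0] = a[i]
        L[i_cells + i, 1 + i] = np.sqrt(1 - a[i] ** 2)
    # granulocytes: -(1/S) * sum_i s_i * cell_i + (s_eps/S) * remainder
    for i in range(5):
        L[i_cells + 5] -= (s[i] / S) * L[i_cells + i]
    L[i_cells + 5, 6] = s_eps / S

    core = np.zeros(n_latent)
    core[0], core[6], core[7] = b, u, v
    extra = 8
    for j in range(n_cpg):
        if j == reference_cpg_index:
            L[1 + j] = core
        else:
            fj = f[j]
            if not 0 < fj <= 1:
                raise ValueError("cpg_attenuation entries must lie in (0, 1]")
            L[1 + j] = fj * core
            L[1 + j, extra] = np.sqrt(1 - fj**2)
            extra += 1
    L[0, 0], L[0, 6], L[0, 7] = p, q, w
    L[0, extra] = np.sqrt(t2)

    corr = L @ L.T
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2
    return names, corr, L


def default_raine_like_spec(n_participants: int = 812, seed: int = 0) -> CohortSpec:
    """Default cohort spec echoing the published study's structure.

    Printed quantities (the reference CpG's six cell correlations, the
    outcome-granulocyte correlation 0.16, the outcome-CpG correlation
    -0.0998 derived from the unadjusted fit, per-CpG complete-case counts)
    are targeted exactly.  Means and SDs of BMI, methylation and cell
    proportions are *documented placeholders* — realistic values for an
    adolescent whole-blood cohort, not published ones; every collinearity
    conclusion depends only on the correlations and the sample size.
    """
    names, corr, _ = build_latent_correlation_matrix()
    cpg_names = tuple(n for n in names if n.startswith("cpg"))
    # complete-case counts per CpG (out of 812) drive the missingness rates
    complete_cases = (780, 758, 723, 812, 790, 778, 740, 801, 760)
    missing = tuple(round(1.0 - c / 812.0, 6) for c in complete_cases)
    return CohortSpec(
        n_participants=n_participants,
        outcome_mean=float(np.log(22.0)),   # median BMI ~22 kg/m^2
        outcome_sd=0.15,
        cpg_names=cpg_names,
        cpg_means=(8.0,) * 9,               # percent methylation placeholders
        cpg_sds=(3.7,) * 9,
        cell_names=CELL_TYPES,
        cell_means=(0.10, 0.17, 0.07, 0.08, 0.08, 0.55),
        cell_sds=(0.035, 0.06, 0.018, 0.014, 0.010, 0.095),
        correlation_matrix=corr,
        missingness_rates=missing,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, *, repair: bool = False) -> pd.DataFrame:
    """Generate a participant table from ``spec``.

    Returns a DataFrame with columns ``participant_id, age, sex, bmi,
    <cpgs...>, <cells...>``.  BMI is the exponential of the Gaussian
    outcome draw (log-normal); methylation is clipped to [0, 100] percent
    and proportions to [0, 1]; per-CpG missingness is completely at random.
    Identical specs (including seed) give identical tables.
    """
    spec.validate()
    means = np.array([spec.outcome_mean, *spec.cpg_means, *spec.cell_means])
    sds = np.array([spec.outcome_sd, *spec.cpg_sds, *spec.cell_sds])
    draws = correlated_gaussian_sample(
        spec.n_participants, means, sds, spec.correlation_matrix,
        seed=spec.seed, repair=repair,
    )
    n_cpg = len(spec.cpg_names)
    out = draws[:, 0]
    meth = draws[:, 1:1 + n_cpg]
    cells = draws[:, 1 + n_cpg:]

    clipped = np.mean((cells < 0) | (cells > 1))
    if clipped > 0:
        logger.info("clipped %.4f%% of cell-proportion draws to [0, 1]", 100 * clipped)
    cells = np.clip(cells, 0.0, 1.0)
    meth = np.clip(meth, 0.0, 100.0)

    # auxiliary draws after the joint block, in a fixed order, so the table
    # is reproducible from the seed alone
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    age = rng.normal(spec.age_mean, spec.age_sd, spec.n_participants)
    sex = rng.binomial(1, spec.sex_prob, spec.n_participants)
    meth = meth.copy()
    for j, rate in enumerate(spec.missingness_rates):
        if rate > 0:
            mask = rng.random(spec.n_participants) < rate
            meth[mask, j] = np.nan

    table = pd.DataFrame({"participant_id": np.arange(1, spec.n_participants + 1)})
    table["age"] = age
    table["sex"] = sex
    table["bmi"] = np.exp(out)
    for j, name in enumerate(spec.cpg_names):
        table[name] = meth[:, j]
    for j, name in enumerate(spec.cell_names):
        table[name] = cells[:, j]
    return table


def validate_cohort(table: pd.DataFrame, cell_names=CELL_TYPES) -> None:
    """Raise if the table violates the cohort invariants."""
    cells = table[list(cell_names)].to_numpy()
    if np.any((cells < 0) | (cells > 1)):
        raise ValueError("cell proportions must lie in [0, 1]")
    mean_sum = float(cells.sum(axis=1).mean())
    if not 0.95 <= mean_sum <= 1.10:
        raise ValueError(
            f"mean six-proportion sum {mean_sum:.3f} outside [0.95, 1.10]"
        )
    meth_cols = [c for c in table.columns if c.startswith("cpg")]
    meth = table[meth_cols].to_numpy()
    finite = meth[np.isfinite(meth)]
    if np.any((finite < 0) | (finite > 100)):
        raise ValueError("methylation values must lie in [0, 100] percent")


# ---------------------------------------------------------------------------
# CSV I/O (missing methylation encoded as empty fields)
# ---------------------------------------------------------------------------

def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    if isinstance(path, str) and path.lstrip().startswith("participant_id"):
        path = io.StringIO(path)
    return pd.read_csv(path)
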