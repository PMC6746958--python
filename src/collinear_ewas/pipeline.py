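"""End-to-end orchestration: cohort, model battery, diagnostics, simulation.

``run_pipeline`` produces TSV analogues of the analysis tables — the
per-CpG model battery with reversal flags, CpG-cell correlations, VIFs
with and without granulocytes, CpG-PC correlations, and the sign-reversal
sweep — plus a JSON manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .synthetic_cohort import (
    CELL_TYPES,
    CohortSpec,
    default_raine_like_spec,
    generate_cohort,
    read_cohort_csv,
)
from .model_fitting import fit_methylation_model, detect_sign_reversal
from .diagnostics import compute_vif, correlation_matrix
from .remediation import pca_cells, pc_substitute_refit, residual_refit
from .simulation import SimulationSpec, default_simulation_spec, sweep_correlations, analytic_sign_probability

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("unadjusted", "six_cell", "five_cell_no_gran", "pc_2", "residual_all")


@dataclass(frozen=True)
class PipelineConfig:
    cohort_csv: str | None = None          # if None, simulate from cohort_spec
    cohort_spec: CohortSpec | None = None  # if None too, use the default spec
    cpgs: tuple[str, ...] = tuple(f"cpg{i}" for i in range(1, 10))
    reference_cpg: str = "cpg4"
    run_models: bool = True
    run_diagnostics: bool = True
    run_simulation: bool = True
    sim_r_values: tuple[float, ...] = (-0.783, -0.5, -0.25)
    sim_replicates: int = 1000
    out_dir: str = "results"
    seed: int = 0

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort_spec is not None:
            d["cohort_spec"] = json.loads(self.cohort_spec.to_json())
        return d


def _model_table(cohort: pd.DataFrame, cpgs, alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for cpg in cpgs:
        fits = {
            "unadjusted": fit_methylation_model(cohort, cpg, "none"),
            "six_cell": fit_methylation_model(cohort, cpg, "six_cell"),
            "five_cell_no_gran": fit_methylation_model(cohort, cpg, "five_cell_no_gran"),
            "pc_2": pc_substitute_refit(cohort, cpg, k=2),
            "residual_all": residual_refit(cohort, cpg, mode="all")[0],
        }
        cmp = detect_sign_reversal(fits["unadjusted"], fits["six_cell"], cpg, alpha)
        for family, fit in fits.items():
            term = cpg if family != "residual_all" else f"{cpg}_resid"
            t = fit.term(term)
            rows.append({
                "cpg": cpg, "model": family,
                "beta": t["beta"], "se": t["se"],
                "ci_low": t["ci_low"], "ci_high": t["ci_high"],
                "p": t["p"], "n": fit.n_used, "r_squared": fit.r_squared,
                "reversal_vs_unadjusted": (
                    cmp.reversal_flag if family == "six_cell" else ""
                ),
                "significance_change_vs_unadjusted": (
                    cmp.significance_change_flag if family == "six_cell" else ""
                ),
            })
    return pd.DataFrame(rows)


def _cpg_cell_corr_table(cohort: pd.DataFrame, cpgs) -> pd.DataFrame:
    cm = correlation_matrix(cohort[list(cpgs) + list(CELL_TYPES)], method="pearson")
    rows = []
    for cpg in cpgs:
        for cell in CELL_TYPES:
            rows.append({
                "cpg": cpg, "cell": cell,
                "r": cm.estimates.loc[cpg, cell],
                "p": cm.p_values.loc[cpg, cell],
                "n": cm.n_pairs.loc[cpg, cell],
            })
    return pd.DataFrame(rows)


def _vif_table(cohort: pd.DataFrame, cpg: str) -> pd.DataFrame:
    base = cohort[[cpg, "age", "sex"]]
    out = []
    for label, cells in (("six_cell", CELL_TYPES),
                         ("five_cell_no_gran", tuple(c for c in CELL_TYPES if c != "gran"))):
        design = pd.concat([base, cohort[list(cells)]], axis=1)
        rep = compute_vif(design, model_id=f"{cpg}:{label}")
        t = rep.table.copy()
        t.insert(0, "model", label)
        out.append(t)
    return pd.concat(out, ignore_index=True)


def _cpg_pc_corr_table(cohort: pd.DataFrame, cpgs) -> pd.DataFrame:
    pca = pca_cells(cohort)
    joined = cohort[list(cpgs)].join(pca.scores[["PC1", "PC2"]])
    cm = correlation_matrix(joined, method="pearson")
    rows = []
    for cpg in cpgs:
        for pc in ("PC1", "PC2"):
            rows.append({
                "cpg": cpg, "component": pc,
                "r": cm.estimates.loc[cpg, pc],
                "p": cm.p_values.loc[cpg, pc],
                "n": cm.n_pairs.loc[cpg, pc],
            })
    return pd.DataFrame(rows)


def _sim_table(config: PipelineConfig) -> pd.DataFrame:
    spec = dataclasses.replace(default_simulation_spec(),
                               replicates=config.sim_replicates, seed=config.seed)
    results = sweep_correlations(spec, config.sim_r_values)
    rows = []
    labels = [f"r_meth_gran={r}" for r in config.sim_r_values] + ["no_granulocyte"]
    for label, res in zip(labels, results):
        oracle_spec = dataclasses.replace(
            spec, r_meth_gran=res.r_meth_gran,
            include_granulocyte=res.include_granulocyte,
        )
        rows.append({
            "scenario": label,
            "r_meth_gran": res.r_meth_gran if res.include_granulocyte else "",
            "fraction_positive": res.fraction_positive,
            "mc_se": res.monte_carlo_se,
            "analytic_probability": analytic_sign_probability(oracle_spec),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the enabled stages and write TSV outputs plus a manifest.

    Returns a mapping from logical table name to written path.  Re-running
    with an identical config reproduces byte-identical outputs.
    """
    if not (config.run_models or config.run_diagnostics or config.run_simulation):
        raise ValueError("at least one pipeline stage must be enabled")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.cohort_csv is not None:
        if not Path(config.cohort_csv).exists():
            raise FileNotFoundError(config.cohort_csv)
        cohort = read_cohort_csv(config.cohort_csv)
        logger.info("loaded cohort from %s (%d rows)", config.cohort_csv, len(cohort))
    else:
        spec = config.cohort_spec or default_raine_like_spec(seed=config.seed)
        cohort = generate_cohort(spec)
        logger.info("simulated cohort (n=%d, seed=%d)", len(cohort), spec.seed)

    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written[name] = path
        logger.info("wrote %s", path)

    try:
        if config.run_models:
            emit("table1", _model_table(cohort, config.cpgs))
        if config.run_diagnostics:
            emit("table2", _cpg_cell_corr_table(cohort, config.cpgs))
            emit("table3", _vif_table(cohort, config.reference_cpg))
            emit("table4", _cpg_pc_corr_table(cohort, config.cpgs))
        if config.run_simulation:
            emit("sim", _sim_table(config))
    except Exception:
        logger.exception("pipeline stage failed")
        raise

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_jsonable(), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {k: str(v) for k, v in written.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = manifest_path
    return written
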