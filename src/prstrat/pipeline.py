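"""End-to-end orchestration: panel -> genotypes -> PRS -> association ->
stratification -> integrated-model evaluation, with reproducible outputs.

Everything that affects numbers lives in :class:`RunConfig` (or the simulation
config it points to); the CLI only selects mode and paths.  A run emits a
fixed bundle of delimited/JSON outputs plus a manifest recording the seed and
row counts at every filtering step.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import per_snp_association, spearman_screen
from .evaluate import integrated_model, roc_coordinates, strata_frame, stratified_or_table
from .panel import (
    RISK_FACTORS,
    GenotypeMatrix,
    complete_case_filter,
    load_panel,
    panel_to_frame,
    read_cohort,
    read_genotypes,
    weights_from_panel,
    write_cohort,
    write_genotypes,
)
from .prs import (
    compute_prs,
    control_quantile_bins,
    scores_frame,
    standardized_scores,
    summarize_prs,
)
from .synthetic import SimulationSpec, inject_missingness, simulate_cohort

#: Published decile-by-status counts of the MASTOS integrated-risk-model
#: stratification (900 controls / 880 cases after complete-case filtering).
#: Used by the ``published_counts`` fixture so the stratified OR table can be
#: reproduced exactly from printed data.
PUBLISHED_DECILE_CONTROLS = (139, 135, 108, 98, 94, 92, 89, 62, 45, 38)
PUBLISHED_DECILE_CASES = (39, 51, 64, 91, 74, 86, 102, 122, 114, 137)


@dataclass
class RunConfig:
    """Everything that affects a pipeline run's numbers."""

    out_dir: str = "prstrat_out"
    panel_path: str | None = None  # default: packaged 15-SNP fixture
    genotypes_path: str | None = None
    genotype_dialect: str = "csv"
    cohort_path: str | None = None
    simulation_config: str | None = None  # YAML SimulationSpec; simulate mode
    missing_policy: str = "expected_dosage"
    prs_bins: int = 4
    prs_ref_bin: int = 2
    risk_bins: int = 10
    risk_ref_bin: int = 5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.prs_ref_bin <= self.prs_bins:
            raise ValueError("PRS reference bin outside 1..n_bins")
        if not 1 <= self.risk_ref_bin <= self.risk_bins:
            raise ValueError("risk-model reference bin outside 1..n_bins")


def _log(message: str) -> None:
    print(f"[prstrat] {message}", file=sys.stderr)


def run_pipeline(config: RunConfig, simulate: bool = False):
    """Execute all stages and write the report bundle under ``config.out_dir``.

    In simulate mode the cohort comes from :func:`simulate_cohort` (spec from
    ``config.simulation_config`` or defaults, reseeded with ``config.seed``);
    in data mode from ``config.genotypes_path`` / ``config.cohort_path``.
    Returns the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "version": __version__, "stages": {}}

    panel = load_panel(config.panel_path)
    weights = weights_from_panel(panel)
    panel_to_frame(panel).to_csv(out / "panel_echo.tsv", sep="\t", index=False)

    if simulate:
        if config.simulation_config:
            spec = SimulationSpec.from_yaml(config.simulation_config)
            spec.seed = config.seed
            spec.__post_init__()
        else:
            spec = SimulationSpec(panel=panel, seed=config.seed)
        cohort, genotypes, truth = simulate_cohort(spec)
        if spec.missing_rates:
            cohort = inject_missingness(cohort, spec.missing_rates, spec.seed + 1)
        manifest["stages"]["simulate"] = {
            "n_cases": int((cohort["status"] == 1).sum()),
            "n_controls": int((cohort["status"] == 0).sum()),
        }
        _log(f"simulated cohort: {len(cohort)} rows "
             f"({manifest['stages']['simulate']['n_cases']} cases)")
    else:
        if not (config.genotypes_path and config.cohort_path):
            raise ValueError("data mode requires genotype and cohort paths")
        genotypes = read_genotypes(config.genotypes_path, config.genotype_dialect, panel)
        cohort = read_cohort(config.cohort_path)
        geno_order = {ind: i for i, ind in enumerate(genotypes.individual_ids)}
        missing_ids = [i for i in cohort["individual_id"] if i not in geno_order]
        if missing_ids:
            raise ValueError(f"cohort ids without genotypes: {missing_ids[:5]}")
        idx = [geno_order[i] for i in cohort["individual_id"]]
        genotypes = GenotypeMatrix(
            list(cohort["individual_id"]), genotypes.snp_ids, genotypes.dosages[idx]
        )
        _log(f"loaded cohort: {len(cohort)} rows")
    manifest["stages"]["input"] = {"n_rows": int(len(cohort))}

    # phenotype complete-case filter (genotype missingness handled by the
    # PRS missing-dosage policy, not by row removal)
    cohort_cc, genotypes_cc, report = complete_case_filter(
        cohort, genotypes, required_fields=RISK_FACTORS
    )
    manifest["stages"]["complete_case"] = report
    _log(f"complete-case filter: {report['n_input']} -> {report['n_kept']} rows")

    y = cohort_cc["status"].to_numpy()
    results = compute_prs(
        genotypes_cc, weights, config.missing_policy, status=y,
        published_mafs=[r.published_eaf for r in panel],
    )
    scores = np.array([r.score for r in results])
    frame = scores_frame(results)
    frame["score_control_sd_units"] = standardized_scores(scores, y)
    prs_bins = control_quantile_bins(scores, y, config.prs_bins)
    frame["prs_bin"] = prs_bins
    frame.to_csv(out / "prs_scores.csv", index=False)
    summarize_prs(results, y).to_csv(out / "prs_summary.csv", index=False)

    per_snp_association(genotypes_cc, y).to_csv(
        out / "per_snp_association.tsv", sep="\t", index=False
    )

    quartile_table = stratified_or_table(prs_bins, y, config.prs_ref_bin)
    strata_frame(quartile_table).to_csv(out / "prs_quantile_table.tsv", sep="\t", index=False)

    screen_cols = cohort_cc[RISK_FACTORS].copy()
    screen_cols["prs"] = scores
    spearman_screen(screen_cols, restrict_to=(y == 0)).to_csv(
        out / "spearman_screen.tsv", sep="\t", index=False
    )

    result = integrated_model(
        cohort_cc, scores, n_bins=config.risk_bins, ref_bin=config.risk_ref_bin,
        threshold=config.threshold,
    )
    strata_frame(result.decile_table).to_csv(out / "decile_table.tsv", sep="\t", index=False)
    roc_coordinates(result.p_hat, y).to_csv(out / "roc.csv", index=False)

    metrics = {
        "auc": result.discrimination.auc,
        "auc_se": result.discrimination.se,
        "auc_ci": [result.discrimination.ci_low, result.discrimination.ci_high],
        "hl_chi2": result.calibration.chi2,
        "hl_df": result.calibration.df,
        "hl_p": result.calibration.p,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "model_terms": result.fit.term_names,
        "coefficients": [float(b) for b in result.fit.coefficients],
        "standard_errors": [float(s) for s in result.fit.standard_errors],
        "converged": bool(result.fit.converged),
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    manifest["stages"]["integrated_model"] = {"n_rows": int(len(cohort_cc))}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _log(f"report bundle written to {out}")
    return manifest


def make_fixture(kind: str, out_dir) -> dict:
    """Write a small on-disk fixture dataset.

    ``tiny``: a 30-individual simulated toy cohort with genotypes and
    covariates in the standard dialects.  ``published_counts``: 1780 rows
    carrying only (decile, status), matching the published decile-by-status
    counts of the integrated risk model exactly, so the stratified OR table
    is reproducible from printed data alone.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "tiny":
        spec = SimulationSpec(n_cases=15, n_controls=15, seed=0)
        cohort, genotypes, _ = simulate_cohort(spec)
        write_cohort(cohort, out / "tiny_cohort.csv")
        write_genotypes(genotypes, out / "tiny_genotypes.csv")
        return {"cohort": str(out / "tiny_cohort.csv"),
                "genotypes": str(out / "tiny_genotypes.csv")}
    if kind == "published_counts":
        rows = []
        for d, (nc, ncase) in enumerate(
            zip(PUBLISHED_DECILE_CONTROLS, PUBLISHED_DECILE_CASES), start=1
        ):
            rows.extend({"decile": d, "status": 0} for _ in range(nc))
            rows.extend({"decile": d, "status": 1} for _ in range(ncase))
        df = pd.DataFrame(rows)
        path = out / "published_decile_counts.csv"
        df.to_csv(path, index=False)
        return {"decile_status": str(path)}
    raise ValueError(f"unknown fixture kind {kind!r}")
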