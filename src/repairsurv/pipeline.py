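"""End-to-end orchestration: adjust -> screen -> best PC -> randomization.

One call runs the whole survival analysis for one cancer cohort, with the
adjustment set chosen per the cohort's clinical dialect ({age, metagene}
when stage is unavailable, {age, stage, metagene} when present) unless
overridden in the run configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjust import (AdjustedExpression, adjust_expression, compute_metagene,
                     correlate_with_metagene, encode_stage, vdw_transform)
from .bestpc import (BestPCResult, assign_gene_directions, fit_pc_model,
                     pathway_composition, select_best_binarized_pc)
from .catalog import (ExclusionRules, MetageneGeneSet, PathwayCatalog,
                      load_packaged_catalog, survival_gene_pool)
from .errors import DegenerateInputError
from .io import RunConfig
from .randtest import EmpiricalTestResult, empirical_pvalue
from .screen import ScreenResult, screen_genes

logger = logging.getLogger(__name__)


def build_covariates(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    signature: MetageneGeneSet,
    adjust_set: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """VDW covariate vectors for the requested adjustment set."""
    cov: dict[str, np.ndarray] = {}
    if "age" in adjust_set:
        cov["age"] = vdw_transform(clinical["age_years"].to_numpy(float))
    if "stage" in adjust_set:
        ranks = encode_stage(clinical["stage"].tolist())
        cov["stage"] = vdw_transform(ranks)
    if "metagene" in adjust_set:
        metagene = compute_metagene(expression, signature)
        cov["metagene"] = vdw_transform(metagene.to_numpy(float))
    return cov


@dataclass
class CancerAnalysis:
    """All survival-analysis outputs for one cohort."""

    adjusted: AdjustedExpression
    screen: ScreenResult
    best_pc: BestPCResult | None
    empirical: EmpiricalTestResult | None
    metagene_correlation: pd.Series | None = None
    directions: pd.DataFrame | None = None
    composition: pd.DataFrame | None = None


def analyze_cohort(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    signature: MetageneGeneSet,
    config: RunConfig,
    catalog: PathwayCatalog | None = None,
    rules: ExclusionRules | None = None,
    adjust_set: tuple[str, ...] | None = None,
    cancer_code: str | None = None,
    run_randomization: bool = True,
) -> CancerAnalysis:
    """Run the full analysis for one aligned cohort.

    ``expression`` columns and ``clinical`` rows must already be aligned
    (same samples, same order).  When ``adjust_set`` is None it is taken
    from ``config.adjust``, dropping "stage" if the clinical table has no
    usable stage labels.
    """
    catalog = catalog or load_packaged_catalog()
    pool = survival_gene_pool(catalog, rules, cancer_code=cancer_code)

    if adjust_set is None:
        adjust_set = config.adjust
        has_stage = ("stage" in clinical.columns
                     and clinical["stage"].astype(str).str.len().gt(0).all())
        if "stage" in adjust_set and not has_stage:
            logger.info("stage unavailable; adjusting for %s",
                        tuple(a for a in adjust_set if a != "stage"))
            adjust_set = tuple(a for a in adjust_set if a != "stage")

    cov = build_covariates(expression, clinical, signature, adjust_set)
    adjusted = adjust_expression(expression, pool, cov)

    metagene_corr = None
    if "metagene" in adjust_set:
        metagene = compute_metagene(expression, signature)
        metagene_corr = correlate_with_metagene(adjusted, metagene)

    time = clinical["os_months"].to_numpy(float)
    event = clinical["os_event"].to_numpy(int)
    screen = screen_genes(adjusted, time, event, alpha=config.alpha)

    best = empirical = directions = composition = None
    if screen.significant:
        model = fit_pc_model(adjusted.residuals.loc[screen.significant],
                             corr_mode=config.corr_mode)
        best = select_best_binarized_pc(model, time, event)
        try:
            dir_table = assign_gene_directions(best, threshold=config.loading_threshold)
            directions = dir_table.table
            composition = pathway_composition(dir_table, catalog)
        except DegenerateInputError:
            logger.warning("HR = 1; gene directions undefined")
        if run_randomization:
            usable_pool = [g for g in pool if g in adjusted.residuals.index]
            empirical = empirical_pvalue(
                best, usable_pool, len(screen.significant), adjusted,
                time, event, B=config.B, seed=config.seed,
                cancer_code=cancer_code, corr_mode=config.corr_mode,
            )
    else:
        logger.info("no significant genes at alpha=%g; PC stage skipped", config.alpha)

    return CancerAnalysis(
        adjusted=adjusted, screen=screen, best_pc=best, empirical=empirical,
        metagene_correlation=metagene_corr, directions=directions,
        composition=composition,
    )
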