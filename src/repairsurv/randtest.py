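"""Randomization (empirical p-value) test for the best binarized PC.

The observed statistic is the best-binarized-PC KM chi-squared built from
the p screened genes.  Its null distribution comes from B random draws of p
genes from the repair-gene pool — same already-adjusted expression, same
correlation -> eigendecomposition -> varimax -> binarize -> KM pipeline, but
with NO univariate screening inside the iteration.  The empirical p-value is
the strict-exceedance fraction

    P = #{b : chi2(b) > chi2_observed} / B,

which can be exactly 0; the add-one corrected (#exceed + 1)/(B + 1) is
reported alongside for downstream use.  Per-cancer RNG streams are derived
from the master seed and a CRC32 hash of the cancer code, so per-cancer
results do not depend on the order cancers are processed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjust import AdjustedExpression
from .bestpc import BestPCResult, fit_pc_model, select_best_binarized_pc
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


def rng_for_cancer(seed: int, cancer_code: str | None = None) -> np.random.Generator:
    """Documented key derivation: master seed + CRC32(cancer code)."""
    if cancer_code is None:
        return np.random.default_rng(seed)
    key = zlib.crc32(cancer_code.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def random_gene_statistic(
    pool: list[str],
    p: int,
    adjusted: AdjustedExpression | pd.DataFrame,
    time,
    event,
    rng: np.random.Generator,
    corr_mode: str = "continuous",
) -> float:
    """Best-binarized-PC chi-squared for one random p-gene set.

    Genes are sampled uniformly without replacement from the pool; the full
    observed pipeline (including varimax) is re-applied.  A degenerate
    sampled set is resampled once, then raises.
    """
    R = adjusted.residuals if isinstance(adjusted, AdjustedExpression) else adjusted
    if p > len(pool):
        raise ValueError(f"p={p} exceeds pool size {len(pool)}")
    for attempt in range(2):
        genes = [pool[i] for i in rng.choice(len(pool), size=p, replace=False)]
        try:
            model = fit_pc_model(R.loc[genes], corr_mode=corr_mode)
            best = select_best_binarized_pc(model, time, event, fit_cox=False)
            return best.chi2
        except DegenerateInputError:
            if attempt == 1:
                raise
            logger.info("degenerate random gene set; resampling once")
    raise AssertionError("unreachable")


@dataclass
class EmpiricalTestResult:
    """Observed best-PC chi-squared against its random-gene-set null."""

    observed_chi2: float
    B: int
    null_chi2: np.ndarray
    empirical_p: float
    add_one_p: float
    seed: int
    p_genes: int = 0
    cancer_code: str | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "cancer_code": self.cancer_code,
            "p_genes": self.p_genes,
            "observed_chi2": self.observed_chi2,
            "B": self.B,
            "empirical_p": self.empirical_p,
            "add_one_p": self.add_one_p,
            "seed": self.seed,
        }])


def empirical_pvalue(
    observed: BestPCResult | float,
    pool: list[str],
    p: int,
    adjusted: AdjustedExpression | pd.DataFrame,
    time,
    event,
    B: int = 1000,
    seed: int = 0,
    cancer_code: str | None = None,
    corr_mode: str = "continuous",
) -> EmpiricalTestResult:
    """Empirical p-value of the observed best binarized PC.

    P = #{b: chi2(b) > observed}/B with strict inequality; the observed gene
    set stays in the sampling pool.  Deterministic given (data, seed, B).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if p > len(pool):
        raise ValueError(f"p={p} exceeds pool size {len(pool)}")
    obs = observed.chi2 if isinstance(observed, BestPCResult) else float(observed)
    rng = rng_for_cancer(seed, cancer_code)
    null = np.empty(B)
    for b in range(B):
        null[b] = random_gene_statistic(pool, p, adjusted, time, event, rng,
                                        corr_mode=corr_mode)
    exceed = int((null > obs).sum())
    return EmpiricalTestResult(
        observed_chi2=obs,
        B=B,
        null_chi2=null,
        empirical_p=exceed / B,
        add_one_p=(exceed + 1) / (B + 1),
        seed=seed,
        p_genes=p,
        cancer_code=cancer_code,
    )
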