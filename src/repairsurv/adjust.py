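"""Rank-normal (van der Waerden) scoring, the proliferation metagene, and
covariate residualization.

The van der Waerden (VDW) transform maps a vector to standard-normal
quantiles of its percentiles, ``Z_i = Phi^-1(rank_i / (n+1))`` with midranks
for ties.  Because only ranks enter, any monotone rescaling of the raw data
(log, normalization constants) leaves the scores unchanged.

The proliferation metagene is the per-sample median of raw expression over
a proliferation signature; it is computed on the raw scale first and then
VDW-transformed when used as a regression covariate.  Per-gene adjusted
expression is the OLS residual of the gene's VDW scores on the VDW scores of
the chosen covariates (age, tumor stage, metagene).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.special import ndtri

from .catalog import MetageneGeneSet
from .errors import CollinearityError, DegenerateInputError, FormatError

logger = logging.getLogger(__name__)


def vdw_transform(values: np.ndarray) -> np.ndarray:
    """Van der Waerden scores: Phi^-1(rank/(n+1)), midranks for ties.

    The rank/(n+1) percentile scheme keeps scores finite at the extremes and
    gives exactly mean-zero scores on tie-free input.  A constant vector has
    no ranks and raises.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("vdw_transform expects a 1-d vector")
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values")
    if not np.isfinite(x).all():
        raise DegenerateInputError("non-finite values in input")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant vector has no ranks")
    ptile = rankdata(x, method="average") / (x.size + 1)
    return ndtri(ptile)


def vdw_transform_matrix(values: np.ndarray) -> np.ndarray:
    """Row-wise VDW transform of a genes x samples matrix."""
    x = np.asarray(values, dtype=float)
    n = x.shape[1]
    ranks = np.apply_along_axis(rankdata, 1, x)
    return ndtri(ranks / (n + 1))


def compute_metagene(expression: pd.DataFrame, signature: MetageneGeneSet) -> pd.Series:
    """Per-sample median expression over the signature genes present.

    Signature genes absent from the matrix are counted and logged; if none
    are present this is an error.
    """
    present = [g for g in signature.genes if g in expression.index]
    if not present:
        raise DegenerateInputError("no metagene signature genes present in expression matrix")
    absent = len(signature.genes) - len(present)
    if absent:
        logger.info("%d of %d metagene genes absent from matrix", absent, len(signature.genes))
    return expression.loc[present].median(axis=0)


_STAGE_RE = re.compile(r"^(?:STAGE\s*)?(IV|III|II|I)\s*([ABC]?)$")
_STAGE_BASE = {"I": 1, "II": 2, "III": 3, "IV": 4}
_SUB = {"": 0, "A": 1, "B": 2, "C": 3}


def stage_code(label: str) -> float:
    """Numeric code for one stage label; I<II<III<IV, A<B<C within stage."""
    m = _STAGE_RE.match(str(label).strip().upper().replace(".", ""))
    if not m:
        raise FormatError(f"unrecognized stage label: {label!r}")
    return _STAGE_BASE[m.group(1)] * 10 + _SUB[m.group(2)]


def encode_stage(labels) -> np.ndarray:
    """Midrank-encode stage labels as an ordinal vector.

    Accepts "Stage IIIA" / "IIIA" / "iii a" dialects.  Unrecognized labels
    raise with the offending values listed.
    """
    labels = list(labels)
    bad = []
    codes = []
    for lab in labels:
        try:
            codes.append(stage_code(lab))
        except FormatError:
            bad.append(lab)
    if bad:
        raise FormatError(f"unrecognized stage labels: {sorted(set(map(str, bad)))}")
    return rankdata(codes, method="average")


def residualize(y: np.ndarray, covariates: list[np.ndarray] | np.ndarray | None) -> np.ndarray:
    """OLS residuals of y on an intercept plus the given covariates.

    With no covariates this is mean-centering.  A collinear covariate pair
    is an error naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if covariates is None or (isinstance(covariates, list) and not covariates):
        return y - y.mean()
    C = np.column_stack(covariates) if isinstance(covariates, list) else np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate length mismatch")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        k = C.shape[1]
        for i in range(k):
            for j in range(i + 1, k):
                r = np.corrcoef(C[:, i], C[:, j])[0, 1]
                if abs(r) > 1 - 1e-12:
                    raise CollinearityError(f"covariates {i} and {j} are collinear (|r|={abs(r):.6f})")
        raise CollinearityError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class AdjustedExpression:
    """Per-gene VDW residuals after covariate regression.

    ``residuals`` is genes x samples; ``coefficients`` holds the per-gene OLS
    coefficients on the intercept and each covariate (for reporting).
    """

    residuals: pd.DataFrame
    covariates: tuple[str, ...]
    coefficients: pd.DataFrame = None
    dropped_genes: list[str] = field(default_factory=list)


def adjust_expression(
    expression: pd.DataFrame,
    genes: list[str],
    covariate_vectors: dict[str, np.ndarray],
    max_missing_frac: float = 0.2,
) -> AdjustedExpression:
    """Full adjustment chain for a gene panel.

    Each panel gene present in ``expression`` is VDW-transformed and
    regressed (with intercept) on the supplied VDW covariate vectors; the
    residuals become the adjusted expression.  Genes missing from the
    matrix, with >``max_missing_frac`` missing cells, or constant are
    dropped with a log message; remaining missing cells are median-imputed
    before ranking.
    """
    present = [g for g in genes if g in expression.index]
    absent = sorted(set(genes) - set(present))
    if absent:
        logger.info("%d panel genes absent from expression matrix", len(absent))
    sub = expression.loc[present].astype(float)
    n = sub.shape[1]

    dropped: list[str] = list(absent)
    keep_rows = []
    for g in present:
        row = sub.loc[g].to_numpy()
        n_miss = int(np.isnan(row).sum())
        if n_miss > max_missing_frac * n:
            dropped.append(g)
            logger.info("gene %s dropped: %d/%d cells missing", g, n_miss, n)
            continue
        if n_miss:
            row = np.where(np.isnan(row), np.nanmedian(row), row)
        if np.ptp(row) == 0:
            dropped.append(g)
            logger.info("gene %s dropped: constant expression", g)
            continue
        keep_rows.append((g, row))
    if not keep_rows:
        raise DegenerateInputError("no usable genes after filtering")

    kept = [g for g, _ in keep_rows]
    raw = np.vstack([r for _, r in keep_rows])
    Z = vdw_transform_matrix(raw)

    names = list(covariate_vectors)
    if names:
        C = np.column_stack([np.asarray(covariate_vectors[k], float) for k in names])
        X = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise CollinearityError("covariate design matrix is rank deficient")
    else:
        X = np.ones((n, 1))
    # one shared design: solve all genes at once
    beta, *_ = np.linalg.lstsq(X, Z.T, rcond=None)
    resid = Z - (X @ beta).T
    coef = pd.DataFrame(beta.T, index=kept, columns=["intercept", *names])
    return AdjustedExpression(
        residuals=pd.DataFrame(resid, index=kept, columns=expression.columns),
        covariates=tuple(names),
        coefficients=coef,
        dropped_genes=dropped,
    )


def correlate_with_metagene(adjusted: AdjustedExpression, metagene: pd.Series) -> pd.Series:
    """Pearson r between each gene's adjusted expression and the metagene.

    Zero-variance residual vectors get a missing value rather than an error.
    """
    m = metagene.loc[adjusted.residuals.columns].to_numpy(dtype=float)
    m = m - m.mean()
    denom_m = np.sqrt((m ** 2).sum())
    R = adjusted.residuals.to_numpy()
    Rc = R - R.mean(axis=1, keepdims=True)
    denom_g = np.sqrt((Rc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Rc @ m) / (denom_g * denom_m)
    r[denom_g == 0] = np.nan
    return pd.Series(r, index=adjusted.residuals.index, name="pearson_r")
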