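"""Best binarized principal component of the significant-gene set.

The p genes surviving the univariate KM screen are summarized by
eigendecomposition of their p x p Pearson correlation matrix followed by
Varimax orthogonal rotation.  Each rotated component score vector is
binarized (negative -> 0, positive -> 1) and tested with the KM logrank
statistic; the component with the greatest chi-squared is the "best
binarized PC".  A univariate Cox proportional-hazards fit on the continuous
best-PC score gives the survival directionality: with hazard ratio HR < 1
a positive score prolongs survival, so genes loading positively prolong
overall survival when upregulated; with HR > 1 the assignment flips.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .catalog import PathwayCatalog
from .errors import DegenerateInputError
from .screen import logrank_chi2_many, median_binarize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Correlation and eigenstructure
# ---------------------------------------------------------------------------

def correlation_matrix(vectors: pd.DataFrame, mode: str = "continuous") -> np.ndarray:
    """Pearson correlation matrix of p aligned gene vectors (rows).

    ``mode="binarized"`` correlates the median-binarized versions instead of
    the continuous residuals.  A constant vector is an error naming the gene.
    """
    X = vectors.to_numpy(dtype=float)
    for g, row in zip(vectors.index, X):
        if np.ptp(row) == 0:
            raise DegenerateInputError(f"gene {g!r} has constant values")
    if mode == "binarized":
        X = np.vstack([median_binarize(row) for row in X]).astype(float)
        for g, row in zip(vectors.index, X):
            if np.ptp(row) == 0:
                raise DegenerateInputError(f"gene {g!r} is constant after binarization")
    elif mode != "continuous":
        raise ValueError("mode must be 'continuous' or 'binarized'")
    if X.shape[0] == 1:
        return np.array([[1.0]])
    return np.corrcoef(X)


def eigendecompose(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and unit eigenvectors of a correlation matrix.

    Sign convention: the largest-magnitude element of each eigenvector is
    made positive, so the decomposition is reproducible across BLAS builds.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    flip = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    return vals, vecs * flip


# ---------------------------------------------------------------------------
# Varimax rotation
# ---------------------------------------------------------------------------

def varimax_criterion(L: np.ndarray) -> float:
    """Varimax objective: sum over columns of the variance of squared loadings."""
    sq = L ** 2
    return float((sq ** 2).sum(axis=0).sum() / L.shape[0]
                 - ((sq.sum(axis=0) / L.shape[0]) ** 2).sum())


def varimax_rotate(
    loadings: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    kaiser: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Varimax orthogonal rotation of a loading matrix.

    Iterates the singular-value update of the rotation matrix until the
    criterion gain falls below ``tol`` or ``max_iter`` sweeps, with Kaiser
    row normalization.  The reported criterion trace is non-decreasing: an
    update that would lower the criterion stops the iteration and the best
    iterate is returned.  Returns (rotated loadings, rotation matrix, trace).
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k == 1:
        return L.copy(), np.eye(1), [varimax_criterion(L)]

    if kaiser:
        h = np.sqrt((L ** 2).sum(axis=1))
        h_safe = np.where(h > 0, h, 1.0)
        Ln = L / h_safe[:, None]
    else:
        h_safe = None
        Ln = L

    R = np.eye(k)
    trace = [varimax_criterion(Ln)]
    best_R, best_c = R, trace[0]
    converged = False
    for _ in range(max_iter):
        LR = Ln @ R
        u, s, vt = np.linalg.svd(
            Ln.T @ (LR ** 3 - LR @ np.diag((LR ** 2).sum(axis=0)) / p)
        )
        R_new = u @ vt
        c_new = varimax_criterion(Ln @ R_new)
        if c_new < best_c - 1e-12:
            break
        trace.append(max(c_new, best_c))
        if c_new > best_c:
            best_R, best_c = R_new, c_new
        if trace[-1] - trace[-2] < tol * max(best_c, 1e-12):
            R = R_new
            converged = True
            break
        R = R_new
    if not converged:
        warnings.warn("varimax rotation did not converge; returning best iterate",
                      RuntimeWarning, stacklevel=2)
    R = best_R
    rotated = (Ln @ R) * (h_safe[:, None] if kaiser else 1.0)
    # sign convention as in eigendecompose
    flip = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    return rotated * flip, R * flip, trace


# ---------------------------------------------------------------------------
# PC model
# ---------------------------------------------------------------------------

@dataclass
class PCModel:
    """Rotated principal-component model of a gene panel."""

    genes: list[str]
    corr: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray        # rotated, p x p
    scores: np.ndarray          # samples x p
    rotation_trace: list[float] = field(default_factory=list)


def pc_scores(standardized: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Component scores: standardized data (samples x p) times loadings."""
    Z = np.asarray(standardized, dtype=float)
    L = np.asarray(loadings, dtype=float)
    if Z.shape[1] != L.shape[0]:
        raise ValueError(f"dimension mismatch: data has {Z.shape[1]} variables, "
                         f"loadings {L.shape[0]}")
    return Z @ L


def fit_pc_model(residuals: pd.DataFrame, corr_mode: str = "continuous") -> PCModel:
    """Correlation -> eigendecomposition -> varimax -> scores, end to end.

    ``residuals`` is genes x samples adjusted expression.  Scores are
    computed from the column-standardized continuous residuals regardless of
    the correlation-input mode.
    """
    corr = correlation_matrix(residuals, mode=corr_mode)
    vals, vecs = eigendecompose(corr)
    raw_loadings = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rotated, _, trace = varimax_rotate(raw_loadings)
    X = residuals.to_numpy(dtype=float).T        # samples x p
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    return PCModel(
        genes=list(residuals.index),
        corr=corr,
        eigenvalues=vals,
        loadings=rotated,
        scores=pc_scores(Z, rotated),
        rotation_trace=trace,
    )


# ---------------------------------------------------------------------------
# Best binarized PC selection and directionality
# ---------------------------------------------------------------------------

@dataclass
class BestPCResult:
    """The rotated component whose binarized score best separates survival."""

    pc_index: int               # 0-based column into the model
    chi2: float
    pvalue: float
    groups: np.ndarray          # binarized best-PC score, per sample
    loadings: pd.Series         # best-PC loadings per gene
    score: np.ndarray           # continuous best-PC score
    hazard_ratio: float = np.nan
    hr_ci: tuple[float, float] = (np.nan, np.nan)
    all_chi2: np.ndarray = None


def binarize_pc_scores(scores: np.ndarray) -> np.ndarray:
    """Negative or zero score -> 0, positive -> 1, per column."""
    return (np.asarray(scores) > 0).astype(np.int8)


def select_best_binarized_pc(
    model: PCModel, time, event, fit_cox: bool = True
) -> BestPCResult:
    """KM-test every binarized component and keep the argmax chi-squared.

    Ties break to the lowest component index; components whose binarized
    groups are degenerate (all one label) are skipped.  When ``fit_cox`` the
    continuous best-PC score is fed to a univariate Cox PH fit for
    directionality.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    G = binarize_pc_scores(model.scores)
    n1 = G.sum(axis=0)
    ok = (n1 > 0) & (n1 < G.shape[0])
    chi2 = np.full(G.shape[1], np.nan)
    if ok.any():
        chi2[ok] = logrank_chi2_many(time, event, G[:, ok].astype(float))
    if np.all(np.isnan(chi2)):
        raise DegenerateInputError("all binarized components are degenerate")
    best = int(np.nanargmax(chi2))   # nanargmax takes the first maximum -> lowest index
    result = BestPCResult(
        pc_index=best,
        chi2=float(chi2[best]),
        pvalue=float(chi2_dist.sf(chi2[best], df=1)),
        groups=G[:, best],
        loadings=pd.Series(model.loadings[:, best], index=model.genes, name="loading"),
        score=model.scores[:, best],
        all_chi2=chi2,
    )
    if fit_cox:
        hr, ci = cox_direction(time, event, result.score)
        result.hazard_ratio, result.hr_ci = hr, ci
    return result


def cox_direction(time, event, score) -> tuple[float, tuple[float, float]]:
    """Univariate Cox PH hazard ratio per unit of a continuous score.

    Efron tie handling; returns (HR, 95% Wald CI).  HR < 1 means larger
    scores prolong survival.
    """
    from lifelines import CoxPHFitter

    score = np.asarray(score, dtype=float)
    if np.ptp(score) == 0:
        raise DegenerateInputError("constant score cannot enter a Cox model")
    df = pd.DataFrame({
        "T": np.asarray(time, dtype=float),
        "E": np.asarray(event, dtype=int),
        "score": score,
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    hr = float(np.exp(cph.params_["score"]))
    lo, hi = cph.confidence_intervals_.loc["score"]
    return hr, (float(np.exp(lo)), float(np.exp(hi)))


UP_PROLONGS = "upregulation-prolongs-OS"
DOWN_PROLONGS = "downregulation-prolongs-OS"


@dataclass
class GeneDirectionTable:
    """Per-gene survival directionality on the best binarized PC."""

    table: pd.DataFrame          # gene, loading, direction
    hazard_ratio: float
    loading_threshold: float


def assign_gene_directions(
    best: BestPCResult, threshold: float = 0.4
) -> GeneDirectionTable:
    """Label each loaded gene's beneficial expression direction.

    A gene is beneficial when upregulated iff sign(loading) * sign(log HR)
    < 0: positive loading with HR < 1, or negative loading with HR > 1.
    Genes with |loading| below the threshold are omitted.  Flipping the
    component's sign flips both the loadings and log HR, leaving every
    direction unchanged.
    """
    hr = best.hazard_ratio
    if not np.isfinite(hr) or hr <= 0:
        raise ValueError("best-PC result lacks a valid Cox hazard ratio")
    if hr == 1.0:
        raise DegenerateInputError("HR = 1 exactly; direction undefined")
    rows = []
    for gene, loading in best.loadings.items():
        if abs(loading) < threshold or loading == 0:
            continue
        beneficial_up = np.sign(loading) * np.sign(np.log(hr)) < 0
        rows.append((gene, float(loading),
                     UP_PROLONGS if beneficial_up else DOWN_PROLONGS))
    table = pd.DataFrame(rows, columns=["gene", "loading", "direction"])
    return GeneDirectionTable(table=table, hazard_ratio=hr, loading_threshold=threshold)


def pathway_composition(
    directions: GeneDirectionTable | pd.DataFrame, catalog: PathwayCatalog
) -> pd.DataFrame:
    """Percentage pathway composition of each direction's gene list.

    Percentages are per direction and rounded to one decimal; a gene absent
    from the catalog is an error.
    """
    table = directions.table if isinstance(directions, GeneDirectionTable) else directions
    rows = []
    for direction, sub in table.groupby("direction", sort=False):
        counts: dict[str, int] = {}
        for gene in sub["gene"]:
            counts[catalog.pathway_of(gene)] = counts.get(catalog.pathway_of(gene), 0) + 1
        total = len(sub)
        for pathway, c in counts.items():
            rows.append((direction, pathway, round(100.0 * c / total, 1)))
    return pd.DataFrame(rows, columns=["direction", "pathway", "percent"])
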