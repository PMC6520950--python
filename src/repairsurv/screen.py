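"""Median binarization and Kaplan-Meier logrank screening.

Each adjusted gene is split at its median into two groups and tested with
the two-sample logrank statistic: the sum over distinct event times of
observed-minus-expected events in group 1, squared and divided by the
hypergeometric variance, referred to a 1-d.f. chi-squared distribution.
Tied events all count at their common time.  The significance boundary at
alpha = 0.05 is chi2 > 3.84.

The statistic is computed by a vectorized routine that evaluates many
grouping vectors against one (time, event) outcome in a single pass — the
randomization test downstream needs tens of thousands of tests per cancer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .adjust import AdjustedExpression
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


def km_significance_threshold(alpha: float = 0.05) -> float:
    """1-d.f. chi-squared critical value; 3.84 at alpha = 0.05."""
    return float(chi2_dist.ppf(1 - alpha, df=1))


def median_binarize(values: np.ndarray) -> np.ndarray:
    """Split at the median: value > median -> 1, else 0.

    Values tied with the median fall in group 0.  A constant vector cannot
    be split and raises.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant vector cannot be median-binarized")
    return (x > np.median(x)).astype(np.int8)


def logrank_chi2_many(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Two-sample logrank chi-squared for K grouping columns at once.

    ``groups`` is (n,) or (n, K) of 0/1 labels sharing one (time, event)
    outcome.  Returns (K,) chi-squared values; a column whose groups never
    differ on any risk set (zero variance) yields NaN.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    G = np.asarray(groups, dtype=float)
    squeeze = G.ndim == 1
    if squeeze:
        G = G[:, None]
    n = time.size

    order = np.argsort(time, kind="stable")
    t, e, Gs = time[order], event[order], G[order]

    # first index of each distinct time block
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    at_risk = n - starts                                   # total at risk per block
    # at-risk count in group 1 = suffix sums of Gs at block starts
    suffix = np.cumsum(Gs[::-1], axis=0)[::-1]
    n1 = suffix[starts]                                    # (n_blocks, K)
    d = np.add.reduceat(e, starts)                         # events per block
    d1 = np.add.reduceat(e[:, None] * Gs, starts, axis=0)  # group-1 events per block

    ev = d > 0
    d, at_risk = d[ev], at_risk[ev]
    n1, d1 = n1[ev], d1[ev]

    frac = n1 / at_risk[:, None]
    O_minus_E = (d1 - d[:, None] * frac).sum(axis=0)
    denom = np.maximum(at_risk - 1, 1)
    V = (d * (at_risk - d) / denom)[:, None] * frac * (1 - frac)
    Vsum = V.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(Vsum > 0, O_minus_E ** 2 / Vsum, np.nan)
    return chi2[0] if squeeze else chi2


@dataclass
class KMResult:
    """One two-sample logrank test."""

    chi2: float
    pvalue: float
    n_group0: int
    n_group1: int
    events_group0: int
    events_group1: int


def km_logrank(time, event, group) -> KMResult:
    """Two-sample Kaplan-Meier logrank test (1 d.f.).

    Requires at least one event overall and both groups non-empty.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if (time < 0).any():
        raise ValueError("negative survival times")
    if event.sum() == 0:
        raise DegenerateInputError("no events in the data")
    n1 = int(group.sum())
    if n1 == 0 or n1 == group.size:
        raise DegenerateInputError("one group is empty")
    chi2 = float(logrank_chi2_many(time, event, group))
    if np.isnan(chi2):
        chi2 = 0.0
    return KMResult(
        chi2=chi2,
        pvalue=float(chi2_dist.sf(chi2, df=1)),
        n_group0=int(group.size - n1),
        n_group1=n1,
        events_group0=int(event[group == 0].sum()),
        events_group1=int(event[group == 1].sum()),
    )


@dataclass
class ScreenResult:
    """Per-gene KM screen over an adjusted expression panel."""

    table: pd.DataFrame          # gene, chi2, pvalue, n0, n1, testable
    significant: list[str]       # genes with pvalue < alpha, input order
    alpha: float


def screen_genes(
    adjusted: AdjustedExpression | pd.DataFrame,
    time,
    event,
    alpha: float = 0.05,
    min_group_events: int = 5,
) -> ScreenResult:
    """Median-binarize each gene and run its KM logrank test.

    Untestable genes (constant residual, a degenerate group, zero logrank
    variance) are kept in the table but flagged and excluded from the
    significant list.  Genes with fewer than ``min_group_events`` events in
    either group are flagged ``low_events`` but still tested.
    """
    R = adjusted.residuals if isinstance(adjusted, AdjustedExpression) else adjusted
    genes = list(R.index)
    if not genes:
        raise DegenerateInputError("no genes to screen")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise DegenerateInputError("no events in the data")

    X = R.to_numpy(dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    G = (X > med).T.astype(float)          # samples x genes
    n1 = G.sum(axis=0)
    testable = (n1 > 0) & (n1 < G.shape[0])

    chi2 = np.full(len(genes), np.nan)
    if testable.any():
        chi2[testable] = logrank_chi2_many(time, event, G[:, testable])
    untestable_var = testable & np.isnan(chi2)
    testable &= ~np.isnan(chi2)
    n_skip = int((~testable).sum())
    if n_skip:
        logger.info("%d untestable genes skipped during screening "
                    "(%d degenerate groups, %d zero-variance)",
                    n_skip, int((n1 == 0).sum() + (n1 == G.shape[0]).sum()),
                    int(untestable_var.sum()))
    if not testable.any():
        raise DegenerateInputError("no testable genes in the screen")

    pval = np.where(testable, chi2_dist.sf(chi2, df=1), np.nan)
    ev1 = (G * event[:, None]).sum(axis=0)
    ev0 = event.sum() - ev1
    table = pd.DataFrame({
        "gene": genes,
        "chi2": chi2,
        "pvalue": pval,
        "n_group0": (G.shape[0] - n1).astype(int),
        "n_group1": n1.astype(int),
        "events_group0": ev0.astype(int),
        "events_group1": ev1.astype(int),
        "testable": testable,
        "low_events": (np.minimum(ev0, ev1) < min_group_events),
    }).set_index("gene")
    significant = [g for g, ok, p in zip(genes, testable, pval) if ok and p < alpha]
    return ScreenResult(table=table, significant=significant, alpha=alpha)
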