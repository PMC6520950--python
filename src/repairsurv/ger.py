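"""Genomic event rates (GER) and UPGMA clustering of cancers.

A GER is the count of qualifying somatic events in a gene group divided by
(genes in group x tumors), in events per gene-tumor.  Qualifying events:
pathogenic-flagged mutations, homozygous deletions (GISTIC score -2), and
high-level amplifications (GISTIC score +2); heterozygous loss and low-level
gain (scores -1/+1) never count.  Each cancer contributes one feature vector
of rates (event types x gene groups: the driver list plus the eight repair
pathways), and cancers are clustered by UPGMA on Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .catalog import DriverGeneSet, PathwayCatalog
from .errors import DegenerateInputError
from .io import GenomicEventsInput

logger = logging.getLogger(__name__)

EVENT_TYPES = ("mutation", "deletion", "amplification")


def compute_ger(
    events: GenomicEventsInput,
    group: list[str],
    n_tumors: int,
    samples: list[str] | None = None,
    dedup_mutations: bool = True,
) -> dict[str, dict]:
    """Event counts and rates for one gene group in one cancer.

    Mutation events are pathogenic-flagged records, counted once per
    (gene, sample) pair when ``dedup_mutations`` (the default; pass False to
    count every record).  Returns a mapping event type -> {count, n_genes,
    n_tumors, rate}.
    """
    group = [g.strip().upper() for g in group]
    if not group:
        raise DegenerateInputError("empty gene group after exclusions")
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    gset = set(group)

    mut = events.mutations
    mut = mut[(mut["pathogenic"] == 1) & mut["gene"].isin(gset)]
    if samples is not None:
        mut = mut[mut["sample"].isin(set(samples))]
    if dedup_mutations:
        mut = mut.drop_duplicates(subset=["gene", "sample"])
    n_mut = int(len(mut))

    cna = events.cna
    rows = [g for g in group if g in cna.index]
    sub = cna.loc[rows]
    if samples is not None:
        cols = [s for s in samples if s in sub.columns]
        sub = sub[cols]
    vals = sub.to_numpy()
    n_del = int((vals == -2).sum())
    n_amp = int((vals == 2).sum())

    denom = len(group) * n_tumors
    return {
        etype: {
            "count": c,
            "n_genes": len(group),
            "n_tumors": n_tumors,
            "rate": c / denom,
        }
        for etype, c in zip(EVENT_TYPES, (n_mut, n_del, n_amp))
    }


def ger_feature_table(
    per_cancer_events: dict[str, GenomicEventsInput],
    per_cancer_n_tumors: dict[str, int],
    catalog: PathwayCatalog,
    drivers: dict[str, DriverGeneSet],
    per_cancer_samples: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Cancers x (group, event type) rate matrix — the clustering input.

    Columns are "<group>_<type>" for the driver list ("driver") and the
    eight repair pathways; 27 features per cancer when all groups are
    non-empty.  Driver genes flagged ``excluded_for_ger`` are removed first.
    """
    rows = {}
    for cancer, events in per_cancer_events.items():
        n_tumors = per_cancer_n_tumors[cancer]
        samples = per_cancer_samples.get(cancer) if per_cancer_samples else None
        feats = {}
        groups = {"driver": drivers[cancer].ger_genes()} if cancer in drivers else {}
        groups.update({code: genes for code, genes in catalog.pathways.items()})
        for name, genes in groups.items():
            ger = compute_ger(events, genes, n_tumors, samples=samples)
            for etype in EVENT_TYPES:
                feats[f"{name}_{etype}"] = ger[etype]["rate"]
        rows[cancer] = feats
    return pd.DataFrame.from_dict(rows, orient="index")


def euclidean_distance_matrix(rates: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between cancers' rate vectors."""
    X = rates.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = rates.index[np.isnan(X).any(axis=1)].tolist()
        raise ValueError(f"missing features for: {bad}")
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=rates.index, columns=rates.index)


@dataclass
class Dendrogram:
    """UPGMA merge history over labelled leaves.

    ``merges`` holds (cluster_a, cluster_b, height) tuples where clusters
    are frozensets of leaf labels; heights are the UPGMA merge distances and
    are non-decreasing (ultrametric).
    """

    leaves: list[str]
    merges: list[tuple[frozenset, frozenset, float]]

    def cophenetic(self, a: str, b: str) -> float:
        """Merge height at which leaves a and b first share a cluster."""
        if a == b:
            return 0.0
        for ca, cb, h in self.merges:
            if (a in ca and b in cb) or (a in cb and b in ca):
                return h
        raise KeyError(f"{a!r}, {b!r} never merged")

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (height/2 units)."""
        node_of: dict[frozenset, tuple[str, float]] = {
            frozenset([leaf]): (leaf, 0.0) for leaf in self.leaves
        }
        rep = None
        for ca, cb, h in self.merges:
            (na, ha), (nb, hb) = node_of.pop(ca), node_of.pop(cb)
            height = h / 2.0
            node = f"({na}:{height - ha:.6g},{nb}:{height - hb:.6g})"
            rep = frozenset(ca | cb)
            node_of[rep] = (node, height)
        return node_of[rep][0] + ";" if rep else f"({self.leaves[0]});"


def upgma_cluster(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA (average-linkage) agglomeration of a labelled distance matrix.

    At every step the closest cluster pair merges; the distance between
    clusters is the unweighted arithmetic mean over all cross pairs of leaf
    distances.  Ties break lexicographically on each cluster's smallest leaf
    label.  Merge heights are non-decreasing.
    """
    labels = list(dist.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    D = dist.to_numpy(dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    idx = {frozenset([lab]): i for i, lab in enumerate(labels)}
    # distances between current clusters, as mean over leaf pairs
    clusters: list[frozenset] = [frozenset([lab]) for lab in labels]
    merges: list[tuple[frozenset, frozenset, float]] = []

    def mean_dist(ca: frozenset, cb: frozenset) -> float:
        ia = [idx[frozenset([x])] for x in ca]
        ib = [idx[frozenset([x])] for x in cb]
        return float(D[np.ix_(ia, ib)].mean())

    def sort_key(c: frozenset) -> str:
        return min(c)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = sorted((clusters[i], clusters[j]), key=sort_key)
                d = mean_dist(a, b)
                key = (d, sort_key(a), sort_key(b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_, _, _), a, b = best
        h = mean_dist(a, b)
        merges.append((a, b, h))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return Dendrogram(leaves=labels, merges=merges)
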