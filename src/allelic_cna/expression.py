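"""Expression integration and centroid-based molecular subtyping.

Samples are assigned to the molecular subtype whose signature centroid
their expression profile correlates with most strongly (Pearson, over the
genes shared between matrix and centroids). Probe-level matrices are first
collapsed to one value per gene (maximum over the gene's probes).
"""
from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .instability import group_association

log = logging.getLogger("allelic_cna")

#: minimum gene overlap required between expression matrix and centroids
MIN_SHARED_GENES = 10


def collapse_to_genes(matrix: pd.DataFrame,
                      probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level, max over probes."""
    mapped = matrix.index.map(probe_to_gene.get)
    keep = mapped.notna()
    out = matrix[keep].groupby(mapped[keep]).max()
    out.index.name = "gene"
    return out


def classify_by_centroids(matrix: pd.DataFrame,
                          centroids: pd.DataFrame) -> pd.DataFrame:
    """Nearest-centroid classification by Pearson correlation.

    Correlations are computed over the gene intersection only. Returns one
    row per sample with per-class correlations, the assigned class,
    confidence (top correlation minus runner-up) and a tie flag.
    """
    shared = matrix.index.intersection(centroids.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between matrix and centroids "
            f"(need >= {MIN_SHARED_GENES})")
    X = matrix.loc[shared].to_numpy(float)          # genes x samples
    C = centroids.loc[shared].to_numpy(float)       # genes x classes
    Xc = X - X.mean(axis=0)
    Cc = C - C.mean(axis=0)
    num = Xc.T @ Cc
    den = np.outer(np.linalg.norm(Xc, axis=0), np.linalg.norm(Cc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num / den, np.nan)   # samples x classes

    classes = list(centroids.columns)
    rows = []
    for i, sample in enumerate(matrix.columns):
        r = corr[i]
        order = np.argsort(-r)
        best, runner = order[0], (order[1] if len(order) > 1 else order[0])
        tie = bool(np.isclose(r[best], r[runner]) and best != runner)
        if tie:
            log.warning("sample %s: correlation tie between %s and %s",
                        sample, classes[best], classes[runner])
        rows.append({"sample": sample,
                     **{c: float(r[j]) for j, c in enumerate(classes)},
                     "assigned": classes[best],
                     "confidence": float(r[best] - r[runner]),
                     "tie": tie})
    return pd.DataFrame(rows)


def correlation_cluster(corr: pd.DataFrame, linkage: str = "complete",
                        metric: str = "euclidean") -> list[str]:
    """Hierarchical clustering of samples on their class-correlation
    vectors; returns the dendrogram leaf order (deterministic: samples are
    pre-sorted by name so equal distances break ties by name)."""
    corr = corr.sort_index()
    if len(corr) == 1:
        return list(corr.index)
    Z = hierarchy.linkage(pdist(corr.to_numpy(float), metric=metric),
                          method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return [corr.index[i] for i in leaves]


def expression_by_cn_group(matrix: pd.DataFrame, gene: str,
                           altered_samples: Sequence[str],
                           log_scale: bool = False) -> tuple[float, float]:
    """Expression difference for one gene: altered samples vs the rest.

    Returns (fold change, rank-sum p). Fold change is mean(altered) /
    mean(rest) on the linear scale; for log2-scale input set
    ``log_scale=True`` (the difference of means is exponentiated).
    """
    if gene not in matrix.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    altered = [s for s in matrix.columns if s in set(altered_samples)]
    rest = [s for s in matrix.columns if s not in set(altered_samples)]
    if len(altered) < 2 or len(rest) < 2:
        raise ValueError("both groups need >= 2 samples")
    a = matrix.loc[gene, altered].to_numpy(float)
    b = matrix.loc[gene, rest].to_numpy(float)
    if log_scale:
        fold = float(2 ** (a.mean() - b.mean()))
    else:
        if b.mean() == 0:
            raise ValueError("reference group mean is 0; fold change undefined")
        fold = float(a.mean() / b.mean())
    values = np.concatenate([a, b])
    groups = np.array(["altered"] * len(a) + ["rest"] * len(b))
    p, _, _ = group_association(values, groups)
    return fold, p
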