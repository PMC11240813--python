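"""Rarefaction and alpha/beta diversity on genus count tables.

Count tables are genera (rows) x samples (columns), integer counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def rarefy(matrix: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample (column) without replacement to ``depth`` reads.

    Samples with fewer total reads than ``depth`` are dropped with a
    warning.  Reproducible under a fixed seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = matrix.sum(axis=0)
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning("dropping %d samples below depth %d: %s",
                       len(dropped), depth, list(dropped))
    cols = {}
    for s in keep:
        counts = matrix[s].to_numpy(np.int64)
        cols[s] = rng.multivariate_hypergeometric(counts, depth)
    out = pd.DataFrame(cols, index=matrix.index)
    if out.empty:
        out = pd.DataFrame(index=matrix.index)
    return out


def shannon_alpha(matrix: pd.DataFrame) -> pd.Series:
    """Shannon index H = -sum p ln p per sample (natural log).

    All-zero samples yield NaN with a warning.
    """
    totals = matrix.sum(axis=0).to_numpy(float)
    vals = np.full(matrix.shape[1], np.nan)
    for j, s in enumerate(matrix.columns):
        if totals[j] <= 0:
            logger.warning("sample %s has zero total; Shannon undefined", s)
            continue
        p = matrix[s].to_numpy(float) / totals[j]
        p = p[p > 0]
        vals[j] = float(-(p * np.log(p)).sum())
    return pd.Series(vals, index=matrix.columns, name="shannon")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between samples."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = matrix.to_numpy(float).T
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.columns, columns=matrix.columns)


def whittaker(matrix: pd.DataFrame) -> float:
    """Whittaker beta diversity gamma / mean(alpha) - 1 on presence/absence."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    present = matrix.to_numpy() > 0
    gamma = int(present.any(axis=1).sum())
    alpha = present.sum(axis=0).mean()
    if alpha == 0:
        raise ValueError("all samples are empty")
    return float(gamma / alpha - 1.0)


def beta_diversity(matrix: pd.DataFrame, metric: str = "bray_curtis"):
    """Dispatch to :func:`bray_curtis` (pairwise matrix) or
    :func:`whittaker` (group-level scalar)."""
    if metric == "bray_curtis":
        return bray_curtis(matrix)
    if metric == "whittaker":
        return whittaker(matrix)
    raise ValueError(f"unknown beta-diversity metric {metric!r}")
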