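"""Basis ("SparCC"-style) correlations for compositional count data.

The estimator works from the log-ratio variance matrix
``t_ij = var(log(x_i / x_j))`` and the sparsity approximation

    sum_{j != i, (i,j) not excluded} t_ij ~= (d_i - 1) w_i + sum_j w_j

which is solved for the basis variances ``w``; correlations follow from
``rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j))``.  The strongest
correlated pair is iteratively excluded from the system (up to ``n_iter``
rounds) so a few dominant associations do not bias the variance
estimates.  Estimates are averaged over Dirichlet-resampled fraction
pseudo-replicates for stability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = var over samples of log(f_i / f_j); fractions is d x n."""
    logf = np.log(fractions)
    v = logf.var(axis=1, ddof=1)
    cov = np.cov(logf)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return t


def _basis_correlations(
    t: np.ndarray, n_iter: int, exclusion_threshold: float
) -> np.ndarray:
    d = t.shape[0]
    include = ~np.eye(d, dtype=bool)  # non-excluded off-diagonal pairs
    excluded_per_comp = np.zeros(d, int)
    rho = np.zeros((d, d))
    for _ in range(max(n_iter, 1)):
        m = np.full((d, d), 1.0)
        np.fill_diagonal(m, d - 1.0 - excluded_per_comp)
        m[~include & ~np.eye(d, dtype=bool)] -= 1.0
        trow = np.where(include, t, 0.0).sum(axis=1)
        w = np.linalg.solve(m, trow)
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        # exclude the strongest remaining pair, if above threshold
        cand = np.abs(np.where(include, rho, 0.0))
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] < exclusion_threshold:
            break
        # never strip a component down to too few equations
        if excluded_per_comp[i] >= d - 3 or excluded_per_comp[j] >= d - 3:
            break
        include[i, j] = include[j, i] = False
        excluded_per_comp[i] += 1
        excluded_per_comp[j] += 1
    return np.clip(rho, -1.0, 1.0)


def sparcc_correlations(
    matrix: pd.DataFrame,
    n_iter: int = 20,
    exclusion_threshold: float = 0.1,
    n_resamples: int = 10,
    pseudocount: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate basis correlations between genera from raw counts.

    ``matrix`` is genera x samples.  Each pseudo-replicate draws sample
    fractions from Dirichlet(counts + pseudocount); the returned matrix
    is the element-wise mean over replicates, symmetric with unit
    diagonal.  With ``n_resamples=0`` the estimate is deterministic,
    using pseudocount-adjusted observed fractions directly.
    """
    d, n = matrix.shape
    if d < 4:
        raise ValueError(
            "need >= 4 genera for basis-correlation estimation; "
            "fall back to plain log-ratio correlation for smaller problems"
        )
    if n < 3:
        raise ValueError("need >= 3 samples")
    rng = np.random.default_rng(seed)
    counts = matrix.to_numpy(float)
    acc = np.zeros((d, d))
    for _ in range(max(n_resamples, 1)):
        if n_resamples == 0:
            adj = counts + pseudocount
            fracs = adj / adj.sum(axis=0, keepdims=True)
        else:
            fracs = np.empty_like(counts)
            for j in range(n):
                fracs[:, j] = rng.dirichlet(counts[:, j] + pseudocount)
        t = _log_ratio_variances(fracs)
        acc += _basis_correlations(t, n_iter, exclusion_threshold)
    rho = acc / max(n_resamples, 1)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=matrix.index, columns=matrix.index)
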