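"""Module-transition ("NetMoss"-style) scoring, biomarker calling and
cross-validated panel evaluation.

For node *i* under condition networks A and B plus the combined network:

* ``D_ij`` is the mean unweighted shortest-path length from *i* to the
  members of module *j* (unreachable members contribute ``n_nodes``),
* ``dD_ij = |D_ij(combined) - D_ij(condition)|`` with modules taken from
  that condition's partition,
* ``Neighbors_A(i)`` is the module neighbourhood of *i* in A, read as all
  modules of A's partition (likewise for B): a node disconnected from a
  module in one network but not the other then contributes its full
  distance change,
* the raw transition score is
  ``sum_{j in Neighbors_A} dD_ij - sum_{l in Neighbors_B} dD_il``,
  and scores are mapped to [0, 1] by min-max over absolute raw values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse.csgraph import shortest_path
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from herdrank.microbiome.network import CooccurrenceNetwork


def _path_lengths(network: CooccurrenceNetwork) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths; inf -> n_nodes."""
    adj = network.adjacency.to_numpy(float)
    n = adj.shape[0]
    sp = shortest_path(adj, method="D", unweighted=True, directed=False)
    sp[~np.isfinite(sp)] = float(n)
    return sp


def _module_distances(sp: np.ndarray, modules: pd.Series, nodes: list[str]) -> np.ndarray:
    """D[i, m] = mean shortest-path length from node i to module m's members."""
    labels = modules.loc[nodes].to_numpy()
    mod_ids = np.unique(labels)
    D = np.empty((len(nodes), len(mod_ids)))
    for m_idx, m in enumerate(mod_ids):
        members = np.flatnonzero(labels == m)
        D[:, m_idx] = sp[:, members].mean(axis=1)
    return D


def _one_sided_sums(
    net: CooccurrenceNetwork,
    net_combined: CooccurrenceNetwork,
    modules: pd.Series,
    nodes: list[str],
) -> np.ndarray:
    """sum over the condition's modules of |D_combined - D_condition| per node."""
    sp_cond = _path_lengths(net)
    sp_comb = _path_lengths(net_combined)
    D_cond = _module_distances(sp_cond, modules, nodes)
    D_comb = _module_distances(sp_comb, modules, nodes)
    return np.abs(D_comb - D_cond).sum(axis=1)


def netmoss_scores(
    net_a: CooccurrenceNetwork,
    net_b: CooccurrenceNetwork,
    net_combined: CooccurrenceNetwork,
    partition_a: pd.Series,
    partition_b: pd.Series,
) -> pd.DataFrame:
    """Per-node transition scores between condition networks A and B.

    Returns a frame with ``raw`` (signed sum difference) and ``score``
    (min-max-normalized absolute value in [0, 1]).  Identical networks
    give identically zero scores.
    """
    nodes = net_a.nodes
    if net_b.nodes != nodes or net_combined.nodes != nodes:
        raise ValueError("the three networks must share an identical node set")
    sum_a = _one_sided_sums(net_a, net_combined, partition_a, nodes)
    sum_b = _one_sided_sums(net_b, net_combined, partition_b, nodes)
    raw = sum_a - sum_b
    # normalize absolute values within each driving direction (sign of
    # raw), so the scale of one direction's rewiring does not mask the
    # other's; identical networks give all-zero raw hence all-zero scores
    mag = np.abs(raw)
    score = np.zeros_like(mag)
    for side in (raw >= 0, raw < 0):
        if side.any() and mag[side].max() > 0:
            score[side] = mag[side] / mag[side].max()
    return pd.DataFrame({"raw": raw, "score": score}, index=pd.Index(nodes, name="genus"))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def differential_biomarkers(
    matrix: pd.DataFrame,
    classes: pd.Series,
    scores: pd.DataFrame,
    score_threshold: float = 0.25,
    fdr_threshold: float = 0.05,
    pseudo_rel: float = 1e-6,
) -> pd.DataFrame:
    """Call biomarkers: transition score above threshold AND BH-adjusted
    rank-sum p below the FDR threshold.

    ``classes`` maps sample -> {"dominant", "submissive"}.  The log2
    fold-change is submissive-over-dominant median relative abundance
    (with a pseudocount); direction is the class with the higher median.
    """
    labels = classes.loc[matrix.columns]
    groups = set(labels.unique())
    if groups != {"dominant", "submissive"}:
        raise ValueError(f"need exactly the two classes dominant/submissive, got {groups}")
    dom_cols = labels.index[labels == "dominant"]
    sub_cols = labels.index[labels == "submissive"]
    if len(dom_cols) < 3 or len(sub_cols) < 3:
        raise ValueError("need >= 3 samples per class")
    rel = matrix / matrix.sum(axis=0)
    rows = []
    for genus in matrix.index:
        x_dom = rel.loc[genus, dom_cols].to_numpy(float)
        x_sub = rel.loc[genus, sub_cols].to_numpy(float)
        stat, p = sps.mannwhitneyu(x_sub, x_dom, alternative="two-sided")
        med_dom, med_sub = np.median(x_dom), np.median(x_sub)
        log2fc = float(np.log2((med_sub + pseudo_rel) / (med_dom + pseudo_rel)))
        rows.append(
            {
                "genus": genus,
                "netmoss_score": float(scores.loc[genus, "score"]),
                "log2fc_sub_over_dom": log2fc,
                "p": float(p),
                "median_dominant": float(med_dom),
                "median_submissive": float(med_sub),
            }
        )
    out = pd.DataFrame(rows).set_index("genus")
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    called = (out["netmoss_score"] >= score_threshold) & (out["p_adj"] < fdr_threshold)
    direction = np.where(
        out["median_submissive"] > out["median_dominant"], "submissive", "dominant"
    )
    out["direction"] = np.where(called, direction, "none")
    out["biomarker"] = called
    return out.sort_values("netmoss_score", ascending=False)


def auc_from_scores(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formula with midranks for ties."""
    y_true = np.asarray(y_true, int)
    y_score = np.asarray(y_score, float)
    n_pos = int(y_true.sum())
    n_neg = int(len(y_true) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute AUC")
    ranks = sps.rankdata(y_score)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def cv_auc(
    matrix: pd.DataFrame,
    classes: pd.Series,
    biomarkers: list[str],
    k: int = 5,
    seed: int = 0,
    ridge_c: float = 1.0,
    pseudo_rel: float = 1e-6,
) -> float:
    """Stratified k-fold CV AUC of a ridge-stabilized logistic classifier
    on log relative abundances of the biomarker panel; out-of-fold scores
    are pooled before the rank-based AUC."""
    if not biomarkers:
        raise ValueError("empty biomarker panel")
    labels = classes.loc[matrix.columns]
    y = (labels == "dominant").to_numpy(int)
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() == 0:
        raise ValueError("need both classes present")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class size {counts.min()}")
    rel = matrix / matrix.sum(axis=0)
    X = np.log(rel.loc[biomarkers].to_numpy(float).T + pseudo_rel)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(len(y))
    for train, test in skf.split(X, y):
        clf = LogisticRegression(C=ridge_c, max_iter=5000)
        clf.fit(X[train], y[train])
        pooled[test] = clf.predict_proba(X[test])[:, 1]
    return auc_from_scores(y, pooled)
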