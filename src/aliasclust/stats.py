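"""Downstream demonstration statistics: Mann-Whitney U and FDR.

After alias clustering, each feature (cluster centroid or unclustered
peak) is tested for a two-group difference with the two-sided
Mann-Whitney U test, and p-values are corrected across the feature family
with the Benjamini-Hochberg step-up procedure.  A permutation utility
reports the mean number of FDR discoveries under random group labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DesignError

#: exact enumeration of the U null is used up to this pooled sample size
_EXACT_MAX_N = 12


def mann_whitney(values_group1, values_group2) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group 1, p).

    Uses exact enumeration of the U distribution when the pooled size is
    <= 12 and there are no ties, otherwise the normal approximation with
    tie correction and continuity correction.  Constant pooled data gives
    U = n1*n2/2 and p = 1.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def feature_tests(
    matrix: pd.DataFrame, groups, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature Mann-Whitney + BH over a feature-by-sample matrix.

    ``matrix`` rows are features and columns are samples; ``groups`` maps
    sample id -> group label (exactly two groups required).  Returns a
    DataFrame with feature_id, U, p, q and a significance flag at
    ``alpha`` applied to q.
    """
    labels = sorted({groups[s] for s in matrix.columns})
    if len(labels) != 2:
        raise DesignError(f"need exactly 2 groups, got {labels}")
    cols1 = [s for s in matrix.columns if groups[s] == labels[0]]
    cols2 = [s for s in matrix.columns if groups[s] == labels[1]]
    stats, ps = [], []
    for _, row in matrix.iterrows():
        u, p = mann_whitney(row[cols1].to_numpy(), row[cols2].to_numpy())
        stats.append(u)
        ps.append(p)
    q = fdr_bh(ps)
    return pd.DataFrame(
        {
            "feature_id": matrix.index,
            "U": stats,
            "p": ps,
            "q": q,
            "significant": q < alpha,
        }
    ).set_index("feature_id")


def permutation_discoveries(
    matrix: pd.DataFrame,
    groups,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Mean FDR-discovery count over random group-label permutations.

    For each of ``n_perm`` permutations of the sample group labels, count
    the features whose BH q-value falls below ``alpha``; return the mean
    count.  Deterministic in ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    sample_ids = list(matrix.columns)
    base_labels = [groups[s] for s in sample_ids]
    counts = []
    for _ in range(n_perm):
        permuted = dict(zip(sample_ids, rng.permutation(base_labels)))
        res = feature_tests(matrix, permuted, alpha=alpha)
        counts.append(int(res["significant"].sum()))
    return float(np.mean(counts))


def significant_peak_accounting(
    results: pd.DataFrame, clusters, alpha: float = 0.05
) -> dict[str, int]:
    """Book-keeping of significant features back onto original peaks.

    Given per-feature results (indexed by feature id, cluster centroids
    included) and the cluster list, report how many original peaks sit in
    significant clusters, how many significant features are unclustered
    peaks, and their total — the count of original peaks accounted
    significant after clustering.
    """
    sig = set(results.index[results["q"] < alpha])
    by_id = {c.cluster_id: c for c in clusters}
    n_sig_clusters = sum(1 for cid in by_id if cid in sig)
    n_peaks_in_sig = sum(len(by_id[cid].members) for cid in by_id if cid in sig)
    n_sig_unclustered = sum(1 for fid in sig if fid not in by_id)
    return {
        "n_significant_features": len(sig),
        "n_significant_clusters": n_sig_clusters,
        "n_peaks_in_significant_clusters": n_peaks_in_sig,
        "n_significant_unclustered_peaks": n_sig_unclustered,
        "n_original_peaks_significant": n_peaks_in_sig + n_sig_unclustered,
    }
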