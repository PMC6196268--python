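"""Univariate differential expression and hierarchical bi-clustering.

A miRNA is *induced* (up in the CD56dim group) when its adjusted p-value is
at most alpha and the difference of group medians on the log2 scale is at
least log2(FC_min); *repressed* when the difference is at most -log2(FC_min).
Fold change is reported as the signed linear-scale equivalent of the median
log2 difference, so a two-fold criterion corresponds to |delta| >= 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import f_oneway, mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleMetadata
from .preprocess import detection_call

__all__ = [
    "DifferentialResult",
    "differential_expression",
    "adjust_pvalues",
    "group_mean_test",
    "hierarchical_bicluster",
    "ClusterTree",
]


@dataclass
class DifferentialResult:
    feature: str
    median_bright: float
    median_dim: float
    delta: float          # median(dim) - median(bright), log2 units
    fold_change: float    # signed 2^|delta|
    p_raw: float
    p_adj: float
    status: str           # induced | repressed | unchanged


def adjust_pvalues(p_values, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini-Hochberg step-up or Bonferroni."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def _exact_mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumeration of group assignments.

    Mid-ranks handle ties; valid for small samples where the normal
    approximation is unreliable.
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    dev_obs = abs(u_obs - center)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= dev_obs - 1e-12:
            count += 1
    return float(u_obs), count / total


def group_mean_test(*groups, kind: str = "welch_t"):
    """Two-group or multi-group location test.

    kind='welch_t'       : Welch two-sample t-test (statistic, p)
    kind='mann_whitney'  : two-sided Mann-Whitney; exact enumeration when both
                           groups have <= 8 samples, mid-rank normal
                           approximation otherwise
    kind='anova_bonferroni': one-way ANOVA over >=3 groups; returns
                           (F, p, {pair: adjusted p}) with Bonferroni-adjusted
                           pairwise post tests on the pooled error term
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if kind == "welch_t":
        if len(groups) != 2:
            raise ValueError("welch_t requires exactly two groups")
        stat, p = ttest_ind(groups[0], groups[1], equal_var=False)
        return float(stat), float(p)
    if kind == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        a, b = groups
        if len(a) <= 8 and len(b) <= 8:
            return _exact_mannwhitney(a, b)
        stat, p = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(stat), float(p)
    if kind == "anova_bonferroni":
        if len(groups) < 3:
            raise ValueError("anova_bonferroni requires at least three groups")
        f_stat, p = f_oneway(*groups)
        # pairwise t on the pooled within-group variance (classical post test)
        k = len(groups)
        ns = np.array([len(g) for g in groups])
        means = np.array([g.mean() for g in groups])
        df_err = int(ns.sum() - k)
        if df_err <= 0:
            raise ValueError("not enough samples for the post test")
        ss_err = sum(((g - g.mean()) ** 2).sum() for g in groups)
        ms_err = ss_err / df_err
        from scipy.stats import t as t_dist

        pairs = list(itertools.combinations(range(k), 2))
        m = len(pairs)
        post = {}
        for i, j in pairs:
            se = np.sqrt(ms_err * (1 / ns[i] + 1 / ns[j]))
            if se == 0:
                p_pair = 1.0
            else:
                t = (means[i] - means[j]) / se
                p_pair = min(1.0, 2 * t_dist.sf(abs(t), df_err) * m)
            post[(i, j)] = float(p_pair)
        return float(f_stat), float(p), post
    raise ValueError(f"unknown test kind {kind!r}")


def differential_expression(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    test: str = "welch_t",
    adjust: str = "bh",
    detection_threshold: float = 1.0,
    detection_fraction: float = 0.5,
    apply_detection_filter: bool = True,
    groups: tuple[str, str] = ("bright", "dim"),
) -> list[DifferentialResult]:
    """Per-feature two-group test with fold-change and significance calls.

    Features not detected in at least ``detection_fraction`` of samples in
    either group are excluded before testing (and before the multiplicity
    adjustment).  ``delta`` is median(second group) - median(first group).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fc_min < 1:
        raise ValueError(f"fc_min must be >= 1, got {fc_min}")
    matrix.require_log2()
    md = metadata.align(matrix)
    g_ref, g_alt = groups
    cols_ref = (md.table["group"] == g_ref).to_numpy()
    cols_alt = (md.table["group"] == g_alt).to_numpy()
    if cols_ref.sum() < 2 or cols_alt.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    if apply_detection_filter:
        det = detection_call(matrix, md, threshold=detection_threshold,
                             fraction=detection_fraction, groups=groups)
        keep = det.detected_half[g_ref] | det.detected_half[g_alt]
        features = [f for f in matrix.feature_ids if f in keep]
    else:
        features = matrix.feature_ids
    if not features:
        return []

    sub = matrix.data.loc[features]
    v_ref = sub.to_numpy()[:, cols_ref]
    v_alt = sub.to_numpy()[:, cols_alt]
    med_ref = np.median(v_ref, axis=1)
    med_alt = np.median(v_alt, axis=1)
    delta = med_alt - med_ref

    p_raw = np.empty(len(features))
    for i in range(len(features)):
        _, p = group_mean_test(v_ref[i], v_alt[i], kind=test)
        p_raw[i] = p
    p_raw = np.nan_to_num(p_raw, nan=1.0)
    p_adj = adjust_pvalues(p_raw, adjust)

    thr = np.log2(fc_min)
    out = []
    for i, f in enumerate(features):
        if p_adj[i] <= alpha and delta[i] >= thr:
            status = "induced"
        elif p_adj[i] <= alpha and delta[i] <= -thr:
            status = "repressed"
        else:
            status = "unchanged"
        fc = float(np.sign(delta[i]) * 2 ** abs(delta[i])) if delta[i] != 0 else 1.0
        out.append(DifferentialResult(
            feature=f,
            median_bright=float(med_ref[i]),
            median_dim=float(med_alt[i]),
            delta=float(delta[i]),
            fold_change=fc,
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
            status=status,
        ))
    return out


@dataclass
class ClusterTree:
    """Agglomerative clustering over one axis of an expression matrix."""

    items: list[str]
    linkage_matrix: np.ndarray  # scipy hierarchy format

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in leaves_list(self.linkage_matrix)]

    def cut(self, k: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.items, (int(x) for x in labels)))

    def to_newick(self) -> str:
        n = len(self.items)
        names: dict[int, str] = {i: self.items[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage_matrix):
            names[n + i] = f"({names[int(a)]},{names[int(b)]}):{h:.6g}"
        return names[n + len(self.linkage_matrix) - 1].rsplit(":", 1)[0] + ";"


def _pairwise_distance(v: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        sd = v.std(axis=1)
        if np.any(sd == 0):
            raise ValueError(
                "constant rows have undefined correlation distance; "
                "use metric='euclidean'"
            )
        return pdist(v, metric="correlation")  # 1 - Pearson r
    if metric == "euclidean":
        return pdist(v, metric="euclidean")
    raise ValueError(f"unknown distance metric {metric!r}")


def hierarchical_bicluster(
    matrix: ExpressionMatrix,
    metric: str = "correlation",
    method: str = "average",
) -> tuple[ClusterTree, ClusterTree]:
    """Cluster features and samples independently (the bi-clustering of the
    two-way heat map).  Items are pre-sorted lexicographically so equal-
    distance merges resolve deterministically."""
    if matrix.n_features < 2 or matrix.n_samples < 2:
        raise ValueError("need at least 2 features and 2 samples")
    feat_sorted = sorted(matrix.feature_ids)
    samp_sorted = sorted(matrix.sample_ids)
    df = matrix.data.loc[feat_sorted, samp_sorted]
    feat_tree = ClusterTree(
        feat_sorted, linkage(_pairwise_distance(df.to_numpy(), metric), method=method)
    )
    samp_tree = ClusterTree(
        samp_sorted, linkage(_pairwise_distance(df.to_numpy().T, metric), method=method)
    )
    return feat_tree, samp_tree
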