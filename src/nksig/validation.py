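"""Signature validation: Monte-Carlo CV accuracy, permutation null and the
two-sample Kolmogorov-Smirnov comparison, plus prediction of samples measured
on a different platform (qPCR).

The reduced signature is assessed by fitting regularized least squares on R
random stratified learning/test splits and recording test accuracy.  The same
procedure with permuted labels yields a null accuracy distribution; a
two-sample KS test between the two distributions quantifies whether the
signature's performance is distinguishable from chance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import ks_2samp

from .io import ExpressionMatrix, SampleMetadata
from .l1l2 import LinearModel, fit_rls, predict
from .selection import stratified_mc_splits

__all__ = [
    "ValidationReport",
    "montecarlo_cv_accuracy",
    "ks_significance",
    "validate_signature",
    "cross_technology_predict",
    "qpcr_to_expression",
]


@dataclass
class ValidationReport:
    accuracy_true: np.ndarray
    accuracy_perm: np.ndarray
    mean_accuracy: float
    ks_statistic: float
    ks_pvalue: float
    seed: int
    harmonization: str = "per-feature z-score within each platform cohort"

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "mean_accuracy": self.mean_accuracy,
            "ks_statistic": self.ks_statistic,
            "ks_pvalue": self.ks_pvalue,
            "seed": self.seed,
            "harmonization": self.harmonization,
            "accuracy_true": list(map(float, self.accuracy_true)),
            "accuracy_perm": list(map(float, self.accuracy_perm)),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def montecarlo_cv_accuracy(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    mu: float = 0.1,
    R: int = 100,
    test_fraction: float = 0.25,
    seed: int = 0,
    permute_labels: bool = False,
    groups: tuple[str, str] = ("bright", "dim"),
) -> np.ndarray:
    """Test-set accuracies of ridge classifiers over R stratified random splits.

    With ``permute_labels`` the labels are shuffled independently in each
    repetition before splitting, which produces the chance-level null.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    matrix.require_log2()
    md = metadata.align(matrix)
    y0 = md.two_group_labels(matrix.sample_ids, positive=groups[1],
                             negative=groups[0])
    X = matrix.values.T
    rng = np.random.default_rng(seed)
    acc = np.empty(R)
    for r in range(R):
        y = rng.permutation(y0) if permute_labels else y0
        (train_idx, test_idx), = stratified_mc_splits(y, 1, test_fraction, rng)
        model = fit_rls(X[train_idx], y[train_idx], mu=mu)
        acc[r] = float(np.mean(predict(model, X[test_idx]) == y[test_idx]))
    return acc


def ks_significance(acc_true, acc_perm) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov comparison of accuracy samples.

    Exact p-value when both samples have at most 25 observations, asymptotic
    otherwise.
    """
    a = np.asarray(acc_true, dtype=float)
    b = np.asarray(acc_perm, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both accuracy samples must be non-empty")
    method = "exact" if (a.size <= 25 and b.size <= 25) else "asymp"
    res = ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def validate_signature(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    features,
    mu: float = 0.1,
    R_true: int = 100,
    R_perm: int = 100,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> ValidationReport:
    """Full validation of a reduced signature: true-label and permuted-label
    Monte-Carlo accuracy distributions and their KS comparison."""
    sub = matrix.subset_features(list(features))
    acc_true = montecarlo_cv_accuracy(sub, metadata, mu=mu, R=R_true,
                                      test_fraction=test_fraction, seed=seed)
    acc_perm = montecarlo_cv_accuracy(sub, metadata, mu=mu, R=R_perm,
                                      test_fraction=test_fraction,
                                      seed=seed + 1, permute_labels=True)
    d, p = ks_significance(acc_true, acc_perm)
    return ValidationReport(
        accuracy_true=acc_true,
        accuracy_perm=acc_perm,
        mean_accuracy=float(acc_true.mean()),
        ks_statistic=d,
        ks_pvalue=p,
        seed=seed,
    )


def qpcr_to_expression(relative: "np.ndarray | object") -> ExpressionMatrix:
    """Wrap a features x samples table of qPCR-derived log2-like values
    (e.g. -dCt per feature) as an expression matrix."""
    import pandas as pd

    if not isinstance(relative, pd.DataFrame):
        raise TypeError("expected a features x samples DataFrame")
    return ExpressionMatrix(relative.astype(float), "log2")


def cross_technology_predict(
    model: LinearModel,
    qpcr_expr,
) -> np.ndarray:
    """Classify samples measured on a different platform with the sign rule.

    Values (a log2-like scale such as -dCt) are z-scored per feature across
    the new cohort, removing platform-specific location and scale, and the
    model's weights are applied to the harmonized values.  Features with zero
    variance in the new cohort cannot be harmonized and are dropped with a
    warning (their weight is excluded).
    """
    if not isinstance(qpcr_expr, ExpressionMatrix):
        qpcr_expr = qpcr_to_expression(qpcr_expr)
    missing = [f for f in model.feature_names if f not in qpcr_expr.feature_ids]
    if missing:
        raise KeyError(f"qPCR cohort lacks model features: {', '.join(missing)}")
    sub = qpcr_expr.data.loc[model.feature_names]
    v = sub.to_numpy(dtype=float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    usable = (sd[:, 0] > 0)
    if not usable.all():
        dropped = [f for f, u in zip(model.feature_names, usable) if not u]
        warnings.warn(
            f"dropping zero-variance feature(s) in the new cohort: "
            f"{', '.join(dropped)}"
        )
    z = np.zeros_like(v)
    z[usable] = (v[usable] - mean[usable]) / sd[usable]
    scores = model.beta[usable] @ z[usable] + model.intercept
    return np.where(scores >= 0.0, 1.0, -1.0)
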