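"""Microarray preprocessing chain.

The chain mirrors standard one-color miRNA array practice: floor raw
intensities at a detection threshold (1 light unit), take base-2 logs,
quantile-normalize arrays against each other, remove additive batch offsets,
and optionally median-center each feature for heat-map display.  Detection
calls summarize which miRNAs are reliably measured in each phenotype group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleMetadata

__all__ = [
    "floor_threshold",
    "log2_transform",
    "quantile_normalize",
    "batch_adjust",
    "median_center",
    "detection_call",
    "DetectionSummary",
    "preprocess_chain",
]


def floor_threshold(matrix: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Replace every linear-scale intensity below ``floor`` by ``floor``."""
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    if matrix.scale != "linear":
        raise ValueError("floor_threshold expects a linear-scale matrix")
    return matrix.copy_with(np.maximum(matrix.values, floor))


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log2; requires strictly positive values (floor first)."""
    if matrix.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    v = matrix.values
    if (v <= 0).any():
        raise ValueError(
            "non-positive intensities present; apply floor_threshold before log2"
        )
    return matrix.copy_with(np.log2(v), scale="log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean distribution of order statistics.

    After normalization each column's sorted values equal the across-column
    mean of sorted values.  Ties within a column receive the mean of the
    reference distribution over the tied rank span, so the transform is
    rank-preserving and permutation-equivariant.
    """
    v = matrix.values
    n_features, n_samples = v.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return matrix.copy_with(v.copy())
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(n_samples):
        order = np.argsort(v[:, j], kind="mergesort")
        col = v[order, j]
        res = np.empty(n_features)
        # runs of tied values share the mean reference over their rank span
        starts = np.flatnonzero(np.r_[True, col[1:] != col[:-1]])
        ends = np.r_[starts[1:], n_features]
        for s, e in zip(starts, ends):
            res[s:e] = reference[s:e].mean()
        out[order, j] = res
    return matrix.copy_with(out)


def batch_adjust(matrix: ExpressionMatrix, metadata: SampleMetadata) -> ExpressionMatrix:
    """Remove per-feature additive batch offsets (location-only adjustment).

    Each batch's per-feature mean is shifted to the feature's grand mean.
    Requires every batch to contain more than one phenotype group; a batch
    holding a single group would confound batch with phenotype and the
    adjustment would erase the biological contrast.
    """
    md = metadata.align(matrix)
    batches = md.table["batch"].to_numpy()
    groups = md.table["group"].to_numpy()
    uniq = pd.unique(batches)
    for b in uniq:
        gb = set(groups[batches == b])
        if len(gb) < 2 and len(set(groups)) >= 2:
            raise ValueError(
                f"batch {b!r} contains a single group {gb}; batch is confounded "
                "with phenotype and cannot be adjusted"
            )
    v = matrix.values.copy()
    grand = v.mean(axis=1, keepdims=True)
    for b in uniq:
        cols = batches == b
        v[:, cols] += grand - v[:, cols].mean(axis=1, keepdims=True)
    return matrix.copy_with(v)


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's across-sample median (log2 scale)."""
    matrix.require_log2()
    v = matrix.values
    return matrix.copy_with(v - np.median(v, axis=1, keepdims=True))


@dataclass
class DetectionSummary:
    """Which features exceed the detection threshold in each group.

    ``detected_half`` holds features over the threshold in at least
    ``ceil(fraction * n)`` samples of a group; ``detected_all`` in every
    sample.  ``shared`` and ``exclusive`` partition the union of the two
    groups' half-detection sets.
    """

    threshold: float
    fraction: float
    detected_half: dict[str, set] = field(default_factory=dict)
    detected_all: dict[str, set] = field(default_factory=dict)
    shared: set = field(default_factory=set)
    exclusive: dict[str, set] = field(default_factory=dict)

    @property
    def counts(self) -> dict:
        out = {}
        for g in self.detected_half:
            out[f"{g}_half"] = len(self.detected_half[g])
            out[f"{g}_all"] = len(self.detected_all[g])
        out["shared"] = len(self.shared)
        out["exclusive_total"] = sum(len(s) for s in self.exclusive.values())
        for g, s in self.exclusive.items():
            out[f"exclusive_{g}"] = len(s)
        return out


def detection_call(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    threshold: float = 1.0,
    fraction: float = 0.5,
    groups: tuple[str, str] = ("bright", "dim"),
) -> DetectionSummary:
    """Detection summary at ``threshold`` light units (on the matrix's scale).

    A feature is detected in a sample when its value exceeds the threshold;
    "half or more" means at least ``ceil(fraction * n)`` of the group's
    samples.  The threshold defaults to 1 LU applied to the normalized log2
    table, matching how the detection counts are reported downstream of
    normalization.
    """
    md = metadata.align(matrix)
    summary = DetectionSummary(threshold=threshold, fraction=fraction)
    features = np.array(matrix.feature_ids)
    for g in groups:
        cols = (md.table["group"] == g).to_numpy()
        if cols.sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
        sub = matrix.values[:, cols]
        n = sub.shape[1]
        need = ceil(fraction * n)
        over = (sub > threshold).sum(axis=1)
        summary.detected_half[g] = set(features[over >= need])
        summary.detected_all[g] = set(features[over == n])
    a, b = groups
    summary.shared = summary.detected_half[a] & summary.detected_half[b]
    summary.exclusive = {
        a: summary.detected_half[a] - summary.detected_half[b],
        b: summary.detected_half[b] - summary.detected_half[a],
    }
    return summary


def preprocess_chain(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata | None = None,
    floor: float = 1.0,
    adjust_batch: bool = True,
    center: bool = False,
) -> ExpressionMatrix:
    """floor -> log2 -> quantile -> batch adjustment -> (optional) median centering."""
    m = floor_threshold(matrix, floor)
    m = log2_transform(m)
    m = quantile_normalize(m)
    if adjust_batch:
        if metadata is None:
            raise ValueError("batch adjustment requires sample metadata")
        m = batch_adjust(m, metadata)
    if center:
        m = median_center(m)
    return m
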