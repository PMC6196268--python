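"""Synthetic data with the statistical structure of the NK-subset study.

The generator emulates a two-group miRNA microarray experiment: ten paired
donors each contributing one CD56bright and one CD56dim sample, ~2000
features of which only a few hundred are expressed above the 1-light-unit
detection floor, a planted set of up- and down-regulated miRNAs with at
least two-fold median differences, features expressed exclusively in one
group, two acquisition batches with an additive log2 offset, and log-normal
measurement noise (Gaussian on the log2 scale).  Ground truth is returned
alongside the data so every pipeline stage can be scored offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleMetadata

__all__ = [
    "SyntheticTruth",
    "generate_microarray",
    "generate_intermediate_group",
    "generate_qpcr",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``effect`` maps every feature to its dim-minus-bright log2 shift (0 for
    null features); ``up``/``down`` list planted features by direction, and
    ``exclusive`` the features pushed below the detection floor in one group.
    ``baseline_log2`` is the bright-group mean on the log2 scale.
    """

    feature_ids: list[str]
    baseline_log2: np.ndarray
    effect: np.ndarray                 # dim mean minus bright mean, log2
    up: list[str]
    down: list[str]
    exclusive: dict[str, list[str]]
    batch_offset: float
    sigma: float
    seed: int
    donor_sd: float = 0.0

    def __post_init__(self) -> None:
        sets = [set(self.up), set(self.down),
                set(self.exclusive.get("bright", [])),
                set(self.exclusive.get("dim", []))]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("planted feature sets must be disjoint")

    @property
    def planted(self) -> list[str]:
        return list(self.up) + list(self.down)

    def effect_of(self, feature: str) -> float:
        return float(self.effect[self.feature_ids.index(feature)])

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "up": self.up, "down": self.down, "exclusive": self.exclusive,
            "batch_offset": self.batch_offset, "sigma": self.sigma,
            "seed": self.seed, "donor_sd": self.donor_sd,
            "effects": {f: float(e) for f, e in
                        zip(self.feature_ids, self.effect) if e != 0.0},
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _feature_names(d: int) -> list[str]:
    return [f"syn-miR-{i + 1:04d}" for i in range(d)]


def generate_microarray(
    n_per_group: int = 10,
    d: int = 2000,
    n_expressed: int = 250,
    n_up: int = 15,
    n_down: int = 15,
    n_exclusive_each: int = 2,
    effect_log2: float = 1.5,
    sigma: float = 0.3,
    batch_offset: float = 0.5,
    donor_sd: float = 0.0,
    expressed_loc: float = 5.5,
    expressed_scale: float = 1.2,
    background_range: tuple[float, float] = (-2.0, 0.5),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleMetadata, SyntheticTruth]:
    """Generate a linear-scale expression matrix with planted differential
    structure, paired donors and two batches.

    Planted up/down features shift the dim group by +/- ``effect_log2`` on
    the log2 scale (>= 2-fold when effect_log2 >= 1).  Exclusive features are
    expressed in one group and sit below the 1 LU floor in the other.  Donors
    are split between two batches with both groups present in each; the
    second batch carries an additive log2 offset.  The returned matrix is on
    the linear scale, ready for the preprocessing chain.
    """
    n_planted = n_up + n_down + 2 * n_exclusive_each
    if n_planted > n_expressed or n_expressed > d:
        raise ValueError(
            f"infeasible design: need n_up+n_down+2*n_exclusive_each "
            f"({n_planted}) <= n_expressed ({n_expressed}) <= d ({d})"
        )
    if n_per_group < 2:
        raise ValueError("need at least 2 donors per group")
    rng = np.random.default_rng(seed)
    features = _feature_names(d)

    expressed_idx = rng.choice(d, size=n_expressed, replace=False)
    planted_idx = rng.choice(expressed_idx, size=n_planted, replace=False)
    up_idx = planted_idx[:n_up]
    down_idx = planted_idx[n_up:n_up + n_down]
    excl_bright_idx = planted_idx[n_up + n_down:n_up + n_down + n_exclusive_each]
    excl_dim_idx = planted_idx[n_up + n_down + n_exclusive_each:]

    baseline = rng.uniform(*background_range, size=d)
    # expressed features: Gaussian on the log2 scale (log-normal intensities)
    # with soft tails, as real array intensity distributions have — a hard
    # upper bound would pile shifted features onto the extreme ranks, where
    # quantile normalization artificially compresses genuine differences
    baseline[expressed_idx] = rng.normal(expressed_loc, expressed_scale,
                                         size=n_expressed)

    effect = np.zeros(d)
    effect[up_idx] = effect_log2
    effect[down_idx] = -effect_log2
    # exclusive-in-bright: expressed in bright, below the floor in dim
    low = rng.uniform(background_range[0], -0.5, size=n_exclusive_each)
    effect[excl_bright_idx] = low - baseline[excl_bright_idx]
    # exclusive-in-dim: below the floor in bright, expressed in dim
    baseline_dim_side = baseline[excl_dim_idx].copy()
    baseline[excl_dim_idx] = rng.uniform(background_range[0], -0.5,
                                         size=n_exclusive_each)
    effect[excl_dim_idx] = baseline_dim_side - baseline[excl_dim_idx]

    donors = [f"d{i + 1:02d}" for i in range(n_per_group)]
    sample_ids, groups_col, donor_col, batch_col = [], [], [], []
    for g, shift in (("bright", 0.0), ("dim", 1.0)):
        for i, donor in enumerate(donors):
            sample_ids.append(f"{g}_{donor}")
            groups_col.append(g)
            donor_col.append(donor)
            batch_col.append("b1" if i < n_per_group // 2 else "b2")

    donor_effects = rng.normal(0.0, donor_sd, size=n_per_group) if donor_sd > 0 \
        else np.zeros(n_per_group)

    log2_values = np.empty((d, len(sample_ids)))
    for j, (g, donor, batch) in enumerate(zip(groups_col, donor_col, batch_col)):
        mean = baseline + (effect if g == "dim" else 0.0)
        col = mean + donor_effects[donors.index(donor)]
        if batch == "b2":
            col = col + batch_offset
        col = col + rng.normal(0.0, sigma, size=d)
        log2_values[:, j] = col

    matrix = ExpressionMatrix(
        pd.DataFrame(2.0 ** log2_values, index=features, columns=sample_ids),
        "linear",
    )
    metadata = SampleMetadata(pd.DataFrame({
        "group": groups_col, "donor": donor_col, "batch": batch_col,
    }, index=pd.Index(sample_ids, name="sample_id")))
    truth = SyntheticTruth(
        feature_ids=features,
        baseline_log2=baseline,
        effect=effect,
        up=[features[i] for i in up_idx],
        down=[features[i] for i in down_idx],
        exclusive={
            "bright": [features[i] for i in excl_bright_idx],
            "dim": [features[i] for i in excl_dim_idx],
        },
        batch_offset=batch_offset,
        sigma=sigma,
        seed=seed,
        donor_sd=donor_sd,
    )
    return matrix, metadata, truth


def generate_intermediate_group(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    truth: SyntheticTruth,
    mixing: float = 0.5,
    n_samples: int = 3,
    seed: int = 1,
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Append a CD56bright/CD16dim-like group with expression halfway between
    the two base groups.

    The new samples' per-feature means are the convex combination
    (1 - mixing) * bright + mixing * dim of the planted group means, with the
    generator's noise level; mixing=0 reproduces bright means, mixing=1 dim
    means.
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError(f"mixing must be in [0, 1], got {mixing}")
    if matrix.scale != "linear":
        raise ValueError("expected the generator's linear-scale matrix")
    rng = np.random.default_rng(seed)
    d = len(truth.feature_ids)
    cols, ids, donors, batches = [], [], [], []
    for i in range(n_samples):
        mean = truth.baseline_log2 + mixing * truth.effect
        col = mean + rng.normal(0.0, truth.sigma, size=d)
        batch = "b1" if i % 2 == 0 else "b2"
        if batch == "b2":
            col = col + truth.batch_offset
        cols.append(2.0 ** col)
        ids.append(f"bright_cd16dim_x{i + 1:02d}")
        donors.append(f"x{i + 1:02d}")
        batches.append(batch)
    extra = pd.DataFrame(np.column_stack(cols), index=truth.feature_ids,
                         columns=ids)
    data = pd.concat([matrix.data, extra], axis=1)
    meta = pd.concat([
        metadata.table,
        pd.DataFrame({"group": "bright_cd16dim", "donor": donors,
                      "batch": batches}, index=pd.Index(ids, name="sample_id")),
    ])
    return ExpressionMatrix(data, "linear"), SampleMetadata(meta)


def generate_qpcr(
    truth: SyntheticTruth,
    targets: list[str],
    n_per_group: int = 3,
    ct_baseline: float = 30.0,
    reference_ct: float = 25.0,
    replicate_sd: float = 0.15,
    n_replicates: int = 3,
    reference_name: str = "RNU6B",
    groups: tuple[str, ...] = ("bright", "dim"),
    seed: int = 2,
) -> pd.DataFrame:
    """Simulate a triplicate qPCR experiment over the planted truth.

    Each target's Ct in a dim sample is ``ct_baseline`` minus its planted
    log2 effect (more template, earlier amplification); bright samples sit at
    the baseline.  The reference gene is constant up to replicate noise.
    Returns the long-format table consumed by the ddCt functions.
    """
    unknown = [t for t in targets if t not in truth.feature_ids]
    if unknown:
        raise KeyError(f"unknown target feature(s): {', '.join(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        shift = {"bright": 0.0, "dim": 1.0, "bright_cd16dim": 0.5}[g]
        for i in range(n_per_group):
            sid = f"q_{g}_{i + 1:02d}"
            for t in targets:
                mean_ct = ct_baseline - shift * truth.effect_of(t)
                for rep in range(1, n_replicates + 1):
                    rows.append({
                        "sample_id": sid, "group": g, "target": t,
                        "replicate": rep,
                        "ct": mean_ct + rng.normal(0.0, replicate_sd),
                        "is_reference": False,
                    })
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "sample_id": sid, "group": g, "target": reference_name,
                    "replicate": rep,
                    "ct": reference_ct + rng.normal(0.0, replicate_sd),
                    "is_reference": True,
                })
    return pd.DataFrame(rows)
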