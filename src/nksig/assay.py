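"""qPCR relative quantification (ddCt) and dual-reporter normalization.

Relative expression follows the comparative-Ct method: replicate Ct values
are averaged on the Ct scale, dCt = mean Ct(target) - mean Ct(reference gene)
per sample, ddCt = dCt(sample) - dCt(calibrator), and relative quantity
RQ = 2^(-ddCt).  RNU6B serves as the reference for miRNA assays and GAPDH
for mRNA assays; the calibrator may be a single sample or a group (then its
dCt is the unweighted group mean).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .univariate import group_mean_test

__all__ = [
    "QPCR_COLUMNS",
    "read_qpcr_tsv",
    "validate_qpcr_table",
    "delta_ct",
    "delta_delta_ct",
    "reporter_relative_activity",
    "group_compare",
]

QPCR_COLUMNS = ["sample_id", "group", "target", "replicate", "ct", "is_reference"]


def read_qpcr_tsv(path) -> pd.DataFrame:
    """Read a long-format qPCR table (sample_id, group, target, replicate,
    ct, is_reference)."""
    df = pd.read_csv(path, sep="\t", dtype={"ct": float})
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    df["is_reference"] = df["is_reference"].astype(bool) if df["is_reference"].dtype != bool \
        else df["is_reference"]
    return validate_qpcr_table(df)


def validate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    bad = table[(table["ct"] <= 0) | (table["ct"] >= 45)]
    if len(bad):
        raise ValueError(
            f"Ct values outside (0, 45) for {sorted(set(bad['sample_id']))}"
        )
    refs = table[table["is_reference"]]
    for sid in table["sample_id"].unique():
        if not len(refs[refs["sample_id"] == sid]):
            raise ValueError(f"sample {sid!r} has no reference-gene Ct")
    return table


def delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, target): dCt = mean Ct(target) - mean Ct(reference).

    Replicates are averaged on the Ct scale (arithmetic mean of the
    triplicates) before the subtraction.
    """
    validate_qpcr_table(table)
    ref_mean = (table[table["is_reference"]]
                .groupby("sample_id")["ct"].mean())
    targets = table[~table["is_reference"]]
    rows = []
    for (sid, tgt), grp in targets.groupby(["sample_id", "target"], sort=True):
        rows.append({
            "sample_id": sid,
            "group": grp["group"].iloc[0],
            "target": tgt,
            "ct_target": grp["ct"].mean(),
            "ct_reference": ref_mean[sid],
            "dct": grp["ct"].mean() - ref_mean[sid],
        })
    return pd.DataFrame(rows)


def delta_delta_ct(table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative expression per sample and target against a calibrator.

    ``calibrator`` names either a sample id or a group label; for a group the
    calibrator dCt is the unweighted mean over its members (per target).
    Returns columns: sample_id, group, target, dct, ddct, rq.
    """
    dct = delta_ct(table)
    rows = []
    for tgt, sub in dct.groupby("target", sort=True):
        if calibrator in set(sub["sample_id"]):
            cal = float(sub.loc[sub["sample_id"] == calibrator, "dct"].iloc[0])
        elif calibrator in set(sub["group"]):
            cal = float(sub.loc[sub["group"] == calibrator, "dct"].mean())
        else:
            raise ValueError(
                f"calibrator {calibrator!r} is neither a sample nor a group "
                f"for target {tgt!r}"
            )
        for _, r in sub.iterrows():
            ddct = r["dct"] - cal
            rows.append({
                "sample_id": r["sample_id"], "group": r["group"],
                "target": tgt, "dct": r["dct"], "ddct": ddct,
                "rq": 2.0 ** (-ddct),
            })
    return pd.DataFrame(rows)


def negative_dct_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a qPCR table into a features x samples matrix of -dCt values.

    -dCt rises with target abundance and is on a log2-like scale, which makes
    it the natural bridge from qPCR to microarray-trained linear models.
    """
    dct = delta_ct(table)
    wide = dct.pivot(index="target", columns="sample_id", values="dct")
    if wide.isna().any().any():
        missing = [(t, s) for (t, s) in
                   zip(*np.where(wide.isna().to_numpy()))]
        raise ValueError(f"incomplete qPCR design: {len(missing)} missing cells")
    return -wide


def reporter_relative_activity(
    firefly: np.ndarray,
    renilla: np.ndarray,
    control_mask: np.ndarray,
) -> np.ndarray:
    """Dual-luciferase normalization: firefly/renilla per well, divided by the
    control-group mean ratio (so control wells average exactly 1)."""
    firefly = np.asarray(firefly, dtype=float)
    renilla = np.asarray(renilla, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if firefly.shape != renilla.shape or firefly.shape != control_mask.shape:
        raise ValueError("firefly, renilla and control_mask must align")
    if (renilla <= 0).any():
        raise ValueError("renilla values must be positive")
    if not control_mask.any():
        raise ValueError("control group is empty")
    ratio = firefly / renilla
    return ratio / ratio[control_mask].mean()


def group_compare(values_by_group: dict, design: str = "two_group_t"):
    """Group comparisons used for assay read-outs.

    design='two_group_t'      : Welch t-test between exactly two groups
    design='mann_whitney'     : two-sided Mann-Whitney between two groups
    design='anova_bonferroni' : one-way ANOVA with Bonferroni-adjusted
                                pairwise post tests over >=3 groups; returns
                                (F, p, {(name_i, name_j): p_adj})
    """
    names = list(values_by_group)
    groups = [values_by_group[n] for n in names]
    if design in ("two_group_t", "mann_whitney"):
        if len(groups) != 2:
            raise ValueError(f"{design} requires exactly two groups")
        kind = "welch_t" if design == "two_group_t" else "mann_whitney"
        return group_mean_test(*groups, kind=kind)
    if design == "anova_bonferroni":
        f_stat, p, post = group_mean_test(*groups, kind="anova_bonferroni")
        named = {(names[i], names[j]): v for (i, j), v in post.items()}
        return f_stat, p, named
    raise ValueError(f"unknown design {design!r}")
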