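"""Readers and writers for expression matrices, metadata, gene sets and signatures.

All formats are plain text: tab-separated matrices, GEO series-matrix files,
GMT gene-set collections, one-gene-per-line reference lists and long-format
target-prediction tables.  Identifiers are treated as opaque, case-preserving
strings; surrounding whitespace is stripped on input.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("bright", "dim", "bright_cd16dim")

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSetCollection",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_series_matrix",
    "read_gmt",
    "read_gene_list",
    "read_target_table",
    "write_signature_tsv",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen[x] = 1
    if dups:
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups))}")
    if len(ids) == 0:
        raise ValueError(f"empty {what} list")


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix.

    ``data`` holds intensities with miRNA names as the row index and sample
    ids as columns.  ``scale`` records whether values are raw light units
    (``linear``) or base-2 logarithms (``log2``); statistical operations
    require ``log2``.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        self.data.index = self.data.index.astype(str).str.strip()
        self.data.columns = self.data.columns.astype(str).str.strip()
        _check_unique(list(self.data.index), "feature ids")
        _check_unique(list(self.data.columns), "sample ids")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def require_log2(self) -> None:
        if self.scale != "log2":
            raise ValueError(
                "operation requires log2-scale intensities; apply "
                "preprocess.log2_transform first"
            )

    def copy_with(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(df, scale or self.scale)

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {', '.join(missing)}")
        if len(features) == 0:
            raise ValueError("empty feature list")
        return ExpressionMatrix(self.data.loc[list(features)].copy(), self.scale)


@dataclass
class SampleMetadata:
    """Per-sample annotations: phenotype group, donor and acquisition batch."""

    table: pd.DataFrame  # index: sample_id; columns: group, donor, batch

    def __post_init__(self) -> None:
        required = {"group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        self.table.index = self.table.index.astype(str).str.strip()
        _check_unique(list(self.table.index), "metadata sample ids")
        for col in ("donor", "batch"):
            if col not in self.table.columns:
                self.table[col] = "0"
        bad = set(self.table["group"].dropna()) - set(GROUPS)
        if bad:
            raise ValueError(
                f"unknown group labels {sorted(bad)}; expected one of {GROUPS}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def groups(self, samples: Sequence[str] | None = None) -> pd.Series:
        t = self.table if samples is None else self.table.loc[list(samples)]
        return t["group"]

    def align(self, matrix: ExpressionMatrix) -> "SampleMetadata":
        """Restrict and order metadata rows to the matrix's samples."""
        missing = [s for s in matrix.sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples without metadata: {', '.join(missing)}")
        return SampleMetadata(self.table.loc[matrix.sample_ids].copy())

    def two_group_labels(
        self, samples: Sequence[str], positive: str = "dim", negative: str = "bright"
    ) -> np.ndarray:
        """Encode samples as +/-1 labels; errors on samples outside the two groups."""
        g = self.table.loc[list(samples), "group"]
        bad = g[~g.isin([positive, negative])]
        if len(bad):
            raise ValueError(f"samples outside groups ({positive}, {negative}): "
                             f"{', '.join(bad.index)}")
        return np.where(g.to_numpy() == positive, 1.0, -1.0)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the reference universe used for enrichment."""

    sets: dict[str, set]
    descriptions: dict[str, str] = field(default_factory=dict)
    reference: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def with_reference(self, reference: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection(self.sets, self.descriptions, set(reference))


def read_expression_tsv(
    path: str | Path,
    orientation: str = "features",
    scale: str = "linear",
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    With ``orientation='features'`` (the default) rows are features and the
    header row carries sample ids; ``'samples'`` reads the transposed layout.
    A first-line directive ``#scale=log2`` (or ``linear``) overrides ``scale``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#scale="):
            scale = first.strip().split("=", 1)[1]
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0, dtype=str)
    # locale-independent numeric parsing with coordinates on failure
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {raw!r} at feature {df.index[i]!r}, "
                    f"sample {col!r} in {path}"
                ) from None
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    if orientation == "samples":
        out = out.T
    elif orientation != "features":
        raise ValueError("orientation must be 'features' or 'samples'")
    return ExpressionMatrix(out, scale)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix with a ``#scale=`` directive; 6 significant digits."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep="\t", float_format="%.6g", index_label="feature")


def read_metadata_tsv(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError("metadata file must have a 'sample_id' column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata_tsv(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(path, sep="\t", index_label="sample_id")


def read_series_matrix(path: str | Path) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Read a GEO series-matrix file (metadata lines prefixed '!', data table
    between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``).

    Sample characteristics are scanned best-effort for group and batch labels
    (``CD56bright``/``CD56dim`` and ``batch: <id>`` patterns); anything
    unparsed is kept verbatim in a ``characteristics`` column.  An explicit
    metadata file always wins over what this reader infers.
    """
    path = Path(path)
    titles: list[str] = []
    accessions: list[str] = []
    characteristics: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_title"):
                titles = _split_quoted(line)[1:]
            elif line.startswith("!Sample_geo_accession"):
                accessions = _split_quoted(line)[1:]
            elif line.startswith("!Sample_characteristics_ch1"):
                characteristics.append(_split_quoted(line)[1:])
    if not (saw_begin and saw_end):
        raise ValueError(
            f"{path}: missing series_matrix_table_begin/end delimiters"
        )
    df = pd.read_csv(_io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    matrix = ExpressionMatrix(df.astype(float), "log2")

    n = matrix.n_samples
    rows = []
    for i, sid in enumerate(matrix.sample_ids):
        texts = [titles[i] if i < len(titles) else ""]
        texts += [c[i] for c in characteristics if i < len(c)]
        joined = "; ".join(t for t in texts if t)
        group = _infer_group(joined)
        batch = _infer_batch(joined)
        rows.append({"sample_id": sid, "group": group, "donor": None,
                     "batch": batch, "characteristics": joined})
    meta = pd.DataFrame(rows).set_index("sample_id")
    # bypass group vocabulary check for unset groups: keep None as-is
    md = SampleMetadata.__new__(SampleMetadata)
    md.table = meta
    if meta["group"].notna().all():
        md = SampleMetadata(meta)
    return matrix, md


def _split_quoted(line: str) -> list[str]:
    return [f.strip().strip('"') for f in line.split("\t")]


def _infer_group(text: str):
    t = text.lower().replace(" ", "")
    if "cd56bright" in t and ("cd16dim" in t or "cd16+" in t):
        return "bright_cd16dim"
    if "cd56bright" in t:
        return "bright"
    if "cd56dim" in t:
        return "dim"
    return None


def _infer_batch(text: str):
    t = text.lower()
    if "batch:" in t:
        after = t.split("batch:", 1)[1].strip()
        return after.split(";")[0].strip().split()[0] if after else "0"
    return "0"


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def read_gene_list(path: str | Path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def read_target_table(path: str | Path, tool: str | None = None) -> pd.DataFrame:
    """Read a miRNA -> gene prediction table (columns mirna, gene[, tool])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "mirna" not in cols or "gene" not in cols:
        raise ValueError(f"{path}: need 'mirna' and 'gene' columns")
    out = pd.DataFrame({
        "mirna": df[cols["mirna"]].str.strip(),
        "gene": df[cols["gene"]].str.strip(),
    })
    if "tool" in cols:
        out["tool"] = df[cols["tool"]].str.strip()
    elif tool is not None:
        out["tool"] = tool
    else:
        raise ValueError(f"{path}: no 'tool' column and no tool name given")
    return out.drop_duplicates(ignore_index=True)


SIGNATURE_COLUMNS = [
    "feature", "median_log2_bright", "median_log2_dim", "delta_log2",
    "fold_change", "p", "p_adj", "status",
]


def write_signature_tsv(results, path: str | Path) -> None:
    """Write differential-expression rows ordered by (p_adj, feature)."""
    rows = []
    for r in results:
        rows.append({
            "feature": r.feature,
            "median_log2_bright": r.median_bright,
            "median_log2_dim": r.median_dim,
            "delta_log2": r.delta,
            "fold_change": r.fold_change,
            "p": r.p_raw,
            "p_adj": r.p_adj,
            "status": r.status,
        })
    df = pd.DataFrame(rows, columns=SIGNATURE_COLUMNS)
    if len(df):
        df = df.sort_values(["p_adj", "feature"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
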