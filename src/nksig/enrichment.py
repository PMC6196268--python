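"""Over-representation analysis of signature target genes in pathway sets.

Given a gene signature (the predicted targets of the selected miRNAs), a
collection of pathway gene sets and a reference universe, each pathway is
tested with the upper-tail hypergeometric distribution: with N reference
genes, K of them in the pathway and n signature genes, the p-value is
P[X >= k] for the observed overlap k.  Only pathways with at least
``min_genes`` overlapping genes are tested; Bonferroni correction runs over
the tested pathways.  The enrichment ratio (k/n)/(K/N) exceeds 1 exactly
when the signature's pathway fraction beats the reference's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "aggregate_targets",
    "shared_specific_partition",
    "enrichment_table",
]


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: set
    k: int            # |signature ∩ set ∩ reference|
    K: int            # |set ∩ reference|
    n: int            # |signature ∩ reference|
    N: int            # |reference|
    ratio: float      # (k/n) / (K/N)
    p_raw: float
    p_adj: float
    significant: bool

    @property
    def score(self) -> float:
        """-log10 adjusted p; the pathway-ranking score."""
        return float(-np.log10(max(self.p_adj, 1e-300)))


def hypergeometric_enrichment(
    signature_genes,
    collection: GeneSetCollection,
    min_genes: int = 3,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation with Bonferroni control.

    Signature and pathway members are intersected with the reference universe
    before counting; pathways overlapping the signature in fewer than
    ``min_genes`` genes are excluded from testing and from the correction
    factor m.  Results are ordered by (p_adj, set name).
    """
    reference = set(collection.reference)
    if not reference:
        raise ValueError("empty reference universe")
    signature = set(signature_genes)
    outside = signature - reference
    if outside:
        warnings.warn(
            f"{len(outside)} signature gene(s) outside the reference are ignored"
        )
    sig = signature & reference
    if not sig:
        raise ValueError("signature has no genes in the reference universe")
    N, n = len(reference), len(sig)

    tested = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & reference
        overlap = sig & members
        if len(overlap) < min_genes:
            continue
        k, K = len(overlap), len(members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        ratio = (k / n) / (K / N)
        tested.append((name, overlap, k, K, p, ratio))

    m = len(tested)
    results = []
    for name, overlap, k, K, p, ratio in tested:
        p_adj = min(1.0, m * p)
        results.append(EnrichmentResult(
            set_name=name, overlap=overlap, k=k, K=K, n=n, N=N,
            ratio=ratio, p_raw=p, p_adj=p_adj,
            significant=p_adj <= alpha,
        ))
    results.sort(key=lambda r: (r.p_adj, r.set_name))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "set": r.set_name, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "ratio": r.ratio, "p_raw": r.p_raw, "p_adj": r.p_adj,
            "score": r.score, "significant": r.significant,
            "overlap": ";".join(sorted(r.overlap)),
        }
        for r in results
    ])


def aggregate_targets(
    tables: list[pd.DataFrame],
    min_support: int = 1,
) -> pd.DataFrame:
    """Union of per-tool miRNA->gene predictions with supporting-tool counts.

    Each table needs columns (mirna, gene, tool).  Rows are deduplicated per
    (mirna, gene, tool); ``n_tools`` counts distinct supporting tools and
    pairs below ``min_support`` are dropped.
    """
    if not tables:
        raise ValueError("need at least one prediction table")
    cat = pd.concat(tables, ignore_index=True)
    missing = {"mirna", "gene", "tool"} - set(cat.columns)
    if missing:
        raise ValueError(f"prediction tables missing columns: {sorted(missing)}")
    cat = cat.drop_duplicates(["mirna", "gene", "tool"])
    counts = (cat.groupby(["mirna", "gene"])["tool"]
              .nunique().reset_index(name="n_tools"))
    out = counts[counts["n_tools"] >= min_support].reset_index(drop=True)
    return out.sort_values(["mirna", "gene"], ignore_index=True)


def targets_for(aggregated: pd.DataFrame, mirnas) -> set:
    """Gene signature: union of predicted targets of the given miRNAs."""
    wanted = set(mirnas)
    return set(aggregated.loc[aggregated["mirna"].isin(wanted), "gene"])


def target_pivot(
    aggregated: pd.DataFrame,
    up_mirnas,
    down_mirnas,
) -> pd.DataFrame:
    """Gene-by-direction table: for each target gene, the miRNAs predicted to
    regulate it, split by the direction of miRNA regulation (up in dim vs up
    in bright)."""
    up, down = set(up_mirnas), set(down_mirnas)
    rows = {}
    for _, r in aggregated.iterrows():
        g = r["gene"]
        rows.setdefault(g, {"up": [], "down": []})
        if r["mirna"] in up:
            rows[g]["up"].append(r["mirna"])
        if r["mirna"] in down:
            rows[g]["down"].append(r["mirna"])
    out = pd.DataFrame([
        {"gene": g,
         "mirnas_up": "-".join(sorted(v["up"])),
         "mirnas_down": "-".join(sorted(v["down"]))}
        for g, v in rows.items()
        if v["up"] or v["down"]
    ])
    return out.sort_values("gene", ignore_index=True) if len(out) else out


def shared_specific_partition(
    results_a: list[EnrichmentResult],
    results_b: list[EnrichmentResult],
    alpha: float = 0.05,
) -> tuple[set, set, set]:
    """Partition significant pathways from two runs on the same collection
    into (shared, specific to a, specific to b)."""
    names_a = {r.set_name for r in results_a}
    names_b = {r.set_name for r in results_b}
    sig_a = {r.set_name for r in results_a if r.p_adj <= alpha}
    sig_b = {r.set_name for r in results_b if r.p_adj <= alpha}
    # same-collection check: tested universes must agree where sets coincide
    for r in results_a:
        if r.set_name in names_b:
            rb = next(x for x in results_b if x.set_name == r.set_name)
            if rb.K != r.K or rb.N != r.N:
                raise ValueError(
                    f"set {r.set_name!r} differs between runs; the two result "
                    "lists come from different collections"
                )
    return sig_a & sig_b, sig_a - sig_b, sig_b - sig_a
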