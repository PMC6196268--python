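"""End-to-end orchestration: detection -> univariate -> multivariate ->
validation -> (optional) enrichment, with a machine-readable run log."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .enrichment import enrichment_table, hypergeometric_enrichment
from .io import (ExpressionMatrix, SampleMetadata, read_expression_tsv,
                 read_gene_list, read_gmt, read_metadata_tsv,
                 write_expression_tsv, write_signature_tsv)
from .preprocess import detection_call, preprocess_chain
from .selection import nested_cv_select
from .univariate import differential_expression
from .validation import validate_signature

logger = logging.getLogger("nksig")

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Every numeric decision of the pipeline, JSON round-trippable."""

    expression_path: str = ""
    metadata_path: str = ""
    gmt_path: str = ""
    reference_path: str = ""
    out_dir: str = "nksig_run"
    seed: int = 0
    # preprocessing
    floor: float = 1.0
    adjust_batch: bool = True
    center: bool = False
    input_scale: str = "linear"
    # detection
    detection_threshold: float = 1.0
    detection_fraction: float = 0.5
    # univariate
    alpha: float = 0.05
    fc_min: float = 2.0
    test: str = "welch_t"
    adjust: str = "bh"
    # selection
    B: int = 5
    test_fraction: float = 0.25
    inner_folds: int = 4
    phi: float = 0.5
    pair_by_donor: bool = False
    # validation
    validation_mu: float = 0.1
    R_true: int = 100
    R_perm: int = 100
    # enrichment
    min_genes: int = 3
    enrichment_alpha: float = 0.05

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - named-stage abort contract
                raise PipelineError(name, e) from e
        return wrapper
    return deco


def run_all(
    config: RunConfig,
    matrix: ExpressionMatrix | None = None,
    metadata: SampleMetadata | None = None,
) -> Path:
    """Run the whole pipeline and write its outputs under ``config.out_dir``.

    Inputs may be passed in memory (``matrix``/``metadata``) or read from the
    configured paths.  Outputs: preprocessed matrix, detection summary, DE
    table, selection run, validation report, optional enrichment table, and
    ``run_log.json`` recording seeds, versions and parameters.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    substreams = {name: int(rng.integers(2**31 - 1))
                  for name in ("selection", "validation")}

    @_stage("load")
    def load():
        m = matrix if matrix is not None else read_expression_tsv(
            config.expression_path, scale=config.input_scale)
        md = metadata if metadata is not None else read_metadata_tsv(
            config.metadata_path)
        return m, md.align(m)

    m, md = load()

    @_stage("preprocess")
    def prep():
        if m.scale == "linear":
            return preprocess_chain(m, md, floor=config.floor,
                                    adjust_batch=config.adjust_batch,
                                    center=config.center)
        return m

    normalized = prep()
    write_expression_tsv(normalized, out / "normalized_log2.tsv")

    @_stage("detection")
    def detect():
        summary = detection_call(normalized, md,
                                 threshold=config.detection_threshold,
                                 fraction=config.detection_fraction)
        (out / "detection_summary.json").write_text(
            json.dumps(summary.counts, indent=1))
        return summary

    detection = detect()

    @_stage("univariate")
    def univariate():
        results = differential_expression(
            normalized, md, alpha=config.alpha, fc_min=config.fc_min,
            test=config.test, adjust=config.adjust,
            detection_threshold=config.detection_threshold,
            detection_fraction=config.detection_fraction)
        write_signature_tsv(results, out / "differential_expression.tsv")
        return results

    de_results = univariate()
    de_signature = [r.feature for r in de_results if r.status != "unchanged"]

    @_stage("selection")
    def select():
        run = nested_cv_select(
            normalized, md, B=config.B, test_fraction=config.test_fraction,
            inner_folds=config.inner_folds, phi=config.phi,
            seed=substreams["selection"], pair_by_donor=config.pair_by_donor)
        run.to_json(out / "selection_run.json")
        return run

    sel = select()

    @_stage("validation")
    def validate():
        features = sel.signature or de_signature
        if not features:
            raise ValueError("no signature features to validate")
        report = validate_signature(
            normalized, md, features, mu=config.validation_mu,
            R_true=config.R_true, R_perm=config.R_perm,
            test_fraction=config.test_fraction,
            seed=substreams["validation"])
        report.to_json(out / "validation_report.json")
        return report

    report = validate()

    enrichment_done = False
    if config.gmt_path and config.reference_path:
        @_stage("enrichment")
        def enrich():
            collection = read_gmt(config.gmt_path).with_reference(
                read_gene_list(config.reference_path))
            results = hypergeometric_enrichment(
                sel.signature or de_signature, collection,
                min_genes=config.min_genes, alpha=config.enrichment_alpha)
            enrichment_table(results).to_csv(
                out / "enrichment.tsv", sep="\t", index=False)
            return results

        enrich()
        enrichment_done = True

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "substreams": substreams,
        "config": asdict(config),
        "detection_counts": detection.counts,
        "n_differential": len(de_signature),
        "selection_signature_size": len(sel.signature),
        "selection_mean_accuracy": sel.mean_accuracy,
        "validation_mean_accuracy": report.mean_accuracy,
        "validation_ks_pvalue": report.ks_pvalue,
        "enrichment": enrichment_done,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    logger.info("run complete: %s", out)
    return out


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
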