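"""End-to-end orchestration: reads -> variant table -> classes -> reports.

The pipeline chains the preprocessing stages and the classifier, keeps a
conservation ledger (every read pair is either merged or attributed to a
rejection; every variant removal is attributed to exactly one criterion)
and writes machine-readable outputs plus a JSON run-metadata record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import classify as _classify
from .errors import ConfigError, IgsflowError
from .preprocess import (
    FilterReport,
    MergeParams,
    VariantTable,
    dereplicate,
    filter_variants,
    merge_sample,
    remove_chimeras,
)
from .seqio import SampleManifest, load_manifest, read_fastq_pairs

logger = logging.getLogger("igsflow")


@dataclass
class RunConfig:
    """Thresholds and paths of one pipeline run."""

    manifest_path: str
    reads_dir: str
    out_dir: str
    roles_path: str | None = None
    min_abundance: int = 5
    min_length: int | None = None
    tau: float = _classify.DEFAULT_TAU
    dq_threshold: int = 6
    min_overlap: int = 20
    chimera_skew: float = 2.0
    chimera_min_improvement: int = 3

    def __post_init__(self) -> None:
        if self.min_abundance < 0:
            raise ConfigError("min_abundance must be >= 0")
        if self.min_length is not None and self.min_length <= 0:
            raise ConfigError("min_length must be positive")
        if not 0 < self.tau <= 1:
            raise ConfigError("tau must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class RunResult:
    table: VariantTable
    labels: list
    compositions: list
    metadata: dict


def preprocess_reads(
    manifest: SampleManifest,
    reads_dir: str | Path,
    params: MergeParams,
    metadata: dict,
) -> Mapping[str, list[str]]:
    reads_dir = Path(reads_dir)
    contigs: dict[str, list[str]] = {}
    per_sample_counts = {}
    for sample in manifest.sample_ids:
        r1 = reads_dir / f"{sample}_R1.fastq"
        r2 = reads_dir / f"{sample}_R2.fastq"
        if not r1.exists() or not r2.exists():
            raise IgsflowError(f"missing FASTQ pair for sample {sample!r}")
        pairs = read_fastq_pairs(r1, r2)
        merged, stats = merge_sample(pairs, params)
        contigs[sample] = merged
        per_sample_counts[sample] = {
            "pairs": stats.n_pairs,
            "merged": stats.n_merged,
            "rejected": stats.n_rejected,
        }
        logger.info(
            "sample %s: %d pairs, %d merged, %d rejected",
            sample,
            stats.n_pairs,
            stats.n_merged,
            stats.n_rejected,
        )
    metadata["merge"] = per_sample_counts
    return contigs


def run_pipeline(config: RunConfig) -> RunResult:
    """Run preprocess -> chimera removal -> filters -> classification."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    metadata: dict = {
        "thresholds": {
            "min_abundance": config.min_abundance,
            "min_length": config.min_length,
            "tau": config.tau,
            "dq_threshold": config.dq_threshold,
            "min_overlap": config.min_overlap,
            "chimera_skew": config.chimera_skew,
            "chimera_min_improvement": config.chimera_min_improvement,
        }
    }
    try:
        manifest = load_manifest(config.manifest_path, roles=config.roles_path)
        params = MergeParams(
            dq_threshold=config.dq_threshold, min_overlap=config.min_overlap
        )

        stage = "preprocess"
        contigs = preprocess_reads(manifest, config.reads_dir, params, metadata)

        stage = "dereplicate"
        table = dereplicate(contigs)
        metadata["dereplicate"] = {"n_variants": table.n_variants}
        logger.info("dereplicated to %d unique variants", table.n_variants)

        stage = "chimera"
        table, hits = remove_chimeras(
            table,
            skew=config.chimera_skew,
            min_improvement=config.chimera_min_improvement,
        )
        metadata["chimera"] = {"n_flagged": len(hits)}
        logger.info("flagged %d chimeric variants", len(hits))

        stage = "filter"
        table, report = filter_variants(
            table,
            min_total_abundance=config.min_abundance,
            min_length=config.min_length,
        )
        metadata["filter"] = {
            "n_input": report.n_input,
            "removed_by_abundance": report.removed_by_abundance,
            "removed_by_length": report.removed_by_length,
            "n_kept": report.n_kept,
        }
        logger.info(
            "filter: %d in, %d removed by abundance, %d by length, %d kept",
            report.n_input,
            report.removed_by_abundance,
            report.removed_by_length,
            report.n_kept,
        )

        stage = "classify"
        labels = _classify.assign_all(table, manifest, tau=config.tau)
        compositions = _classify.compose(table, labels, manifest)

        stage = "write"
        table.write_tsv(out / "table.tsv")
        table.write_fasta(out / "variants.fasta")
        _classify.write_labels_tsv(table, labels, out / "labels.tsv")
        _classify.composition_frame(compositions).to_csv(
            out / "compositions.tsv", sep="\t"
        )
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
    except Exception as exc:
        with open(out / "run_metadata.json", "w") as fh:
            json.dump({**metadata, "failed_stage": stage, "error": str(exc)}, fh, indent=2)
        raise IgsflowError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return RunResult(
        table=table, labels=labels, compositions=compositions, metadata=metadata
    )
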