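"""Thin orchestration: run analysis stages from a flat configuration and
write reproducible report bundles.

Every numeric artifact is accompanied by provenance metadata (inputs,
seeds, thresholds, package version), and re-running an identical
configuration byte-reproduces every CSV/JSON artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .benchstats import embed_tsne, region_report, subthreshold_count
from .clustering import cluster_census, greedy_cluster, vj_coherence
from .geometry import pairwise_distance_matrix
from .io import apply_gene_table, read_gene_table, read_structure
from .model import StructureError, extract_region
from .seqmetrics import SequenceRecord, identity_threshold_scan
from .synthetic import GeneratorConfig, generate_repertoire, write_repertoire

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Flat run configuration; CLI flags override file values."""

    stages: list[str] = field(default_factory=list)
    outdir: str = "tcrloops_out"
    seed: int = 0
    # structure inputs
    input_dir: Optional[str] = None
    pred_dir: Optional[str] = None
    ref_dir: Optional[str] = None
    gene_table: Optional[str] = None
    chain_map: dict[str, str] = field(default_factory=lambda: {"A": "alpha", "B": "beta"})
    # analysis parameters
    chain: str = "alpha"
    region: str = "CDR3"
    tau: float = 1.0
    min_group: int = 5
    subthreshold: float = 2.0
    identity_thresholds: list[float] = field(default_factory=lambda: [0.5, 0.6, 0.7, 0.8, 0.9])
    perplexity: float = 10.0
    # synthetic stage
    n_records: int = 100

    def __post_init__(self) -> None:
        for name, value in (("tau", self.tau), ("subthreshold", self.subthreshold)):
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        for s in self.identity_thresholds:
            if not 0 < s <= 1:
                raise ConfigError(f"identity threshold {s} outside (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _provenance(config: RunConfig, stage: str, **extra) -> dict:
    return {
        "stage": stage,
        "package_version": __version__,
        "seed": config.seed,
        "tau": config.tau,
        "subthreshold": config.subthreshold,
        **extra,
    }


def _load_records(config: RunConfig, directory: str) -> list:
    paths = sorted(Path(directory).glob("*.pdb"))
    if not paths:
        raise StructureError(f"no PDB files in {directory}")
    records = [read_structure(p, config.chain_map) for p in paths]
    gene_table = config.gene_table
    if gene_table is None and (Path(directory) / "genes.csv").exists():
        gene_table = str(Path(directory) / "genes.csv")  # repertoire sidecar
    if gene_table:
        apply_gene_table(records, read_gene_table(gene_table))
    return records


def _stage_synth(config: RunConfig, outdir: Path) -> None:
    gen = GeneratorConfig(n_records=config.n_records, seed=config.seed)
    records, truth = generate_repertoire(gen)
    write_repertoire(records, truth, outdir / "synthetic")


def _stage_cluster(config: RunConfig, outdir: Path) -> None:
    if not config.input_dir:
        raise ConfigError("cluster stage needs input_dir")
    records = _load_records(config, config.input_dir)
    loops = [extract_region(r, config.chain, config.region) for r in records]
    matrix = pairwise_distance_matrix(loops, ids=[r.record_id for r in records])
    logger.info("clustering %d loops in id order (lexicographic)", len(loops))
    assignment = greedy_cluster(matrix, config.tau)
    census = cluster_census(assignment)
    rows = []
    labels = assignment.labels()
    reps = set(assignment.representatives())
    for idx, rid in enumerate(matrix.ids):
        rows.append((rid, int(labels[idx]), idx in reps))
    pd.DataFrame(rows, columns=["id", "cluster_index", "is_representative"]).to_csv(
        outdir / "clusters.csv", index=False
    )
    payload = {
        "census": census.to_dict(),
        "provenance": _provenance(config, "cluster", chain=config.chain,
                                  region=config.region, input_dir=config.input_dir),
    }
    (outdir / "census.json").write_text(json.dumps(payload, indent=1))


def _stage_vj_coherence(config: RunConfig, outdir: Path) -> None:
    if not config.input_dir:
        raise ConfigError("vj-coherence stage needs input_dir")
    records = _load_records(config, config.input_dir)
    loops = [extract_region(r, config.chain, "CDR3") for r in records]
    report = vj_coherence(loops, tau=config.subthreshold, min_group=config.min_group)
    payload = {
        **report.to_dict(),
        "provenance": _provenance(config, "vj_coherence", chain=config.chain,
                                  input_dir=config.input_dir),
    }
    (outdir / "vj_coherence.json").write_text(json.dumps(payload, indent=1))


def _stage_seq_scan(config: RunConfig, outdir: Path) -> None:
    if not config.input_dir:
        raise ConfigError("seq-scan stage needs input_dir")
    records = _load_records(config, config.input_dir)
    seqs = [
        SequenceRecord(r.record_id, f"{config.region}{config.chain}",
                       extract_region(r, config.chain, config.region).sequence)
        for r in records
    ]
    counts = identity_threshold_scan(seqs, config.identity_thresholds)
    payload = {
        "cluster_counts": {str(k): v for k, v in counts.items()},
        "provenance": _provenance(config, "seq_scan", chain=config.chain,
                                  region=config.region,
                                  thresholds=config.identity_thresholds),
    }
    (outdir / "seq_scan.json").write_text(json.dumps(payload, indent=1))


def _stage_benchmark(config: RunConfig, outdir: Path) -> None:
    if not config.pred_dir or not config.ref_dir:
        raise ConfigError("benchmark stage needs pred_dir and ref_dir")
    predictions = _load_records(config, config.pred_dir)
    references = _load_records(config, config.ref_dir)
    report = region_report(predictions, references, model_name=Path(config.pred_dir).name)
    report.table.to_csv(outdir / "region_rmsd.csv", float_format="%.6g")
    summary = report.summary()
    summary.to_csv(outdir / "region_summary.csv", float_format="%.6g")
    fractions = {}
    for region in report.table.columns:
        count, fraction = subthreshold_count(report, region, config.subthreshold)
        fractions[region] = {"count": count, "fraction": fraction}
    payload = {
        "model": report.model_name,
        "n_missing_cells": report.n_missing(),
        "subthreshold": fractions,
        "provenance": _provenance(config, "benchmark", pred_dir=config.pred_dir,
                                  ref_dir=config.ref_dir),
    }
    (outdir / "benchmark.json").write_text(json.dumps(payload, indent=1))


def _stage_embed(config: RunConfig, outdir: Path) -> None:
    if not config.input_dir:
        raise ConfigError("embed stage needs input_dir")
    records = _load_records(config, config.input_dir)
    loops = [extract_region(r, config.chain, config.region) for r in records]
    matrix = pairwise_distance_matrix(loops, ids=[r.record_id for r in records])
    assignment = greedy_cluster(matrix, config.tau)
    coords = embed_tsne(matrix, perplexity=config.perplexity, seed=config.seed,
                        labels=assignment.labels())
    coords.to_csv(outdir / "tsne.csv", float_format="%.6g")


_STAGES = {
    "synth": _stage_synth,
    "cluster": _stage_cluster,
    "vj-coherence": _stage_vj_coherence,
    "seq-scan": _stage_seq_scan,
    "benchmark": _stage_benchmark,
    "embed": _stage_embed,
}


def run_pipeline(config: RunConfig) -> list[tuple[str, str]]:
    """Run the configured stages in order; returns (stage, error) failures.

    Completed stages keep their artifacts; failures are written to a
    manifest in the output directory.
    """
    unknown = [s for s in config.stages if s not in _STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; known: {sorted(_STAGES)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failures: list[tuple[str, str]] = []
    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            _STAGES[stage](config, outdir)
        except (StructureError, ConfigError, OSError) as exc:
            logger.error("stage %s failed: %s", stage, exc)
            failures.append((stage, str(exc)))
    if failures:
        (outdir / "failures.json").write_text(
            json.dumps([{"stage": s, "error": e} for s, e in failures], indent=1)
        )
    return failures
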