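"""End-to-end orchestration: search/parse -> outliers -> partitions -> assignment.

``run_pipeline`` wires the stages together from a :class:`PipelineConfig`,
writes the assignment and partition tables plus a JSON run manifest
(parameter values, seed, input checksums, stage counts) and logs the stage
statistics at INFO level. Either a precomputed hit table or a runnable
external search configuration must be present; rerunning from the
persisted hit table reproduces byte-identical downstream outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import subprocess
from dataclasses import asdict, dataclass
from pathlib import Path

from atlastax.estimator import AtlasPartitioner
from atlastax.io_formats import (
    BLAST_FIELDS,
    parse_blast_tabular,
    read_fasta,
    read_taxonomy_map,
    write_outputs,
)

logger = logging.getLogger("atlastax")

OUTFMT = "6 " + " ".join(BLAST_FIELDS)


@dataclass
class PipelineConfig:
    """Everything one run needs; flat so it maps 1:1 onto CLI flags."""

    queries: str
    reference: str
    taxonomy: str
    hit_table: str | None = None  # precomputed search results
    blast_bin: str = "blastn"
    blast_task: str = "megablast"  # search algorithm when driving BLAST
    alpha: float = 0.5
    background: tuple[float, float, float, float] | None = None
    min_gain: float = 20.0
    max_hits: int = 100
    edge_sd_multiplier: float = 2.0
    resolution: float = 1.0
    assignment_threshold: float = 0.5
    seed: int = 42
    out_prefix: str = "atlas_out"

    def __post_init__(self) -> None:
        if self.hit_table is None and not self.blast_bin:
            raise ValueError("need either a hit table or a search configuration")


def run_blast_search(config: PipelineConfig, out_path: str | Path) -> Path:
    """Drive an external blastn search producing the 14-field table."""
    if shutil.which(config.blast_bin) is None:
        raise FileNotFoundError(f"search binary {config.blast_bin!r} not on PATH")
    cmd = [
        config.blast_bin,
        "-task", config.blast_task,
        "-query", config.queries,
        "-subject", config.reference,
        "-outfmt", OUTFMT,
        "-max_target_seqs", str(config.max_hits),
        "-out", str(out_path),
    ]
    logger.info("running search: %s", " ".join(cmd))
    subprocess.run(cmd, check=True)
    return Path(out_path)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig):
    """Execute every stage and write outputs plus a run manifest.

    Returns ``(assignments, partition_set, summaries)``. A zero-query
    input completes with empty outputs and a warning.
    """
    queries = read_fasta(config.queries)
    taxonomy = read_taxonomy_map(config.taxonomy)
    if config.hit_table is not None:
        hit_path = Path(config.hit_table)
    else:
        hit_path = Path(config.out_prefix + ".hits.tsv")
        run_blast_search(config, hit_path)
    hits = parse_blast_tabular(hit_path)
    if not queries:
        logger.warning("no query sequences; writing empty outputs")

    est = AtlasPartitioner(
        alpha=config.alpha,
        background=config.background,
        min_gain=config.min_gain,
        max_hits=config.max_hits,
        edge_sd_multiplier=config.edge_sd_multiplier,
        resolution=config.resolution,
        assignment_threshold=config.assignment_threshold,
        random_state=config.seed,
    )
    est.fit(queries, hits, taxonomy=taxonomy)
    by_query = {a.query_id: a for a in est.predict()}
    assignments = [by_query[q.id] for q in queries]  # input order

    n_outliers = sum(1 for o in est.outlier_sets_.values() if o)
    n_assigned = sum(1 for a in assignments if a.assigned)
    n_singleton = est.partitions_.n_singletons
    stats = {
        "n_queries": len(queries),
        "n_queries_with_outliers": n_outliers,
        "n_graph_nodes": est.graph_.number_of_nodes(),
        "n_graph_edges_prefilter": est.graph_.number_of_edges(),
        "n_graph_edges_postfilter": est.filtered_graph_.number_of_edges(),
        "edge_weight_threshold": est.edge_threshold_,
        "n_partitions": len(est.partitions_),
        "n_singleton_partitions": n_singleton,
        "n_nonsingleton_partitions": len(est.partitions_) - n_singleton,
        "n_assigned": n_assigned,
        "n_unclassified": len(queries) - n_assigned,
    }
    for key, val in stats.items():
        logger.info("%s: %s", key, val)

    write_outputs(assignments, est.summaries_, config.out_prefix)
    manifest = {
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "out_prefix"
        },
        "seed": config.seed,
        "inputs": {
            "queries": _sha256(config.queries),
            "taxonomy": _sha256(config.taxonomy),
            "reference": _sha256(config.reference),
            "hit_table": _sha256(hit_path),
        },
        "stats": stats,
    }
    with open(config.out_prefix + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return assignments, est.partitions_, est.summaries_
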