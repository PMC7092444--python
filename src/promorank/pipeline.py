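"""End-to-end orchestration: rank -> annotate -> filter -> select -> report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from ._errors import ConfigError
from .annotation import compute_upstream_distance, read_gene_features
from .expression import read_collection
from .prioritize import (MAX_RANK_DEFAULT, MIN_UTR_DEFAULT, TARGET_LENGTH_DEFAULT,
                         TOP_N_DEFAULT, apply_filters, attach_promoters,
                         select_top, write_report)
from .ranking import aggregate_ranks, write_rank_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; thresholds default to the
    published study constants (max rank 1000, minimum 5'-UTR 950 bp, top 6
    genes, 1024 bp promoter target)."""

    matrix_paths: list[str] = field(default_factory=list)
    manifest_path: str = ""
    gff3_path: str = ""
    fasta_path: str = ""
    out_dir: str = "promorank_out"
    max_rank: int = MAX_RANK_DEFAULT
    min_utr: int = MIN_UTR_DEFAULT
    top_n: int = TOP_N_DEFAULT
    target_length: int = TARGET_LENGTH_DEFAULT
    target_overrides: dict[str, int] = field(default_factory=dict)
    universe_policy: str = "require-identical"
    replicate_policy: str = "average"
    missing_policy: str = "strict"
    feature_type: str = "gene"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_rank", "min_utr", "top_n", "target_length"):
            if getattr(self, name) < 0 or (name in ("max_rank", "top_n")
                                           and getattr(self, name) == 0):
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full prioritization pipeline and write every artifact.

    Stages: read expression collection; aggregate ranks; parse the gene
    annotation; compute upstream distances; filter, select and attach
    promoter windows; write the rank table, candidate report, promoter
    BED/FASTA and a JSON manifest with sha256 checksums of all outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage=read_expression matrices=%d", len(config.matrix_paths))
    collection = read_collection(
        config.matrix_paths, config.manifest_path,
        universe_policy=config.universe_policy,
        replicate_policy=config.replicate_policy,
        missing_policy=config.missing_policy,
    )
    logger.info("stage=read_expression datasets=%d genes=%d",
                len(collection), len(collection.gene_universe))

    profiles = aggregate_ranks(collection)
    rank_path = out / "rank_table.tsv"
    write_rank_table(profiles, rank_path, collection.dataset_ids)
    logger.info("stage=aggregate_ranks profiles=%d", len(profiles))

    features, contig_lengths = read_gene_features(
        config.gff3_path, feature_type=config.feature_type,
        fasta_path=config.fasta_path or None,
    )
    utrs = compute_upstream_distance(features, contig_lengths)
    logger.info("stage=annotation features=%d", len(features))

    candidates = apply_filters(profiles, utrs,
                               max_rank_threshold=config.max_rank,
                               min_utr=config.min_utr)
    selected = select_top(candidates, config.top_n)
    attach_promoters(
        selected, {f.gene_id: f for f in features}, utrs,
        target_length=config.target_length,
        target_overrides=config.target_overrides,
    )
    logger.info("stage=selection genes=%d passing=%d selected=%d",
                len(candidates), sum(c.passes for c in candidates), len(selected))

    summary = {
        "n_datasets": len(collection),
        "n_genes": len(collection.gene_universe),
        "max_rank": config.max_rank,
        "min_utr": config.min_utr,
        "top_n": config.top_n,
        "target_length": config.target_length,
        "seed": config.seed,
    }
    paths = write_report(candidates, out, fasta_path=config.fasta_path or None,
                         run_summary=summary)
    paths["rank_table"] = rank_path

    manifest = {
        name: {"path": str(p), "sha256": _sha256(Path(p))}
        for name, p in sorted(paths.items())
    }
    manifest_path = out / "artifact_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
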