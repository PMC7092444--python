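"""Exclusion filters, top-n selection and the candidate report.

A gene qualifies as a promoter candidate when (a) its worst (maximum) rank
across all datasets is no greater than ``max_rank_threshold`` — it is highly
expressed even in its least favorable dataset — and (b) its upstream
intergenic space is at least ``min_utr`` bp, leaving room for a regulatory
region.  Both boundaries are inclusive: a maximum rank of exactly 1000 and a
5'-UTR of exactly 950 bp pass the default filters; only strictly worse
values are excluded.  The first ``n`` passing candidates in median-rank
order are selected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._errors import ConfigError
from .annotation import (GeneFeature, PromoterWindow, UtrRecord,
                         promoter_window, write_bed6, write_promoter_fasta)
from .ranking import RankProfile

logger = logging.getLogger(__name__)

MAX_RANK_DEFAULT = 1000
MIN_UTR_DEFAULT = 950
TOP_N_DEFAULT = 6
TARGET_LENGTH_DEFAULT = 1024


@dataclass
class PromoterCandidate:
    """A gene with its rank summary, UTR length, filter flags and promoter."""

    gene_id: str
    min_rank: int
    max_rank: int
    median_rank: float
    utr_length: int | None          # None: gene missing from the annotation
    passes_max_rank: bool
    passes_utr: bool
    selected: bool = False
    promoter: PromoterWindow | None = None

    @property
    def passes(self) -> bool:
        return self.passes_max_rank and self.passes_utr


def apply_filters(
    profiles: Sequence[RankProfile],
    utrs: Sequence[UtrRecord],
    max_rank_threshold: int = MAX_RANK_DEFAULT,
    min_utr: int = MIN_UTR_DEFAULT,
) -> list[PromoterCandidate]:
    """Flag every profile against the two exclusion filters.

    Profiles without a matching UTR record are retained, flagged as failing
    the UTR filter (un-annotated genes are reported, never silently dropped).
    Input order (the aggregation order) is preserved.
    """
    if max_rank_threshold <= 0:
        raise ConfigError(f"max_rank_threshold must be > 0, got {max_rank_threshold}")
    if min_utr < 0:
        raise ConfigError(f"min_utr must be >= 0, got {min_utr}")
    utr_by_gene = {u.gene_id: u for u in utrs}
    candidates = []
    for p in profiles:
        utr = utr_by_gene.get(p.gene_id)
        candidates.append(
            PromoterCandidate(
                gene_id=p.gene_id,
                min_rank=p.min_rank,
                max_rank=p.max_rank,
                median_rank=p.median_rank,
                utr_length=None if utr is None else utr.utr_length,
                passes_max_rank=p.max_rank <= max_rank_threshold,
                passes_utr=utr is not None and utr.utr_length >= min_utr,
            )
        )
    n_fail_rank = sum(not c.passes_max_rank for c in candidates)
    n_fail_utr = sum(not c.passes_utr for c in candidates)
    logger.info(
        "filters: %d genes in, %d fail max-rank<=%d, %d fail utr>=%d, %d pass both",
        len(candidates), n_fail_rank, max_rank_threshold, n_fail_utr, min_utr,
        sum(c.passes for c in candidates),
    )
    return candidates


def select_top(
    candidates: Sequence[PromoterCandidate], n: int = TOP_N_DEFAULT
) -> list[PromoterCandidate]:
    """Mark the first ``n`` passing candidates (in given order) as selected.

    If fewer than ``n`` pass, all passing candidates are selected and a
    warning is logged.  Returns the selected candidates, order preserved.
    """
    if n <= 0:
        raise ConfigError(f"selection size n must be > 0, got {n}")
    selected = []
    for c in candidates:
        c.selected = False
    for c in candidates:
        if c.passes and len(selected) < n:
            c.selected = True
            selected.append(c)
    if len(selected) < n:
        logger.warning("only %d of the requested %d candidates pass the filters",
                       len(selected), n)
    return selected


def attach_promoters(
    candidates: Sequence[PromoterCandidate],
    features: Mapping[str, GeneFeature],
    utrs: Sequence[UtrRecord],
    target_length: int = TARGET_LENGTH_DEFAULT,
    target_overrides: Mapping[str, int] | None = None,
) -> None:
    """Compute the promoter window for every selected, annotated candidate.

    ``target_overrides`` maps gene_id to a per-gene target length, for
    promoters deliberately tested at a non-default size.
    """
    utr_by_gene = {u.gene_id: u for u in utrs}
    overrides = dict(target_overrides or {})
    for c in candidates:
        if not c.selected or c.gene_id not in features:
            continue
        c.promoter = promoter_window(
            features[c.gene_id],
            utr_by_gene[c.gene_id],
            overrides.get(c.gene_id, target_length),
        )


def candidates_to_frame(candidates: Sequence[PromoterCandidate]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "min_rank": c.min_rank,
            "max_rank": c.max_rank,
            "median_rank": c.median_rank,
            "utr_length": "" if c.utr_length is None else c.utr_length,
            "promoter_length": "" if c.promoter is None else c.promoter.length,
            "passes_max_rank": c.passes_max_rank,
            "passes_utr": c.passes_utr,
            "selected": c.selected,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "min_rank", "max_rank", "median_rank", "utr_length",
                 "promoter_length", "passes_max_rank", "passes_utr", "selected"],
    )


def report_depth_slice(
    candidates: Sequence[PromoterCandidate], n: int = TOP_N_DEFAULT,
    depth_factor: int = 2,
) -> list[PromoterCandidate]:
    """Head of the candidate list down to the ``depth_factor * n``-th passing row.

    Failing rows interleaved above that point are kept, mirroring a report
    that prints excluded genes alongside the selected ones.
    """
    limit = depth_factor * n
    out: list[PromoterCandidate] = []
    passing = 0
    for c in candidates:
        out.append(c)
        if c.passes:
            passing += 1
            if passing >= limit:
                break
    return out


def write_report(
    candidates: Sequence[PromoterCandidate],
    out_dir: Path | str,
    fasta_path: Path | str | None = None,
    run_summary: Mapping | None = None,
) -> dict[str, Path]:
    """Write the candidate TSV, promoter BED/FASTA and a JSON run summary.

    The TSV is a faithful round-trippable dump of the candidate list; BED and
    FASTA cover the selected candidates with a non-empty promoter window.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out / "candidates.tsv",
        "bed": out / "promoters.bed",
        "fasta": out / "promoters.fasta",
        "summary": out / "run_summary.json",
    }
    candidates_to_frame(candidates).to_csv(paths["report"], sep="\t", index=False)

    windows = [(c.promoter, c.median_rank) for c in candidates
               if c.selected and c.promoter is not None and not c.promoter.empty]
    write_bed6(windows, paths["bed"])
    if fasta_path is not None:
        write_promoter_fasta(fasta_path, [w for w, _ in windows], paths["fasta"])
    else:
        paths["fasta"].write_text("")

    summary = dict(run_summary or {})
    summary.setdefault("n_candidates", len(candidates))
    summary.setdefault("n_selected", sum(c.selected for c in candidates))
    paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True))
    return paths


def read_report(path: Path | str) -> list[PromoterCandidate]:
    """Reload a candidates.tsv written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        utr = row["utr_length"]
        out.append(
            PromoterCandidate(
                gene_id=str(row["gene_id"]),
                min_rank=int(row["min_rank"]),
                max_rank=int(row["max_rank"]),
                median_rank=float(row["median_rank"]),
                utr_length=None if pd.isna(utr) else int(utr),
                passes_max_rank=bool(row["passes_max_rank"]),
                passes_utr=bool(row["passes_utr"]),
                selected=bool(row["selected"]),
            )
        )
    return out
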