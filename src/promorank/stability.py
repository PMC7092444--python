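"""Stability of the prioritized list under dataset subsampling.

How much does the head of the gene list depend on how many datasets went
into it?  For each requested subset size, random dataset subsets are drawn
(without replacement within a subset), the rank aggregation is recomputed on
the subset — with the median order statistic taken at the subset's own N —
and the subset's top-k is compared with the full-collection top-k by overlap
count and Jaccard index over the two heads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .expression import DatasetCollection
from .ranking import RankProfile, aggregate_ranks

logger = logging.getLogger(__name__)


@dataclass
class StabilityResult:
    """Top-k agreement with the full collection at one subset size."""

    subset_size: int
    n_replicates: int
    overlaps: list[int]
    jaccards: list[float]

    @property
    def mean_overlap(self) -> float:
        return float(np.mean(self.overlaps))

    @property
    def mean_jaccard(self) -> float:
        return float(np.mean(self.jaccards))

    @property
    def sem_overlap(self) -> float:
        """Standard error of the mean overlap."""
        if len(self.overlaps) < 2:
            return 0.0
        return float(np.std(self.overlaps, ddof=1) / np.sqrt(len(self.overlaps)))


def aggregate_on_subset(
    collection: DatasetCollection, dataset_ids: Sequence[str]
) -> list[RankProfile]:
    """Rank aggregation restricted to a subset of datasets.

    Identical semantics to the full aggregation; in particular the median
    index is recomputed for the subset's own dataset count.
    """
    if not dataset_ids:
        raise ConfigError("dataset subset must be non-empty")
    return aggregate_ranks(collection.subset(list(dataset_ids)))


def topk_overlap(
    list_a: Sequence[RankProfile] | Sequence[str],
    list_b: Sequence[RankProfile] | Sequence[str],
    k: int,
) -> tuple[int, float]:
    """Overlap count and Jaccard index of the two list heads.

    Accepts profile lists or plain gene-id lists.  ``k`` larger than a list
    truncates to the full list with a warning.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")

    def head(lst: Sequence) -> set[str]:
        ids = [x.gene_id if isinstance(x, RankProfile) else str(x) for x in lst]
        if k > len(ids):
            warnings.warn(
                f"k={k} exceeds list length {len(ids)}; using the full list",
                stacklevel=3,
            )
        return set(ids[:k])

    a, b = head(list_a), head(list_b)
    overlap = len(a & b)
    union = len(a | b)
    return overlap, (overlap / union if union else 1.0)


def stability_curve(
    collection: DatasetCollection,
    sizes: Sequence[int],
    k: int = 20,
    n_replicates: int = 50,
    seed: int = 0,
) -> list[StabilityResult]:
    """Top-k overlap with the full-collection list across subset sizes.

    Subsets are drawn uniformly without replacement; a subset of the full
    size is the identity comparison and scores overlap = k exactly.
    """
    n = len(collection)
    for size in sizes:
        if size < 1:
            raise ConfigError(f"subset size must be >= 1, got {size}")
        if size > n:
            raise ConfigError(f"subset size {size} exceeds dataset count {n}")
    rng = np.random.default_rng(seed)
    full_top = aggregate_ranks(collection)
    all_ids = np.array(collection.dataset_ids)

    results = []
    for size in sizes:
        overlaps, jaccards = [], []
        for _ in range(n_replicates):
            chosen = rng.choice(all_ids, size=size, replace=False)
            sub = aggregate_on_subset(collection, list(chosen))
            o, j = topk_overlap(sub, full_top, k)
            overlaps.append(o)
            jaccards.append(j)
        results.append(StabilityResult(size, n_replicates, overlaps, jaccards))
        logger.info("stability: size=%d mean_overlap=%.2f mean_jaccard=%.3f",
                    size, results[-1].mean_overlap, results[-1].mean_jaccard)
    return results


def results_to_frames(
    results: Sequence[StabilityResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-replicate, summary) tables of a stability run."""
    rows = [
        {"subset_size": r.subset_size, "replicate": i + 1,
         "overlap": o, "jaccard": j}
        for r in results
        for i, (o, j) in enumerate(zip(r.overlaps, r.jaccards))
    ]
    summary = [
        {"subset_size": r.subset_size, "n_replicates": r.n_replicates,
         "mean_overlap": r.mean_overlap, "sem_overlap": r.sem_overlap,
         "mean_jaccard": r.mean_jaccard}
        for r in results
    ]
    return pd.DataFrame(rows), pd.DataFrame(summary)


def write_stability_tables(
    results: Sequence[StabilityResult], out_dir: Path | str
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_rep, summary = results_to_frames(results)
    paths = {"replicates": out / "stability_replicates.tsv",
             "summary": out / "stability_summary.tsv"}
    per_rep.to_csv(paths["replicates"], sep="\t", index=False)
    summary.to_csv(paths["summary"], sep="\t", index=False, float_format="%.4f")
    return paths
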