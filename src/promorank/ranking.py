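"""Within-dataset expression ranking and per-gene rank aggregation.

The score of a gene is the *order-statistic median* of its per-dataset ranks:
rank genes by intensity within each dataset (rank 1 = highest), collect one
rank per dataset for each gene, and summarize the rank vector by its minimum,
maximum and median.  For an odd number of datasets N the median is the
((N+1)/2)-th smallest rank — e.g. the 42nd of 83 sorted ranks; for even N it
is the mean of the two middle ranks and may be half-integer.

Because only ranks enter the aggregation, the procedure is invariant to any
strictly increasing transform applied per dataset — no cross-dataset
normalization is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .expression import DatasetCollection, ExpressionDataset


@dataclass
class RankProfile:
    """Per-gene rank vector across datasets plus its order statistics."""

    gene_id: str
    ranks: dict[str, int]          # dataset_id -> rank in 1..G
    min_rank: int
    max_rank: int
    median_rank: float             # half-integer possible for even N

    @classmethod
    def from_ranks(cls, gene_id: str, ranks: Mapping[str, int]) -> "RankProfile":
        values = list(ranks.values())
        return cls(
            gene_id=gene_id,
            ranks=dict(ranks),
            min_rank=min(values),
            max_rank=max(values),
            median_rank=median_rank(values),
        )


def rank_within_dataset(
    dataset: ExpressionDataset, universe: Iterable[str]
) -> dict[str, int]:
    """Rank genes of `universe` by intensity within one dataset.

    Rank 1 is the highest intensity.  Ties are broken by ascending gene_id so
    that ranks are always an exact permutation of 1..G — average-rank ties
    would break the order-statistic semantics of the median.

    Genes of the universe absent from the dataset (union-worst-rank policy)
    all receive the worst rank G.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("gene universe is empty")
    present = sorted(universe & dataset.genes)
    absent = universe - dataset.genes
    order = sorted(present, key=lambda g: (-dataset.intensities[g], g))
    ranks = {g: i + 1 for i, g in enumerate(order)}
    worst = len(universe)
    for g in absent:
        ranks[g] = worst
    return ranks


def median_rank(ranks: Sequence[float]) -> float:
    """Order-statistic median: k-th smallest for odd N, mid-pair mean for even N."""
    if len(ranks) == 0:
        raise ValidationError("median of an empty rank list")
    ordered = np.sort(np.asarray(ranks, dtype=float))
    n = len(ordered)
    if n % 2:
        return float(ordered[(n - 1) // 2])
    return float((ordered[n // 2 - 1] + ordered[n // 2]) / 2.0)


def profile_sort_key(p: RankProfile) -> tuple:
    """Deterministic report ordering: median, then max, then min, then gene_id."""
    return (p.median_rank, p.max_rank, p.min_rank, p.gene_id)


def aggregate_ranks(collection: DatasetCollection) -> list[RankProfile]:
    """One profile per universe gene, sorted ascending by median rank.

    Ties are broken by max rank, then min rank, then gene_id, so output order
    is fully deterministic.
    """
    if not collection.datasets:
        raise ValidationError("cannot aggregate an empty collection")
    per_dataset = {
        d.dataset_id: rank_within_dataset(d, collection.gene_universe)
        for d in collection.datasets
    }
    profiles = [
        RankProfile.from_ranks(
            gene, {ds_id: ranks[gene] for ds_id, ranks in per_dataset.items()}
        )
        for gene in sorted(collection.gene_universe)
    ]
    profiles.sort(key=profile_sort_key)
    return profiles


def profiles_to_frame(
    profiles: Sequence[RankProfile], dataset_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabulate profiles: gene_id, min/max/median, then one rank column per dataset."""
    if dataset_ids is None:
        dataset_ids = list(profiles[0].ranks) if profiles else []
    rows = []
    for p in profiles:
        row = {
            "gene_id": p.gene_id,
            "min_rank": p.min_rank,
            "max_rank": p.max_rank,
            "median_rank": p.median_rank,
        }
        row.update({f"rank_{d}": p.ranks[d] for d in dataset_ids})
        rows.append(row)
    columns = ["gene_id", "min_rank", "max_rank", "median_rank"] + [
        f"rank_{d}" for d in dataset_ids
    ]
    return pd.DataFrame(rows, columns=columns)


def write_rank_table(profiles: Sequence[RankProfile], path: Path | str,
                     dataset_ids: Sequence[str] | None = None) -> None:
    profiles_to_frame(profiles, dataset_ids).to_csv(path, sep="\t", index=False)


def read_rank_table(path: Path | str) -> list[RankProfile]:
    """Inverse of :func:`write_rank_table` (order preserved)."""
    df = pd.read_csv(path, sep="\t")
    rank_cols = [c for c in df.columns if c.startswith("rank_")]
    profiles = []
    for _, row in df.iterrows():
        ranks = {c[len("rank_"):]: int(row[c]) for c in rank_cols}
        profiles.append(
            RankProfile(
                gene_id=str(row["gene_id"]),
                ranks=ranks,
                min_rank=int(row["min_rank"]),
                max_rank=int(row["max_rank"]),
                median_rank=float(row["median_rank"]),
            )
        )
    return profiles
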