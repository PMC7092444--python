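"""Reading and validation of multi-dataset expression input.

A *dataset* is one expression vector over a gene universe (one transcriptome
experiment, possibly averaged over replicate sample columns).  Input is one or
more TSV matrices (first column ``gene_id``, remaining columns sample IDs)
plus a TSV manifest with columns ``sample_id``, ``dataset_id``, ``condition``
mapping every sample column to its dataset.

No normalization is applied on read: downstream scoring is rank-based and
therefore invariant to any within-dataset monotone transform, so scale
disagreements between datasets are immaterial by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError, InputFormatError, ManifestError, ValidationError

logger = logging.getLogger(__name__)

#: Gene-universe policies.
#:   require-identical -- every dataset must cover the same genes (default)
#:   intersect         -- universe is the intersection; extra genes dropped
#:   union-worst-rank  -- universe is the union; a gene absent from a dataset
#:                        receives the worst possible rank there
UNIVERSE_POLICIES = ("require-identical", "intersect", "union-worst-rank")

#: How multiple sample columns mapped to one dataset_id are handled.
REPLICATE_POLICIES = ("average", "each-sample-is-a-dataset")

#: How missing / non-numeric cells are handled.
MISSING_POLICIES = ("strict", "drop-gene")


@dataclass
class ExpressionDataset:
    """One transcriptome set: a gene -> intensity map with identity labels."""

    dataset_id: str
    condition: str
    intensities: dict[str, float]

    def __post_init__(self) -> None:
        values = np.fromiter(self.intensities.values(), dtype=float,
                             count=len(self.intensities))
        if not np.all(np.isfinite(values)):
            raise ValidationError(
                f"dataset {self.dataset_id!r} contains non-finite intensities"
            )

    @property
    def genes(self) -> set[str]:
        return set(self.intensities)


@dataclass
class DatasetCollection:
    """An ordered list of datasets plus the gene universe they are scored on."""

    datasets: list[ExpressionDataset]
    gene_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate dataset_id in collection")
        if self.datasets and not self.gene_universe:
            raise ValidationError("gene_universe is empty")

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def dataset_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]

    def subset(self, dataset_ids: Sequence[str]) -> "DatasetCollection":
        """Restrict to the given dataset ids (order taken from the argument)."""
        from ._errors import ReferenceLookupError

        by_id = {d.dataset_id: d for d in self.datasets}
        missing = [i for i in dataset_ids if i not in by_id]
        if missing:
            raise ReferenceLookupError(f"unknown dataset_id(s): {missing}")
        return DatasetCollection(
            datasets=[by_id[i] for i in dataset_ids],
            gene_universe=set(self.gene_universe),
        )


def _read_matrix(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise InputFormatError(
            f"{path}: first column must be 'gene_id', got {df.columns[0]!r}"
        )
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise InputFormatError(f"{path}: duplicate gene row {dup.iloc[0]!r}")
    return df.set_index("gene_id")


def read_manifest(path: Path | str) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "dataset_id", "condition"}
    if not required.issubset(m.columns):
        raise InputFormatError(
            f"{path}: manifest needs columns {sorted(required)}, got {list(m.columns)}"
        )
    if m["sample_id"].duplicated().any():
        raise ManifestError(f"{path}: a sample_id appears more than once")
    return m


def read_collection(
    matrix_paths: Sequence[Path | str],
    manifest_path: Path | str,
    *,
    universe_policy: str = "require-identical",
    replicate_policy: str = "average",
    missing_policy: str = "strict",
) -> DatasetCollection:
    """Build a :class:`DatasetCollection` from TSV matrices and a manifest.

    Sample columns sharing a ``dataset_id`` are mean-averaged on the stored
    scale (``replicate_policy="average"``) or promoted to individual datasets
    suffixed ``<dataset_id>.<sample_id>`` (``"each-sample-is-a-dataset"``).
    """
    if universe_policy not in UNIVERSE_POLICIES:
        raise ConfigError(f"universe_policy must be one of {UNIVERSE_POLICIES}")
    if replicate_policy not in REPLICATE_POLICIES:
        raise ConfigError(f"replicate_policy must be one of {REPLICATE_POLICIES}")
    if missing_policy not in MISSING_POLICIES:
        raise ConfigError(f"missing_policy must be one of {MISSING_POLICIES}")

    matrices = [_read_matrix(p) for p in matrix_paths]
    manifest = read_manifest(manifest_path)

    sample_home: dict[str, pd.DataFrame] = {}
    for mat in matrices:
        for col in mat.columns:
            sample_home[col] = mat
    missing_samples = [s for s in manifest["sample_id"] if s not in sample_home]
    if missing_samples:
        raise ManifestError(
            f"manifest sample(s) missing from matrices: {missing_samples}"
        )

    datasets: list[ExpressionDataset] = []
    for dataset_id, rows in manifest.groupby("dataset_id", sort=False):
        conditions = rows["condition"].unique()
        if len(conditions) > 1:
            raise ManifestError(
                f"dataset {dataset_id!r} maps to multiple conditions: {list(conditions)}"
            )
        cols = [sample_home[s][s] for s in rows["sample_id"]]
        if replicate_policy == "each-sample-is-a-dataset" and len(cols) > 1:
            for sample_id, col in zip(rows["sample_id"], cols):
                datasets.append(
                    _make_dataset(f"{dataset_id}.{sample_id}", conditions[0],
                                  col.to_frame(), missing_policy)
                )
        else:
            merged = pd.concat(cols, axis=1)
            datasets.append(
                _make_dataset(str(dataset_id), conditions[0], merged, missing_policy)
            )

    universe = resolve_universe(datasets, universe_policy)
    if universe_policy == "intersect":
        for d in datasets:
            d.intensities = {g: d.intensities[g] for g in d.intensities
                             if g in universe}
    return DatasetCollection(datasets=datasets, gene_universe=universe)


def _make_dataset(
    dataset_id: str, condition: str, frame: pd.DataFrame, missing_policy: str
) -> ExpressionDataset:
    values = frame.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1) | ~np.isfinite(values).all(axis=1)
    if bad.any():
        if missing_policy == "strict":
            gene = values.index[bad][0]
            raise ValidationError(
                f"dataset {dataset_id!r}: non-numeric or missing value for gene {gene!r}"
            )
        values = values.loc[~bad]
        logger.info("dataset %s: dropped %d gene(s) with missing values",
                    dataset_id, int(bad.sum()))
    mean = values.mean(axis=1)
    return ExpressionDataset(dataset_id, condition, mean.to_dict())


def resolve_universe(
    datasets: Iterable[ExpressionDataset], policy: str
) -> set[str]:
    """Apply the gene-universe policy to a list of datasets."""
    gene_sets = [d.genes for d in datasets]
    if not gene_sets:
        raise ValidationError("collection has no datasets")
    union: set[str] = set().union(*gene_sets)
    intersection = set.intersection(*gene_sets)
    if policy == "require-identical":
        if union != intersection:
            odd = sorted(union - intersection)[:5]
            raise ValidationError(
                "datasets do not share an identical gene universe "
                f"(e.g. {odd}); use policy 'intersect' or 'union-worst-rank'"
            )
        return union
    if policy == "intersect":
        dropped = len(union) - len(intersection)
        if dropped:
            logger.info("universe policy 'intersect': dropped %d gene(s)", dropped)
        if not intersection:
            raise ValidationError("gene universe empty after intersection")
        return intersection
    return union


def write_collection(collection: DatasetCollection, matrix_path: Path | str,
                     manifest_path: Path | str) -> None:
    """Write a collection back to the TSV matrix + manifest interchange format.

    Each dataset becomes one sample column named after its dataset_id, so a
    read/write/read round trip reproduces the collection.
    """
    genes = sorted(collection.gene_universe)
    data = {
        d.dataset_id: [d.intensities.get(g, np.nan) for g in genes]
        for d in collection.datasets
    }
    frame = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    frame.to_csv(matrix_path, sep="\t", float_format="%.6f")
    manifest = pd.DataFrame(
        {
            "sample_id": collection.dataset_ids,
            "dataset_id": collection.dataset_ids,
            "condition": [d.condition for d in collection.datasets],
        }
    )
    manifest.to_csv(manifest_path, sep="\t", index=False)
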