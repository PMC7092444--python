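"""Within-dataset ranking and rank aggregation, checked against brute force."""

import itertools
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promorank import ValidationError
from promorank.expression import DatasetCollection, ExpressionDataset
from promorank.ranking import (RankProfile, aggregate_ranks, median_rank,
                               profile_sort_key, rank_within_dataset)

# ---------------------------------------------------------------------------
# independent brute-force oracle: different code path on purpose
# ---------------------------------------------------------------------------


def brute_rank(intensities: dict[str, float]) -> dict[str, int]:
    """rank(g) = 1 + #{h: x_h > x_g} + #{h: x_h == x_g and h < g}."""
    out = {}
    for g, xg in intensities.items():
        higher = sum(1 for h, xh in intensities.items() if xh > xg)
        tied_before = sum(
            1 for h, xh in intensities.items() if xh == xg and h < g
        )
        out[g] = 1 + higher + tied_before
    return out


def brute_aggregate(collection: DatasetCollection):
    """(gene, min, max, median) rows in final report order, via statistics."""
    per_ds = {d.dataset_id: brute_rank(d.intensities) for d in collection.datasets}
    rows = []
    for g in sorted(collection.gene_universe):
        ranks = [per_ds[d][g] for d in per_ds]
        rows.append((g, min(ranks), max(ranks), float(statistics.median(ranks))))
    rows.sort(key=lambda r: (r[3], r[2], r[1], r[0]))
    return rows


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ranks, expected",
    [
        (list(range(1, 84)), 42.0),   # odd N: the 42nd of 83 sorted ranks
        ([7], 7.0),
        ([4, 2, 10, 6], 5.0),         # even N: mean of the middle pair
        ([3, 1, 2], 2.0),
    ],
)
def test_median_rank_order_statistic(ranks, expected):
    rng = np.random.default_rng(0)
    shuffled = list(rng.permutation(ranks))
    assert median_rank(shuffled) == expected


def test_median_rank_empty_list_rejected():
    with pytest.raises(ValidationError):
        median_rank([])


@pytest.mark.parametrize(
    "intensities, expected",
    [
        ({"a": 10.0, "b": 7.5, "c": 9.9}, {"a": 1, "c": 2, "b": 3}),
        ({"a": 5.0, "b": 5.0}, {"a": 1, "b": 2}),  # tie -> gene_id order
    ],
)
def test_rank_within_dataset_examples(intensities, expected):
    ds = ExpressionDataset("d", "c", intensities)
    assert rank_within_dataset(ds, intensities.keys()) == expected


def test_rank_empty_universe_rejected(tiny_collection):
    with pytest.raises(ValidationError):
        rank_within_dataset(tiny_collection.datasets[0], set())


def test_absent_gene_gets_worst_rank():
    ds = ExpressionDataset("d", "c", {"a": 3.0, "b": 1.0})
    ranks = rank_within_dataset(ds, {"a", "b", "z"})
    assert ranks == {"a": 1, "b": 2, "z": 3}


@given(
    values=st.lists(
        st.integers(min_value=-5000, max_value=5000).map(lambda i: i / 100.0),
        min_size=2, max_size=12,
    )
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_rank_invariant_under_monotone_transform(values):
    genes = [f"g{i}" for i in range(len(values))]
    base = ExpressionDataset("d", "c", dict(zip(genes, values)))
    transformed = ExpressionDataset(
        "d", "c", {g: float(2.0 ** v) for g, v in zip(genes, values)}
    )
    assert rank_within_dataset(base, genes) == rank_within_dataset(
        transformed, genes
    )


def test_profile_summary_arithmetic():
    p = RankProfile.from_ranks("g", {"d1": 5, "d2": 2, "d3": 9})
    assert (p.min_rank, p.max_rank, p.median_rank) == (2, 9, 5.0)


def test_rank_multiset_is_full_permutation(tiny_collection):
    for ds in tiny_collection.datasets:
        ranks = rank_within_dataset(ds, tiny_collection.gene_universe)
        assert sorted(ranks.values()) == [1, 2, 3]


def test_aggregate_ordering_and_bounds(tiny_collection):
    profiles = aggregate_ranks(tiny_collection)
    assert [profile_sort_key(p) for p in profiles] == sorted(
        profile_sort_key(p) for p in profiles
    )
    g = len(tiny_collection.gene_universe)
    for p in profiles:
        assert 1 <= p.min_rank <= p.median_rank <= p.max_rank <= g
        assert len(p.ranks) == len(tiny_collection)


def _collection_from_values(matrix: dict[str, dict[str, float]]) -> DatasetCollection:
    datasets = [
        ExpressionDataset(ds_id, "c", dict(vals)) for ds_id, vals in matrix.items()
    ]
    universe = set(next(iter(matrix.values())))
    return DatasetCollection(datasets, gene_universe=universe)


def test_aggregate_matches_bruteforce_exhaustively():
    """All 3-gene orderings in each of 3 datasets (216 collections) + ties."""
    genes = ["a", "b", "c"]
    orderings = list(itertools.permutations([1.0, 2.0, 3.0]))
    for combo in itertools.product(orderings, repeat=3):
        coll = _collection_from_values(
            {f"d{i}": dict(zip(genes, vals)) for i, vals in enumerate(combo)}
        )
        got = [
            (p.gene_id, p.min_rank, p.max_rank, p.median_rank)
            for p in aggregate_ranks(coll)
        ]
        assert got == brute_aggregate(coll)
    # tie-heavy values
    tied = list(itertools.product([1.0, 2.0], repeat=3))
    for combo in itertools.product(tied, repeat=2):
        coll = _collection_from_values(
            {f"d{i}": dict(zip(genes, vals)) for i, vals in enumerate(combo)}
        )
        got = [
            (p.gene_id, p.min_rank, p.max_rank, p.median_rank)
            for p in aggregate_ranks(coll)
        ]
        assert got == brute_aggregate(coll)


@given(
    n_genes=st.integers(2, 6),
    n_datasets=st.integers(1, 3),
    data=st.data(),
)
@settings(deadline=None, max_examples=80, derandomize=True)
def test_aggregate_matches_bruteforce_random(n_genes, n_datasets, data):
    genes = [f"g{i}" for i in range(n_genes)]
    matrix = {}
    for d in range(n_datasets):
        vals = data.draw(
            st.lists(
                st.sampled_from([0.0, 1.0, 1.5, 2.0, 7.25]),  # forces ties
                min_size=n_genes, max_size=n_genes,
            )
        )
        matrix[f"d{d}"] = dict(zip(genes, vals))
    coll = _collection_from_values(matrix)
    got = [
        (p.gene_id, p.min_rank, p.max_rank, p.median_rank)
        for p in aggregate_ranks(coll)
    ]
    assert got == brute_aggregate(coll)


def test_aggregate_empty_collection_rejected():
    with pytest.raises(ValidationError):
        aggregate_ranks(DatasetCollection([], set()))
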