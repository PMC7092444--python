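"""Synthetic expression collections and toy genomes with planted ground truth.

The generator emulates the study design the pipeline targets: tens of
transcriptome datasets collected under a smaller number of biological
conditions, over a gene-dense fungal genome.  A chosen set of *planted*
constitutive genes is always highly expressed; every other gene has a
baseline level plus a per-condition response shared by all datasets of that
condition (replicate datasets are correlated, as real replicated series are).

Log-intensity model for gene g in dataset d of condition c:

    x(g, d) = mu_g + beta(g, c) + eps(g, d)

* planted genes:     mu_g = mu_high, beta = 0
* responsive genes:  mu_g ~ Normal(mu_base_mean, mu_base_sd);
                     beta(g, c) ~ Normal(0, tau_condition), drawn once per
                     (gene, condition) and shared across that condition's
                     datasets
* eps(g, d) ~ Normal(0, sigma_noise) independently per gene and dataset.

The genome generator places genes sequentially on contigs with intergenic
gaps drawn from a two-component (short/long) mixture, assigns strands at
random, and records every gene's upstream intergenic distance exactly as
laid out — the downstream annotation module must reproduce these distances
from the emitted FASTA/GFF3 alone.

All randomness derives from a single master seed via named
``numpy.random.SeedSequence`` sub-streams (expression, geometry, sequence),
so equal configs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._errors import ConfigError
from .expression import DatasetCollection, ExpressionDataset


@dataclass(frozen=True)
class GapMixture:
    """Two-component intergenic-gap model (bp).

    With probability ``fraction_long`` a gap is drawn from the long component
    (exponential with mean ``long_mean``, shifted by ``long_offset`` to mimic
    the roomy intergenic stretches that can host a full-length promoter),
    otherwise from the short component (exponential with mean ``short_mean``,
    the tightly packed head-to-tail neighbors).
    """

    short_mean: float = 300.0
    long_mean: float = 2000.0
    long_offset: float = 1000.0
    fraction_long: float = 0.5

    def sample(self, rng: np.random.Generator) -> int:
        if rng.random() < self.fraction_long:
            return int(round(self.long_offset + rng.exponential(self.long_mean)))
        return int(round(rng.exponential(self.short_mean)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study; defaults are the standard benchmark
    configuration used throughout the tests (3000 genes, 20 datasets under 10
    conditions, 25 planted constitutive genes)."""

    n_genes: int = 3000
    n_datasets: int = 20
    n_conditions: int = 10
    n_constitutive: int = 25
    mu_high: float = 12.0
    mu_base_mean: float = 7.0
    mu_base_sd: float = 2.0
    tau_condition: float = 2.0
    sigma_noise: float = 0.5
    n_contigs: int = 5
    gene_len_mean: int = 1500
    gap_lengths: GapMixture = field(default_factory=GapMixture)
    seed: int = 11

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_datasets", "n_conditions", "n_constitutive",
                     "n_contigs", "gene_len_mean"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("mu_base_sd", "tau_condition", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_constitutive >= self.n_genes:
            raise ConfigError(
                f"n_constitutive ({self.n_constitutive}) must be < n_genes "
                f"({self.n_genes})"
            )
        if not 0.0 <= self.gap_lengths.fraction_long <= 1.0:
            raise ConfigError("gap_lengths.fraction_long must lie in [0, 1]")

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """Named deterministic sub-streams derived from the master seed."""
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(3)
        names = ("expression", "geometry", "sequence")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class SyntheticTruth:
    """Planted gene set and genome geometry, for recovery and round-trip tests."""

    constitutive_gene_ids: set[str]
    gene_coordinates: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    utr_lengths: dict[str, int] = field(default_factory=dict)
    at_contig_edge: set[str] = field(default_factory=set)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: Path | str) -> None:
        payload = {
            "constitutive_gene_ids": sorted(self.constitutive_gene_ids),
            "gene_coordinates": {g: list(c) for g, c in self.gene_coordinates.items()},
            "utr_lengths": self.utr_lengths,
            "at_contig_edge": sorted(self.at_contig_edge),
            "contig_lengths": self.contig_lengths,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Path | str) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            constitutive_gene_ids=set(payload["constitutive_gene_ids"]),
            gene_coordinates={
                g: (c[0], int(c[1]), int(c[2]), c[3])
                for g, c in payload["gene_coordinates"].items()
            },
            utr_lengths={g: int(v) for g, v in payload["utr_lengths"].items()},
            at_contig_edge=set(payload["at_contig_edge"]),
            contig_lengths={k: int(v) for k, v in payload["contig_lengths"].items()},
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_expression(
    config: SyntheticConfig,
) -> tuple[DatasetCollection, SyntheticTruth]:
    """Simulate the dataset collection and choose the planted gene set.

    Datasets are assigned round-robin to conditions; every dataset contains
    every gene (single-platform design).  The returned truth carries the
    planted ids only — genome geometry is filled in by
    :func:`generate_genome`.
    """
    rng = config.rng_streams()["expression"]
    genes = _gene_ids(config.n_genes)
    planted_idx = rng.choice(config.n_genes, size=config.n_constitutive, replace=False)
    planted = {genes[i] for i in planted_idx}

    mu = rng.normal(config.mu_base_mean, config.mu_base_sd, size=config.n_genes)
    mu[planted_idx] = config.mu_high

    # beta[g, c]: per-condition response, zero for planted genes
    beta = rng.normal(0.0, config.tau_condition,
                      size=(config.n_genes, config.n_conditions))
    beta[planted_idx, :] = 0.0

    datasets: list[ExpressionDataset] = []
    d_width = max(2, len(str(config.n_datasets)))
    c_width = max(2, len(str(config.n_conditions)))
    for d in range(config.n_datasets):
        c = d % config.n_conditions
        eps = rng.normal(0.0, config.sigma_noise, size=config.n_genes)
        x = mu + beta[:, c] + eps
        datasets.append(
            ExpressionDataset(
                dataset_id=f"D{d + 1:0{d_width}d}",
                condition=f"C{c + 1:0{c_width}d}",
                intensities=dict(zip(genes, x.tolist())),
            )
        )
    collection = DatasetCollection(datasets=datasets, gene_universe=set(genes))
    return collection, SyntheticTruth(constitutive_gene_ids=planted)


def generate_genome(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    fasta_path: Path | str,
    gff3_path: Path | str,
) -> tuple[Path, Path]:
    """Lay out the toy genome, record its geometry in ``truth``, write files.

    Genes are placed left to right, ceil(n_genes/n_contigs) per contig, with
    gaps from the configured mixture before each gene and a 500 bp tail after
    the last one.  Strands are random.  The recorded upstream distance of
    each gene is exactly the geometric gap the layout created:

    * + strand gene: the gap to the previous gene's end (contig edge for the
      first gene, distance = start - 1);
    * - strand gene: the gap to the next gene's start (contig edge for the
      last gene, distance = contig_length - end).

    Sequence content is uniform random A/C/G/T — only coordinates matter to
    the downstream analysis.
    """
    streams = config.rng_streams()
    rng_geo, rng_seq = streams["geometry"], streams["sequence"]
    genes = _gene_ids(config.n_genes)
    if not truth.constitutive_gene_ids <= set(genes):
        raise ConfigError("truth.constitutive_gene_ids not drawn from this config")

    per_contig = -(-config.n_genes // config.n_contigs)  # ceil
    truth.gene_coordinates.clear()
    truth.utr_lengths.clear()
    truth.at_contig_edge.clear()
    truth.contig_lengths.clear()

    contigs: dict[str, list[tuple[str, int, int, str]]] = {}
    for ci in range(config.n_contigs):
        contig = f"contig{ci + 1:02d}"
        block = genes[ci * per_contig : (ci + 1) * per_contig]
        if not block:
            continue
        cursor = 0  # 0-based position of last placed base
        placed: list[tuple[str, int, int, str]] = []
        for g in block:
            gap = config.gap_lengths.sample(rng_geo)
            length = max(150, int(round(rng_geo.normal(config.gene_len_mean,
                                                       config.gene_len_mean / 4))))
            start = cursor + gap + 1
            end = start + length - 1
            strand = "+" if rng_geo.random() < 0.5 else "-"
            placed.append((g, start, end, strand))
            cursor = end
        contig_len = cursor + 500
        truth.contig_lengths[contig] = contig_len
        contigs[contig] = placed
        for i, (g, start, end, strand) in enumerate(placed):
            truth.gene_coordinates[g] = (contig, start, end, strand)
            if strand == "+":
                if i == 0:
                    truth.utr_lengths[g] = start - 1
                    truth.at_contig_edge.add(g)
                else:
                    truth.utr_lengths[g] = start - placed[i - 1][2] - 1
            else:
                if i == len(placed) - 1:
                    truth.utr_lengths[g] = contig_len - end
                    truth.at_contig_edge.add(g)
                else:
                    truth.utr_lengths[g] = placed[i + 1][1] - end - 1

    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    bases = np.array(list("ACGT"))
    with open(fasta_path, "w") as fh:
        for contig, length in truth.contig_lengths.items():
            seq = "".join(bases[rng_seq.integers(0, 4, size=length)])
            fh.write(f">{contig}\n")
            for i in range(0, length, 70):
                fh.write(seq[i : i + 70] + "\n")

    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in truth.contig_lengths.items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for contig, placed in contigs.items():
            for g, start, end, strand in placed:
                fh.write(
                    f"{contig}\tpromorank\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={g}\n"
                )
    return fasta_path, gff3_path


def simulate_to_dir(config: SyntheticConfig, out_dir: Path | str) -> dict[str, Path]:
    """Run both generators and write the full artifact set to a directory.

    Writes ``matrix.tsv``, ``manifest.tsv``, ``genome.fasta``,
    ``annotation.gff3`` and ``truth.json``; returns the path map.
    """
    from .expression import write_collection

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collection, truth = generate_expression(config)
    paths = {
        "matrix": out / "matrix.tsv",
        "manifest": out / "manifest.tsv",
        "fasta": out / "genome.fasta",
        "gff3": out / "annotation.gff3",
        "truth": out / "truth.json",
    }
    write_collection(collection, paths["matrix"], paths["manifest"])
    generate_genome(config, truth, paths["fasta"], paths["gff3"])
    truth.to_json(paths["truth"])
    return paths


def config_from_dict(payload: dict) -> SyntheticConfig:
    """Build a config from a plain dict (YAML-friendly); unknown keys error."""
    payload = dict(payload)
    gap = payload.pop("gap_lengths", None)
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    if gap is not None:
        payload["gap_lengths"] = GapMixture(**gap)
    return SyntheticConfig(**payload)
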