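"""Gene models, strand-aware upstream intergenic distance, promoter windows.

The "5'-UTR length" used throughout is the intergenic distance from a gene's
5' end to the nearest upstream gene body on the same contig, regardless of
the neighbor's strand — it is the space available as a promoter.  For a
+ strand gene this is the gap to the closest feature ending before its start;
for a - strand gene, the gap to the closest feature starting after its end.
A neighbor overlapping the 5' end gives distance 0; a gene with no upstream
neighbor is flagged and measured to the contig edge.

Coordinate conventions: GFF3 features are 1-based inclusive; promoter windows
(and the BED output) are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from pyfaidx import Fasta

from ._errors import InputFormatError, ReferenceLookupError, ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval: 1-based inclusive coordinates, start <= end."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start},{self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class UtrRecord:
    """Upstream intergenic distance of one gene."""

    gene_id: str
    utr_length: int
    upstream_neighbor_id: str | None
    at_contig_edge: bool


@dataclass(frozen=True)
class PromoterWindow:
    """Promoter interval, 0-based half-open, abutting the gene's 5' coordinate.

    ``strand`` is the strand of the downstream gene; an empty (length-0)
    window marks a gene whose upstream neighbor leaves no promoter space.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def empty(self) -> bool:
        return self.length == 0


def read_gene_features(
    gff3_path: Path | str,
    feature_type: str = "gene",
    fasta_path: Path | str | None = None,
) -> tuple[list[GeneFeature], dict[str, int]]:
    """Parse gene models of ``feature_type`` from a GFF3 file.

    Contig lengths come from ``##sequence-region`` directives, falling back to
    the companion FASTA when given.  Features are returned sorted by
    (contig, start); the 5' anchor can be switched to the start codon by
    requesting ``feature_type="CDS"`` on annotations that provide it.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    contig_lengths: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            contig_lengths[parts[1]] = int(parts[3])
    if fasta_path is not None:
        fasta = Fasta(str(fasta_path))
        for name in fasta.keys():
            contig_lengths.setdefault(name, len(fasta[name]))

    features: list[GeneFeature] = []
    for f in db.features_of_type(feature_type):
        if "ID" not in f.attributes:
            raise InputFormatError(
                f"{gff3_path}: {feature_type} feature at {f.seqid}:{f.start}-{f.end} "
                "lacks an ID attribute"
            )
        if contig_lengths and f.seqid not in contig_lengths:
            raise ReferenceLookupError(
                f"{gff3_path}: feature on unknown contig {f.seqid!r}"
            )
        features.append(
            GeneFeature(
                gene_id=f.attributes["ID"][0],
                contig=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand,
            )
        )
    if not features:
        raise ValidationError(
            f"{gff3_path}: no features of type {feature_type!r} found"
        )
    features.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return features, contig_lengths


def compute_upstream_distance(
    features: Sequence[GeneFeature],
    contig_lengths: Mapping[str, int] | None = None,
) -> list[UtrRecord]:
    """Strand-aware upstream intergenic distance for every gene.

    For a + strand gene the upstream neighbor is the feature (any strand)
    with the greatest end before the gene's start; distance =
    ``start - neighbor.end - 1``.  For a - strand gene it is the feature with
    the least start after the gene's end; distance =
    ``neighbor.start - gene.end - 1``.  An overlapping neighbor yields 0.
    Without a neighbor the distance runs to the contig edge (start-1 on the
    left; ``contig_length - end`` on the right, requiring contig lengths).
    """
    if not features:
        raise ValidationError("no gene features given")
    contig_lengths = dict(contig_lengths or {})
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in features:
        by_contig.setdefault(f.contig, []).append(f)

    records: list[UtrRecord] = []
    for contig, genes in by_contig.items():
        genes = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(genes):
            others = [h for h in genes if h.gene_id != g.gene_id]
            if g.strand == "+":
                candidates = [h for h in others if h.start < g.start]
                if candidates:
                    neighbor = max(candidates, key=lambda h: (h.end, h.gene_id))
                    gap = g.start - neighbor.end - 1
                    records.append(
                        UtrRecord(g.gene_id, max(gap, 0), neighbor.gene_id, False)
                    )
                else:
                    records.append(UtrRecord(g.gene_id, g.start - 1, None, True))
            else:
                candidates = [h for h in others if h.end > g.end]
                if candidates:
                    neighbor = min(candidates, key=lambda h: (h.start, h.gene_id))
                    gap = neighbor.start - g.end - 1
                    records.append(
                        UtrRecord(g.gene_id, max(gap, 0), neighbor.gene_id, False)
                    )
                else:
                    if contig not in contig_lengths:
                        raise ReferenceLookupError(
                            f"contig length needed for edge gene {g.gene_id!r} "
                            f"on {contig!r}"
                        )
                    gap = contig_lengths[contig] - g.end
                    records.append(UtrRecord(g.gene_id, max(gap, 0), None, True))
    order = {f.gene_id: i for i, f in enumerate(features)}
    records.sort(key=lambda r: order[r.gene_id])
    return records


def promoter_window(
    gene: GeneFeature, utr: UtrRecord, target_length: int = 1024
) -> PromoterWindow:
    """Window of length ``min(target_length, utr_length)`` flush with the 5' end.

    On + strand the half-open window is ``[start-1-L, start-1)``; on - strand
    the mirrored ``[end, end+L)``.  A zero-length UTR yields an empty window,
    flagged rather than raised.
    """
    if utr.gene_id != gene.gene_id:
        raise ValidationError(
            f"UTR record {utr.gene_id!r} does not belong to gene {gene.gene_id!r}"
        )
    if target_length < 0:
        raise ValidationError("target_length must be >= 0")
    length = min(target_length, utr.utr_length)
    if gene.strand == "+":
        end0 = gene.start - 1
        return PromoterWindow(gene.gene_id, gene.contig, end0 - length, end0, "+")
    start0 = gene.end
    return PromoterWindow(gene.gene_id, gene.contig, start0, start0 + length, "-")


def extract_sequence(fasta: Fasta | Path | str, window: PromoterWindow) -> str:
    """Promoter sequence, 5'->3' toward the start codon, uppercase.

    + strand windows are plain contig slices; - strand windows are reverse
    complemented so the returned string always reads into the gene.
    """
    if not isinstance(fasta, Fasta):
        fasta = Fasta(str(fasta))
    if window.contig not in fasta:
        raise ReferenceLookupError(f"contig {window.contig!r} not in FASTA")
    contig_len = len(fasta[window.contig])
    if window.start < 0 or window.end > contig_len:
        raise ReferenceLookupError(
            f"window [{window.start},{window.end}) outside contig "
            f"{window.contig!r} (length {contig_len})"
        )
    seq = fasta[window.contig][window.start:window.end].seq.upper()
    return reverse_complement(seq) if window.strand == "-" else seq


def write_bed6(
    windows: Iterable[tuple[PromoterWindow, float]], path: Path | str
) -> None:
    """BED6 of promoter windows; score column is the (rounded) median rank."""
    with open(path, "w") as fh:
        for window, score in windows:
            fh.write(
                f"{window.contig}\t{window.start}\t{window.end}\t"
                f"{window.gene_id}\t{round(score)}\t{window.strand}\n"
            )


def write_promoter_fasta(
    fasta: Fasta | Path | str,
    windows: Iterable[PromoterWindow],
    path: Path | str,
    line_width: int = 70,
) -> None:
    """Promoter sequences with headers ``>geneID|contig:start-end(strand)|len=L``."""
    if not isinstance(fasta, Fasta) and Path(str(fasta)).exists():
        fasta = Fasta(str(fasta))
    with open(path, "w") as fh:
        for w in windows:
            seq = extract_sequence(fasta, w)
            fh.write(f">{w.gene_id}|{w.contig}:{w.start}-{w.end}({w.strand})|len={w.length}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
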