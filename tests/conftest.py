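import textwrap
from pathlib import Path

import pytest

from promorank.annotation import GeneFeature
from promorank.expression import DatasetCollection, ExpressionDataset


@pytest.fixture
def tiny_collection() -> DatasetCollection:
    """3 genes x 2 datasets with forced orderings."""
    d1 = ExpressionDataset("d1", "c1", {"a": 10.0, "b": 7.5, "c": 9.9})
    d2 = ExpressionDataset("d2", "c1", {"a": 1.0, "b": 8.0, "c": 5.0})
    return DatasetCollection([d1, d2], gene_universe={"a", "b", "c"})


def write_genome(tmp_path: Path, genes, contig_sequences) -> tuple[Path, Path]:
    """Write a toy FASTA/GFF3 pair.

    ``genes``: iterable of (gene_id, contig, start, end, strand), 1-based
    inclusive.  ``contig_sequences``: mapping contig -> sequence string.
    """
    fasta = tmp_path / "genome.fasta"
    gff3 = tmp_path / "genes.gff3"
    with open(fasta, "w") as fh:
        for contig, seq in contig_sequences.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, seq in contig_sequences.items():
            fh.write(f"##sequence-region {contig} 1 {len(seq)}\n")
        for gene_id, contig, start, end, strand in genes:
            fh.write(
                f"{contig}\ttest\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene_id}\n"
            )
    return fasta, gff3


@pytest.fixture
def matrix_and_manifest(tmp_path: Path) -> tuple[Path, Path]:
    """Smallest TSV input: one matrix (3 genes x 2 samples), two datasets."""
    matrix = tmp_path / "matrix.tsv"
    matrix.write_text(textwrap.dedent("""\
        gene_id\ts1\ts2
        a\t10.0\t1.0
        b\t7.5\t8.0
        c\t9.9\t5.0
        """))
    manifest = tmp_path / "manifest.tsv"
    manifest.write_text(textwrap.dedent("""\
        sample_id\tdataset_id\tcondition
        s1\td1\tc1
        s2\td2\tc2
        """))
    return matrix, manifest


def make_feature(gene_id="g", contig="chr1", start=100, end=200, strand="+"):
    return GeneFeature(gene_id, contig, start, end, strand)
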