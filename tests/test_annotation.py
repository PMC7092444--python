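"""Gene models, upstream intergenic distances, promoter windows and extraction."""

import numpy as np
import pytest

from promorank import (InputFormatError, ReferenceLookupError, ValidationError)
from promorank.annotation import (GeneFeature, UtrRecord,
                                  compute_upstream_distance, extract_sequence,
                                  promoter_window, read_gene_features,
                                  reverse_complement, write_bed6)
from promorank.synthetic import SyntheticConfig, generate_expression, generate_genome

from conftest import make_feature, write_genome


def utr_of(records, gene_id):
    return next(r for r in records if r.gene_id == gene_id)


class TestReadGeneFeatures:
    def test_two_genes_sorted(self, tmp_path):
        fasta, gff3 = write_genome(
            tmp_path,
            [("g2", "chr1", 500, 700, "-"), ("g1", "chr1", 10, 100, "+")],
            {"chr1": "A" * 1000},
        )
        features, contig_lengths = read_gene_features(gff3)
        assert [f.gene_id for f in features] == ["g1", "g2"]
        assert contig_lengths == {"chr1": 1000}
        assert features[0] == GeneFeature("g1", "chr1", 10, 100, "+")

    def test_contig_lengths_fall_back_to_fasta(self, tmp_path):
        fasta, gff3 = write_genome(
            tmp_path, [("g1", "chr1", 10, 100, "+")], {"chr1": "ACGT" * 50}
        )
        # strip the sequence-region directives
        lines = [l for l in gff3.read_text().splitlines()
                 if not l.startswith("##sequence-region")]
        gff3.write_text("\n".join(lines) + "\n")
        _, contig_lengths = read_gene_features(gff3, fasta_path=fasta)
        assert contig_lengths == {"chr1": 200}

    def test_missing_feature_type_named_in_error(self, tmp_path):
        _, gff3 = write_genome(
            tmp_path, [("g1", "chr1", 10, 100, "+")], {"chr1": "A" * 200}
        )
        with pytest.raises(ValidationError, match="mRNA"):
            read_gene_features(gff3, feature_type="mRNA")

    def test_missing_id_attribute(self, tmp_path):
        gff3 = tmp_path / "noid.gff3"
        gff3.write_text(
            "##gff-version 3\n##sequence-region chr1 1 500\n"
            "chr1\tt\tgene\t10\t100\t.\t+\t.\tName=foo\n"
        )
        with pytest.raises(InputFormatError, match="ID"):
            read_gene_features(gff3)

    def test_unknown_contig(self, tmp_path):
        gff3 = tmp_path / "bad.gff3"
        gff3.write_text(
            "##gff-version 3\n##sequence-region chr1 1 500\n"
            "chr2\tt\tgene\t10\t100\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ReferenceLookupError, match="chr2"):
            read_gene_features(gff3)


class TestUpstreamDistance:
    def test_plus_strand_gap(self):
        genes = [make_feature("up", start=3000, end=3800, strand="+"),
                 make_feature("g", start=5000, end=6000, strand="+")]
        rec = utr_of(compute_upstream_distance(genes, {"chr1": 10000}), "g")
        assert rec.utr_length == 1199
        assert rec.upstream_neighbor_id == "up"
        assert not rec.at_contig_edge

    def test_minus_strand_gap_967(self):
        # a 967 bp upstream space realized on the - strand
        genes = [make_feature("g", start=100, end=900, strand="-"),
                 make_feature("next", start=1868, end=2500, strand="+")]
        rec = utr_of(compute_upstream_distance(genes, {"chr1": 5000}), "g")
        assert rec.utr_length == 967
        assert rec.upstream_neighbor_id == "next"

    def test_adjacent_plus_strand_967(self):
        genes = [make_feature("first", start=1, end=1000, strand="+"),
                 make_feature("second", start=1968, end=2500, strand="+")]
        recs = compute_upstream_distance(genes, {"chr1": 5000})
        assert utr_of(recs, "second").utr_length == 967
        first = utr_of(recs, "first")
        assert first.utr_length == 0 and first.at_contig_edge

    def test_contig_edges(self):
        plus = [make_feature("g", start=501, end=900, strand="+")]
        rec = compute_upstream_distance(plus, {"chr1": 2000})[0]
        assert (rec.utr_length, rec.at_contig_edge, rec.upstream_neighbor_id) == (
            500, True, None)
        minus = [make_feature("g", start=100, end=1500, strand="-")]
        rec = compute_upstream_distance(minus, {"chr1": 2000})[0]
        assert (rec.utr_length, rec.at_contig_edge) == (500, True)

    def test_overlapping_neighbor_gives_zero(self):
        genes = [make_feature("a", start=100, end=600, strand="+"),
                 make_feature("g", start=500, end=900, strand="+")]
        assert utr_of(compute_upstream_distance(genes, {"chr1": 2000}), "g").utr_length == 0

    def test_neighbor_strand_ignored(self):
        for neighbor_strand in "+-":
            genes = [make_feature("up", start=100, end=400, strand=neighbor_strand),
                     make_feature("g", start=1000, end=1500, strand="+")]
            rec = utr_of(compute_upstream_distance(genes, {"chr1": 5000}), "g")
            assert rec.utr_length == 599

    def test_empty_features_rejected(self):
        with pytest.raises(ValidationError):
            compute_upstream_distance([], {})


class TestPromoterWindow:
    @pytest.mark.parametrize("utr_len, target, expected", [
        (6093, 1024, 1024),   # roomy UTR capped at the target
        (967, 1024, 967),     # short UTR caps the window
        (0, 1024, 0),         # no space: empty window, flagged not raised
    ])
    def test_capping(self, utr_len, target, expected):
        gene = make_feature("g", start=10000, end=12000, strand="+")
        utr = UtrRecord("g", utr_len, "up", False)
        w = promoter_window(gene, utr, target)
        assert w.length == expected
        assert w.empty == (expected == 0)
        assert w.end == gene.start - 1  # abuts the 5' coordinate (0-based)

    def test_minus_strand_window_mirrored(self):
        gene = make_feature("g", start=100, end=900, strand="-")
        w = promoter_window(gene, UtrRecord("g", 967, "next", False), 1024)
        assert (w.start, w.end, w.strand) == (900, 1867, "-")

    def test_mismatched_record_rejected(self):
        gene = make_feature("g")
        with pytest.raises(ValidationError):
            promoter_window(gene, UtrRecord("other", 10, None, True))


class TestExtractSequence:
    def test_plus_and_minus_slices(self, tmp_path):
        fasta, _ = write_genome(tmp_path, [], {"chr1": "AAACGT"})
        from promorank.annotation import PromoterWindow
        plus = PromoterWindow("g", "chr1", 1, 4, "+")
        minus = PromoterWindow("g", "chr1", 1, 4, "-")
        assert extract_sequence(fasta, plus) == "AAC"
        assert extract_sequence(fasta, minus) == "GTT"

    def test_out_of_bounds(self, tmp_path):
        fasta, _ = write_genome(tmp_path, [], {"chr1": "AAACGT"})
        from promorank.annotation import PromoterWindow
        with pytest.raises(ReferenceLookupError):
            extract_sequence(fasta, PromoterWindow("g", "chr1", 2, 99, "+"))
        with pytest.raises(ReferenceLookupError):
            extract_sequence(fasta, PromoterWindow("g", "chrX", 0, 2, "+"))

    def test_strand_extractions_are_reverse_complements(self, tmp_path):
        """extract(+, w) == revcomp(extract(-, w)) over 100 random windows."""
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        fasta, _ = write_genome(tmp_path, [], {"chr1": seq})
        from promorank.annotation import PromoterWindow
        for _ in range(100):
            start = int(rng.integers(0, 4000))
            end = start + int(rng.integers(1, 900))
            plus = extract_sequence(fasta, PromoterWindow("g", "chr1", start, end, "+"))
            minus = extract_sequence(fasta, PromoterWindow("g", "chr1", start, end, "-"))
            assert plus == reverse_complement(minus)


def test_windows_never_overlap_gene_bodies(tmp_path):
    """On a generated genome, promoter windows stay inside intergenic space."""
    config = SyntheticConfig(n_genes=120, n_datasets=2, n_conditions=1,
                             n_constitutive=5, n_contigs=3, seed=9)
    _, truth = generate_expression(config)
    fasta, gff3 = generate_genome(config, truth, tmp_path / "g.fa",
                                  tmp_path / "g.gff3")
    features, contig_lengths = read_gene_features(gff3)
    utrs = compute_upstream_distance(features, contig_lengths)
    utr_by_gene = {u.gene_id: u for u in utrs}
    bodies = {}
    for f in features:
        bodies.setdefault(f.contig, []).append((f.start - 1, f.end))  # 0-based
    for f in features:
        utr = utr_by_gene[f.gene_id]
        w = promoter_window(f, utr, 1024)
        assert w.length == min(1024, utr.utr_length)
        for (bs, be) in bodies[f.contig]:
            assert w.end <= bs or w.start >= be or w.empty


def test_bed6_output(tmp_path):
    from promorank.annotation import PromoterWindow
    path = tmp_path / "out.bed"
    write_bed6([(PromoterWindow("g1", "chr1", 10, 1034, "+"), 4.5)], path)
    assert path.read_text() == "chr1\t10\t1034\tg1\t4\t+\n"
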