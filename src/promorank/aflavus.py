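"""Published prioritization summary for *Aspergillus flavus* NRRL 3357.

The thirteen top-ranked constitutively highly expressed genes from the
survey of 83 transcriptome microarray datasets (75 public sets under 28
secondary-metabolism-related conditions plus 8 in-house sets under 4
conditions), with their expression-rank summaries (minimum / maximum /
median over the 83 sets), the upstream intergenic distance to the next gene,
and — for the six genes whose upstream regions were taken forward as
promoters P1-P6 — the length of the sequence actually tested.

These rows serve as a reference fixture: re-applying the exclusion filters
(maximum rank <= 1000, 5'-UTR >= 950 bp) and the top-6 selection to them
must recover exactly the six promoter genes.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Number of transcriptome datasets in the survey (75 public + 8 in-house).
N_DATASETS = 83

#: Genes on the expression platform.
N_GENES = 13481

#: Published 83-dataset average expression values used in the worked
#: fold-change comparison: beta-tubulin (AFLA_051840) vs. the acetamidase
#: (amdS-homolog) gene AFLA_036780.
TUBULIN_MEAN_EXPRESSION = 11.5
AMDS_HOMOLOG_MEAN_EXPRESSION = 6.6


@dataclass(frozen=True)
class PublishedCandidate:
    gene_id: str
    min_rank: int
    max_rank: int
    median_rank: int
    utr_length: int
    tested_length: int | None     # None: upstream region not tested
    promoter_name: str | None
    description: str


TOP13_CANDIDATES: tuple[PublishedCandidate, ...] = (
    PublishedCandidate("AFLA_090780", 1, 32, 5, 1309, 1029, "P1",
                       "Translation elongation factor EF-1 alpha subunit (TEF1)"),
    PublishedCandidate("AFLA_064900", 19, 772, 12, 525, None, None,
                       "Hypothetical protein"),
    PublishedCandidate("AFLA_025100", 3, 886, 12, 1792, 1024, "P2",
                       "Glyceraldehyde 3-phosphate dehydrogenase (GpdA)"),
    PublishedCandidate("AFLA_014570", 1, 313, 12, 3461, 1024, "P3",
                       "Conserved hypothetical protein"),
    PublishedCandidate("AFLA_050690", 3, 174, 16, 314, None, None,
                       "Mitochondrial ADP/ATP carrier protein"),
    PublishedCandidate("AFLA_113120", 5, 177, 18, 6093, 1024, "P4",
                       "GPI-anchored cell wall organization protein (Ecm33)"),
    PublishedCandidate("AFLA_048690", 1, 1022, 18, 2918, None, None,
                       "Alcohol dehydrogenase, putative"),
    PublishedCandidate("AFLA_063260", 1, 11577, 19, 409, None, None,
                       "Conserved hypothetical protein"),
    PublishedCandidate("AFLA_083050", 1, 98, 21, 345, None, None,
                       "40S ribosomal protein S25"),
    PublishedCandidate("AFLA_052860", 1, 555, 27, 967, 967, "P5",
                       "Chaperone/heat shock protein (Hsp12)"),
    PublishedCandidate("AFLA_047870", 7, 128, 34, 41, None, None,
                       "40S ribosomal protein S16"),
    PublishedCandidate("AFLA_006300", 8, 570, 34, 2864, None, None,
                       "Nucleoside diphosphate kinase"),
    PublishedCandidate("AFLA_030930", 6, 140, 34, 2864, 1024, "P6",
                       "Fructose-bisphosphate aldolase, class II"),
)

#: The six genes whose upstream regions were tested as promoters, keyed by name.
PROMOTER_GENES: dict[str, str] = {
    c.promoter_name: c.gene_id for c in TOP13_CANDIDATES if c.promoter_name
}


def published_profiles():
    """The 13 published rows as :class:`~promorank.ranking.RankProfile`-like
    summaries usable by the filter/selection stage.

    Per-dataset rank vectors are not published, so each profile carries a
    synthetic two-entry rank map realizing the published min and max; the
    published median is kept verbatim.
    """
    from .ranking import RankProfile

    profiles = []
    for c in TOP13_CANDIDATES:
        profiles.append(
            RankProfile(
                gene_id=c.gene_id,
                ranks={"published_min": c.min_rank, "published_max": c.max_rank},
                min_rank=c.min_rank,
                max_rank=c.max_rank,
                median_rank=float(c.median_rank),
            )
        )
    return profiles


def published_utrs():
    """The 13 published upstream intergenic distances as UtrRecords."""
    from .annotation import UtrRecord

    return [UtrRecord(c.gene_id, c.utr_length, "unpublished", False)
            for c in TOP13_CANDIDATES]
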