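import pytest

from domainscan.types import (
    DomainAnnotation,
    DomainSource,
    GeneModel,
    MutationRecord,
    VariantClass,
)


@pytest.fixture
def vps25_model():
    """Single-exon plus-strand gene encoding a 176-residue protein."""
    return GeneModel(
        gene="VPS25",
        transcript_id="T_VPS25",
        chrom="chr17",
        strand="+",
        exons=((101, 101 + 176 * 3 - 1),),
        cds_start=101,
        cds_end=101 + 176 * 3 - 1,
        protein_length=176,
    )


@pytest.fixture
def vps25_annotations():
    """The two nested CATH superfamily occurrences and one Pfam domain."""
    return [
        DomainAnnotation("1.10.10.10", DomainSource.CATH, "VPS25", 102, 176),
        DomainAnnotation("1.10.10.570", DomainSource.CATH, "VPS25", 1, 176),
        DomainAnnotation("ESCRT-II", DomainSource.PFAM, "VPS25", 10, 145),
    ]


@pytest.fixture
def two_exon_minus_gene():
    """Two exons of 30 nt each on the minus strand (20 residues total)."""
    return GeneModel(
        gene="GMINUS",
        transcript_id="T_GMINUS",
        chrom="chr1",
        strand="-",
        exons=((1001, 1030), (1101, 1130)),
        cds_start=1001,
        cds_end=1130,
        protein_length=20,
    )


def make_mutation(
    pos,
    gene="VPS25",
    patient="P1",
    cancer="BRCA",
    vclass=VariantClass.MISSENSE,
    chrom="chr17",
):
    return MutationRecord(
        patient_id=patient,
        cancer_type=cancer,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref_allele="A",
        alt_allele="G",
        variant_class=vclass,
    )


@pytest.fixture
def mutation_factory():
    return make_mutation


def spliced_cds_oracle(model):
    """Brute-force residue map: genomic position -> residue index.

    Builds the explicit spliced CDS coordinate list in transcription order
    and indexes it — deliberately independent of the arithmetic used by
    ``mapping.genomic_to_residue``.
    """
    positions = []
    for lo, hi in model.exons:
        for p in range(lo, hi + 1):
            if model.cds_start <= p <= model.cds_end:
                positions.append(p)
    if model.strand == "-":
        positions.reverse()
    return {p: i // 3 + 1 for i, p in enumerate(positions)}
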