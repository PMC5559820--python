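"""Core record types shared across the pipeline.

All genomic and residue coordinates are 1-based inclusive, matching the
MAF / UniProt conventions of the upstream data sources.  Protein lengths
count coding residues only; the stop codon is excluded, so the total CDS
length in nucleotides is exactly ``3 * protein_length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class VariantClass(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


class DomainSource(str, Enum):
    PFAM = "PFAM"
    CATH = "CATH"


#: Label used for the union cohort of all cancer types.
PAN_CANCER = "PanCancer"


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation observed in one patient."""

    patient_id: str
    cancer_type: str
    gene: str
    chrom: str
    pos: int  # 1-based genomic coordinate
    ref_allele: str  # may be "" for an insertion
    alt_allele: str  # may be "" for a deletion
    variant_class: VariantClass

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.cancer_type:
            raise ValueError("cancer_type must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not isinstance(self.variant_class, VariantClass):
            object.__setattr__(
                self, "variant_class", VariantClass(self.variant_class)
            )


@dataclass(frozen=True)
class GeneModel:
    """Transcript structure of one protein-coding gene.

    One canonical transcript per gene: multi-isoform genes must be reduced
    upstream.  ``exons`` are (start, end) genomic intervals sorted by start;
    the CDS span lies within their union.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    protein_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = 0
        for start, end in exons:
            if start > end:
                raise ValueError(f"exon start {start} > end {end} in {self.gene}")
            if start <= prev_end:
                raise ValueError(f"exons overlap or unsorted in {self.gene}")
            prev_end = end
        if self.cds_start > self.cds_end:
            raise ValueError(f"cds_start > cds_end in {self.gene}")
        if self.cds_nt_length() != 3 * self.protein_length:
            raise ValueError(
                f"{self.gene}: CDS spans {self.cds_nt_length()} nt but "
                f"protein_length={self.protein_length} requires "
                f"{3 * self.protein_length}"
            )

    def cds_segments(self) -> list[tuple[int, int]]:
        """Exon pieces intersected with the CDS span, ascending."""
        segs = []
        for start, end in self.exons:
            lo = max(start, self.cds_start)
            hi = min(end, self.cds_end)
            if lo <= hi:
                segs.append((lo, hi))
        return segs

    def cds_nt_length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.cds_segments())


@dataclass(frozen=True)
class DomainAnnotation:
    """One occurrence of a domain on one protein."""

    domain_id: str
    source: DomainSource
    gene: str
    start_res: int
    end_res: int

    def __post_init__(self) -> None:
        if not isinstance(self.source, DomainSource):
            object.__setattr__(self, "source", DomainSource(self.source))
        if not (1 <= self.start_res <= self.end_res):
            raise ValueError(
                f"invalid residue interval [{self.start_res}, {self.end_res}] "
                f"for {self.domain_id} on {self.gene}"
            )

    @property
    def length(self) -> int:
        return self.end_res - self.start_res + 1


@dataclass(frozen=True)
class GeneSetDefinition:
    """A named gene set, optionally partitioned into groups (e.g. complexes)."""

    set_name: str
    members: tuple[tuple[str, Optional[str]], ...]  # (gene, group-or-None)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_name!r} has no members")
        object.__setattr__(
            self, "members", tuple((g, grp) for g, grp in self.members)
        )

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    def groups(self) -> dict[str, list[str]]:
        """Group label -> member genes, over grouped members only."""
        out: dict[str, list[str]] = {}
        for gene, grp in self.members:
            if grp is not None:
                out.setdefault(grp, []).append(gene)
        return out


@dataclass(frozen=True)
class DomainHit:
    """A non-synonymous mutation falling inside a domain occurrence."""

    mutation: MutationRecord
    domain_id: str
    source: DomainSource
    gene: str
    residue: int


@dataclass
class RegionTestResult:
    """Binomial enrichment test outcome for one region (domain or gene).

    ``p = l / L`` is the per-mutation probability of landing in the region
    under the uniform null; ``p_upper`` is the upper tail P(X >= k); the
    region is a candidate when ``p_upper < alpha / m``.
    """

    region_id: str
    l: int
    L: int
    n: int
    k: int
    p: float
    p_upper: float
    m: int
    alpha: float
    candidate: bool


@dataclass
class CancerCohort:
    """All post-filter mutations and domain hits for one cancer type."""

    cancer_type: str
    patients: set[str]
    mutations: list[MutationRecord]
    hits: list[DomainHit] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return len(self.patients)


@dataclass
class CandidateProfile:
    """Per-cancer candidate regions with coverage and specificity."""

    cancer_type: str
    source: str  # "PFAM", "CATH" or "GENE"
    results: list[RegionTestResult]
    coverage: dict[str, float] = field(default_factory=dict)
    specific_regions: set[str] = field(default_factory=set)
    specific_proteins: set[str] = field(default_factory=set)

    @property
    def candidate_ids(self) -> set[str]:
        return {r.region_id for r in self.results if r.candidate}


@dataclass
class OverlapResult:
    """Pfam-vs-CATH region overlap for one protein.

    Percentages are rounded half-up to integers for reporting (matching how
    such overlaps are usually quoted); the raw ratios are kept alongside.
    """

    gene: str
    pfam_region_len: int
    cath_region_len: int
    overlap_len: int
    pct_of_cath: int
    pct_of_pfam: int
    raw_pct_of_cath: float
    raw_pct_of_pfam: float
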