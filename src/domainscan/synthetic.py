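"""Synthetic gene models, domain annotations, gene sets and mutation cohorts.

The generator emulates the statistical structure of a multi-cancer somatic
mutation study: per-patient mutation lists scattered uniformly over the
coding genome, with optional planted enrichment multiplying the
per-position rate inside chosen domains.  Genes are laid end to end on one
synthetic chromosome with fixed intergenic gaps — enough structure to
exercise coordinate mapping without pretending to genome realism.

Planted enrichment is rejection-free: positions inside an enriched domain
simply carry ``fold`` times the background probability mass, so the fold
factor is controlled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    DomainAnnotation,
    DomainSource,
    GeneModel,
    GeneSetDefinition,
    MutationRecord,
    VariantClass,
)

__all__ = [
    "SyntheticConfig",
    "generate_gene_models",
    "generate_domain_annotations",
    "generate_gene_sets",
    "generate_cohort",
    "sample_region_counts",
]

_CHROM = "chrS"
_INTERGENIC_GAP = 100
_INTRON_RANGE = (30, 90)
_BASES = "ACGT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Scenario description for one synthetic dataset.

    Ranges are inclusive (lo, hi).  ``exon_length`` is in codons so the
    total CDS is always a whole number of codons.  ``mutations_per_patient``
    is a Poisson mean.  ``planted_enrichments`` maps domain ids to fold
    multipliers (>= 1) applied to the per-position mutation rate inside
    every occurrence of that domain.
    """

    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (1, 4)
    exon_length: tuple[int, int] = (20, 60)  # codons
    n_domains_pfam: int = 60
    n_domains_cath: int = 40
    domain_length: tuple[int, int] = (20, 80)  # residues
    cancer_types: tuple[str, ...] = ("CANCER_A", "CANCER_B", "CANCER_C", "CANCER_D")
    patients_per_cancer: int = 50
    mutations_per_patient: float = 20.0
    synonymous_fraction: float = 0.25
    planted_enrichments: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        def _positive(name, value):
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")

        _positive("n_genes", self.n_genes)
        _positive("n_domains_pfam", self.n_domains_pfam)
        _positive("n_domains_cath", self.n_domains_cath)
        _positive("patients_per_cancer", self.patients_per_cancer)
        if self.mutations_per_patient < 0:
            raise ValueError("mutations_per_patient must be >= 0")
        for name in ("exons_per_gene", "exon_length", "domain_length"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) invalid")
        if not (0.0 <= self.synonymous_fraction <= 1.0):
            raise ValueError("synonymous_fraction must lie in [0, 1]")
        for dom, fold in self.planted_enrichments:
            if fold < 1.0:
                raise ValueError(
                    f"planted_enrichments: fold for {dom} must be >= 1, got {fold}"
                )
        if not self.cancer_types:
            raise ValueError("cancer_types must be non-empty")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent streams per stage so regenerating one table never
    # perturbs another
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_gene_models(config: SyntheticConfig) -> list[GeneModel]:
    """Genes laid end to end on one chromosome, plus strand and splicing."""
    rng = _rng(config, 0)
    models = []
    cursor = 1
    for i in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exon_codons = rng.integers(config.exon_length[0],
                                   config.exon_length[1] + 1, size=n_exons)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor + _INTERGENIC_GAP
        for j, codons in enumerate(exon_codons):
            if j > 0:
                pos += int(rng.integers(*_INTRON_RANGE))
            start = pos
            end = pos + int(codons) * 3 - 1
            exons.append((start, end))
            pos = end + 1
        cursor = exons[-1][1]
        models.append(
            GeneModel(
                gene=f"G{i:04d}",
                transcript_id=f"T{i:04d}",
                chrom=_CHROM,
                strand=strand,
                exons=tuple(exons),
                cds_start=exons[0][0],
                cds_end=exons[-1][1],
                protein_length=int(exon_codons.sum()),
            )
        )
    return models


def _domain_ids(source: DomainSource, n: int) -> list[str]:
    if source is DomainSource.PFAM:
        return [f"PF{i:05d}" for i in range(1, n + 1)]
    return [f"1.10.{i}.10" for i in range(1, n + 1)]


def generate_domain_annotations(
    genes: list[GeneModel], config: SyntheticConfig
) -> list[DomainAnnotation]:
    """Place 1-3 occurrences of each domain id on randomly chosen genes."""
    rng = _rng(config, 1)
    lo, hi = config.domain_length
    eligible = [g for g in genes if g.protein_length >= lo]
    if not eligible:
        raise ValueError(
            f"no protein long enough for minimum domain length {lo}"
        )
    annotations = []
    specs = [(DomainSource.PFAM, config.n_domains_pfam),
             (DomainSource.CATH, config.n_domains_cath)]
    for source, n_domains in specs:
        for dom_id in _domain_ids(source, n_domains):
            n_occ = int(rng.integers(1, 4))
            for _ in range(n_occ):
                gene = eligible[int(rng.integers(len(eligible)))]
                max_len = min(hi, gene.protein_length)
                length = int(rng.integers(lo, max_len + 1))
                start = int(rng.integers(1, gene.protein_length - length + 2))
                annotations.append(
                    DomainAnnotation(
                        domain_id=dom_id,
                        source=source,
                        gene=gene.gene,
                        start_res=start,
                        end_res=start + length - 1,
                    )
                )
    return annotations


def generate_gene_sets(
    genes: list[GeneModel], config: SyntheticConfig, n_sets: int = 2,
    genes_per_set: int = 12, n_groups: int = 3,
) -> list[GeneSetDefinition]:
    """Small grouped gene sets (emulating e.g. complexes of organelle genes)."""
    rng = _rng(config, 2)
    sets = []
    for s in range(n_sets):
        size = min(genes_per_set, len(genes))
        chosen = rng.choice(len(genes), size=size, replace=False)
        members = tuple(
            (genes[int(i)].gene, f"GROUP_{int(i) % n_groups}")
            for i in sorted(chosen)
        )
        sets.append(GeneSetDefinition(f"SET_{s}", members))
    return sets


def _coding_position_table(genes: list[GeneModel]):
    """Arrays (genomic positions, gene index) over the whole coding genome,
    plus residue indices per position."""
    pos_chunks, gene_idx_chunks, residue_chunks = [], [], []
    for gi, g in enumerate(genes):
        segs = g.cds_segments()
        positions = np.concatenate(
            [np.arange(lo, hi + 1) for lo, hi in segs]
        )
        # CDS offsets in transcription order
        if g.strand == "-":
            order = np.argsort(-positions)
        else:
            order = np.argsort(positions)
        offsets = np.empty(len(positions), dtype=np.int64)
        offsets[order] = np.arange(1, len(positions) + 1)
        residues = (offsets + 2) // 3
        pos_chunks.append(positions)
        gene_idx_chunks.append(np.full(len(positions), gi, dtype=np.int64))
        residue_chunks.append(residues)
    return (
        np.concatenate(pos_chunks),
        np.concatenate(gene_idx_chunks),
        np.concatenate(residue_chunks),
    )


def generate_cohort(
    genes: list[GeneModel],
    domains: list[DomainAnnotation],
    config: SyntheticConfig,
) -> list[MutationRecord]:
    """Simulate all patients of all cancer types.

    Background mutations are uniform over coding positions; positions
    inside a planted domain's occurrences carry ``fold`` times the
    background mass (folds multiply where occurrences overlap).
    """
    known = {d.domain_id for d in domains}
    for dom_id, _ in config.planted_enrichments:
        if dom_id not in known:
            raise ValueError(
                f"planted domain {dom_id!r} unknown; known ids: "
                f"{sorted(known)[:20]}{'...' if len(known) > 20 else ''}"
            )
    rng = _rng(config, 3)
    positions, gene_idx, residues = _coding_position_table(genes)
    gene_names = [g.gene for g in genes]
    gene_index_by_name = {name: i for i, name in enumerate(gene_names)}

    weights = np.ones(len(positions), dtype=np.float64)
    for dom_id, fold in config.planted_enrichments:
        for ann in domains:
            if ann.domain_id != dom_id:
                continue
            gi = gene_index_by_name[ann.gene]
            inside = (
                (gene_idx == gi)
                & (residues >= ann.start_res)
                & (residues <= ann.end_res)
            )
            weights[inside] *= fold
    prob = weights / weights.sum()

    records: list[MutationRecord] = []
    for cancer in config.cancer_types:
        for p in range(config.patients_per_cancer):
            patient = f"{cancer}_P{p:04d}"
            n_mut = int(rng.poisson(config.mutations_per_patient))
            if n_mut == 0:
                continue
            idx = rng.choice(len(positions), size=n_mut, p=prob)
            syn = rng.random(n_mut) < config.synonymous_fraction
            ref_i = rng.integers(0, 4, size=n_mut)
            alt_shift = rng.integers(1, 4, size=n_mut)
            for i in range(n_mut):
                j = int(idx[i])
                vclass = (
                    VariantClass.SYNONYMOUS if syn[i] else VariantClass.MISSENSE
                )
                records.append(
                    MutationRecord(
                        patient_id=patient,
                        cancer_type=cancer,
                        gene=gene_names[int(gene_idx[j])],
                        chrom=_CHROM,
                        pos=int(positions[j]),
                        ref_allele=_BASES[int(ref_i[i])],
                        alt_allele=_BASES[(int(ref_i[i]) + int(alt_shift[i])) % 4],
                        variant_class=vclass,
                    )
                )
    return records


def sample_region_counts(
    lengths: np.ndarray,
    n: int,
    rng: np.random.Generator,
    folds: np.ndarray | None = None,
) -> np.ndarray:
    """Hit counts per region for ``n`` mutations falling on regions with the
    given residue lengths.

    Uniform placement over the concatenated regions makes the count vector
    multinomial with probabilities proportional to length; a fold vector
    multiplies the mass of enriched regions (the same rejection-free
    mixture the cohort generator uses, without materialising positions).
    """
    lengths = np.asarray(lengths, dtype=np.float64)
    if np.any(lengths <= 0):
        raise ValueError("region lengths must be strictly positive")
    mass = lengths if folds is None else lengths * np.asarray(folds, dtype=np.float64)
    return rng.multinomial(n, mass / mass.sum())
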