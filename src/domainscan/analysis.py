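"""Per-cancer and pan-cancer candidate analysis.

Cohorts are built per cancer type plus one pan-cancer union cohort, which
enters every Bonferroni family as one additional "type" (hence family
sizes of the form regions x (types + 1)).  Domain-level tests draw their
universe from the tested source only: n counts hits on that source's
domains, and L is the summed length of all its occurrences proteome-wide.
Gene-level tests use the genome-wide total coding length for L even when
only a restricted gene set is tested, while m scales with the set size.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import stats
from .mapping import assign_to_domains, genomic_to_residue
from .types import (
    CancerCohort,
    CandidateProfile,
    DomainAnnotation,
    DomainHit,
    DomainSource,
    GeneModel,
    GeneSetDefinition,
    MutationRecord,
    PAN_CANCER,
    RegionTestResult,
)

logger = logging.getLogger(__name__)

__all__ = [
    "build_cohorts",
    "test_domains",
    "test_genes",
    "test_gene_groups",
    "patient_coverage",
    "cumulative_coverage",
    "build_profile",
    "specific_regions",
    "specific_proteins",
    "restrict_gene_candidates",
    "compare_causal_list",
    "export_bipartite",
]


def build_cohorts(
    records: Sequence[MutationRecord],
    models: Sequence[GeneModel],
    annotations: Sequence[DomainAnnotation],
) -> list[CancerCohort]:
    """One cohort per cancer type plus the pan-cancer union (always last).

    ``records`` must already be filtered to coding non-synonymous.
    """
    if not records:
        logger.warning("no mutations supplied; returning no cohorts")
        return []
    by_type: dict[str, list[MutationRecord]] = {}
    for rec in records:
        by_type.setdefault(rec.cancer_type, []).append(rec)
    cohorts = []
    for cancer in sorted(by_type):
        muts = by_type[cancer]
        cohorts.append(
            CancerCohort(
                cancer_type=cancer,
                patients={m.patient_id for m in muts},
                mutations=muts,
                hits=assign_to_domains(muts, models, annotations),
            )
        )
    pan_muts = list(records)
    cohorts.append(
        CancerCohort(
            cancer_type=PAN_CANCER,
            patients={m.patient_id for m in pan_muts},
            mutations=pan_muts,
            hits=assign_to_domains(pan_muts, models, annotations),
        )
    )
    return cohorts


def _domain_lengths(
    annotations: Sequence[DomainAnnotation], source: DomainSource
) -> dict[str, int]:
    """Domain id -> summed residue length of all its occurrences."""
    lengths: dict[str, int] = {}
    for ann in annotations:
        if ann.source is source:
            lengths[ann.domain_id] = lengths.get(ann.domain_id, 0) + ann.length
    return lengths


def test_domains(
    cohort: CancerCohort,
    annotations: Sequence[DomainAnnotation],
    source: DomainSource,
    m: int,
    alpha: float = 0.05,
) -> list[RegionTestResult]:
    """Test every domain of one source against the in-universe uniform null.

    l_i sums all occurrences of domain i proteome-wide; L sums all domains
    of the source; n counts the cohort's hits on that source (one per
    mutation and domain id); k_i the hits on domain i.
    """
    lengths = _domain_lengths(annotations, source)
    if not lengths:
        raise ValueError(f"no {source.value} domains annotated")
    L = sum(lengths.values())
    if L <= 0:
        raise ValueError("total domain length is zero")
    source_hits = [h for h in cohort.hits if h.source is source]
    n = len(source_hits)
    counts: dict[str, int] = {}
    for h in source_hits:
        counts[h.domain_id] = counts.get(h.domain_id, 0) + 1
    return [
        stats.test_region(dom, lengths[dom], L, n, counts.get(dom, 0), m, alpha)
        for dom in sorted(lengths)
    ]


def _gene_mutation_counts(
    cohort: CancerCohort, models: Mapping[str, GeneModel]
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in cohort.mutations:
        model = models.get(rec.gene)
        if model is None:
            continue
        if genomic_to_residue(rec.pos, model) is not None:
            counts[rec.gene] = counts.get(rec.gene, 0) + 1
    return counts


def test_genes(
    cohort: CancerCohort,
    models: Sequence[GeneModel],
    gene_universe: Sequence[str],
    m: int,
    alpha: float = 0.05,
) -> list[RegionTestResult]:
    """Test each gene of ``gene_universe`` (coding length vs genome-wide L).

    n is every filtered coding mutation in the cohort, not just those in
    the universe: the null places any coding mutation on gene i with
    probability l_i / L.
    """
    by_name = {g.gene: g for g in models}
    unknown = [g for g in gene_universe if g not in by_name]
    if unknown:
        raise ValueError(f"genes absent from models: {unknown}")
    L = sum(g.protein_length for g in models)
    counts = _gene_mutation_counts(cohort, by_name)
    n = sum(counts.values())
    return [
        stats.test_region(
            gene, by_name[gene].protein_length, L, n, counts.get(gene, 0), m, alpha
        )
        for gene in gene_universe
    ]


def test_gene_groups(
    cohort: CancerCohort,
    models: Sequence[GeneModel],
    gene_set: GeneSetDefinition,
    m: int,
    alpha: float = 0.05,
) -> list[RegionTestResult]:
    """Group-level test: each group's l and k sum over its member genes."""
    by_name = {g.gene: g for g in models}
    groups = gene_set.groups()
    if not groups:
        raise ValueError(f"gene set {gene_set.set_name!r} has no group labels")
    unknown = [g for genes in groups.values() for g in genes if g not in by_name]
    if unknown:
        raise ValueError(f"genes absent from models: {unknown}")
    L = sum(g.protein_length for g in models)
    counts = _gene_mutation_counts(cohort, by_name)
    n = sum(counts.values())
    results = []
    for group in sorted(groups):
        members = groups[group]
        l = sum(by_name[g].protein_length for g in members)
        k = sum(counts.get(g, 0) for g in members)
        results.append(stats.test_region(group, l, L, n, k, m, alpha))
    return results


def _covered_patients(region_id: str, cohort: CancerCohort) -> set[str]:
    return {
        h.mutation.patient_id for h in cohort.hits if h.domain_id == region_id
    }


def patient_coverage(region_id: str, cohort: CancerCohort) -> float:
    """Percent of cohort patients with >= 1 mutation inside the region."""
    if not cohort.patients:
        raise ValueError(f"cohort {cohort.cancer_type} has no patients")
    return 100.0 * len(_covered_patients(region_id, cohort)) / len(cohort.patients)


def cumulative_coverage(region_ids: Iterable[str], cohort: CancerCohort) -> float:
    """Percent of patients covered by ANY of the listed regions (union)."""
    if not cohort.patients:
        raise ValueError(f"cohort {cohort.cancer_type} has no patients")
    ids = set(region_ids)
    covered = {
        h.mutation.patient_id for h in cohort.hits if h.domain_id in ids
    }
    return 100.0 * len(covered) / len(cohort.patients)


def build_profile(
    cohort: CancerCohort,
    source: DomainSource,
    results: Sequence[RegionTestResult],
) -> CandidateProfile:
    """Assemble a profile with per-candidate patient coverage."""
    profile = CandidateProfile(
        cancer_type=cohort.cancer_type,
        source=source.value,
        results=list(results),
    )
    for r in results:
        if r.candidate:
            profile.coverage[r.region_id] = patient_coverage(r.region_id, cohort)
    return profile


def specific_regions(profiles: Sequence[CandidateProfile]) -> list[CandidateProfile]:
    """Mark each candidate region specific to the only cancer type (if any)
    in which it is a candidate; pan-cancer does not count as a competitor."""
    individual = [p for p in profiles if p.cancer_type != PAN_CANCER]
    candidate_in: dict[str, set[str]] = {}
    for p in individual:
        for region in p.candidate_ids:
            candidate_in.setdefault(region, set()).add(p.cancer_type)
    for p in profiles:
        if p.cancer_type == PAN_CANCER:
            p.specific_regions = set()
            continue
        p.specific_regions = {
            region
            for region in p.candidate_ids
            if candidate_in[region] == {p.cancer_type}
        }
    return list(profiles)


def specific_proteins(
    profile: CandidateProfile,
    annotations: Sequence[DomainAnnotation],
    cohort: CancerCohort,
) -> set[str]:
    """Genes whose candidate domains are all specific to this cancer type.

    A gene qualifies iff it carries at least one candidate domain with a
    mutation in this cohort, and every candidate domain annotated on it is
    in the profile's specific set.
    """
    candidates = profile.candidate_ids
    source = DomainSource(profile.source)
    gene_candidate_doms: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.source is source and ann.domain_id in candidates:
            gene_candidate_doms.setdefault(ann.gene, set()).add(ann.domain_id)
    mutated_doms_by_gene: dict[str, set[str]] = {}
    for h in cohort.hits:
        if h.source is source:
            mutated_doms_by_gene.setdefault(h.gene, set()).add(h.domain_id)
    out = set()
    for gene, doms in gene_candidate_doms.items():
        mutated = mutated_doms_by_gene.get(gene, set()) & doms
        if mutated and doms <= profile.specific_regions:
            out.add(gene)
    profile.specific_proteins = out
    return out


def restrict_gene_candidates(
    gene_results: Mapping[str, Sequence[RegionTestResult]],
    profiles: Sequence[CandidateProfile],
    annotations: Sequence[DomainAnnotation],
) -> dict[str, list[str]]:
    """Per cancer type, candidate genes that also contain >= 1 candidate
    domain (of the profiles' source) in the same cancer type.

    ``gene_results`` maps cancer type -> gene-level test results; profiles
    must all share one source.
    """
    profile_by_type = {p.cancer_type: p for p in profiles}
    sources = {p.source for p in profiles}
    if len(sources) > 1:
        raise ValueError("profiles mix domain sources")
    source = DomainSource(next(iter(sources)))
    doms_by_gene: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.source is source:
            doms_by_gene.setdefault(ann.gene, set()).add(ann.domain_id)
    out: dict[str, list[str]] = {}
    for cancer, results in gene_results.items():
        profile = profile_by_type.get(cancer)
        candidate_doms = profile.candidate_ids if profile else set()
        kept = [
            r.region_id
            for r in results
            if r.candidate and doms_by_gene.get(r.region_id, set()) & candidate_doms
        ]
        out[cancer] = kept
    return out


def compare_causal_list(
    profiles: Sequence[CandidateProfile],
    causal_genes: Sequence[tuple[str, str]],
    annotations: Sequence[DomainAnnotation],
    cohorts: Sequence[CancerCohort],
) -> pd.DataFrame:
    """Compare an external causal-gene list against the candidate results.

    ``causal_genes`` holds (gene, cancer_type) pairs.  For each cancer type
    (and overall) counts the causal genes that have >= 1 domain of the
    source, that have mutations on those domains in the matching cohort,
    and that carry >= 1 candidate domain; percentages are of the causal
    genes listed for that type.
    """
    sources = {p.source for p in profiles}
    if len(sources) != 1:
        raise ValueError("profiles must share one domain source")
    source = DomainSource(next(iter(sources)))
    profile_by_type = {p.cancer_type: p for p in profiles}
    cohort_by_type = {c.cancer_type: c for c in cohorts}
    doms_by_gene: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.source is source:
            doms_by_gene.setdefault(ann.gene, set()).add(ann.domain_id)

    rows = []
    by_type: dict[str, list[str]] = {}
    for gene, cancer in causal_genes:
        by_type.setdefault(cancer, []).append(gene)
    for cancer in sorted(by_type) + ["overall"]:
        genes = (
            [g for gs in by_type.values() for g in gs]
            if cancer == "overall"
            else by_type[cancer]
        )
        with_dom = [g for g in genes if doms_by_gene.get(g)]
        if cancer == "overall":
            mutated_genes = {
                h.gene
                for c in cohorts
                for h in c.hits
                if h.source is source and c.cancer_type != PAN_CANCER
            }
            candidate_doms = set().union(
                *(p.candidate_ids for p in profiles)
            ) if profiles else set()
        else:
            cohort = cohort_by_type.get(cancer)
            mutated_genes = (
                {h.gene for h in cohort.hits if h.source is source}
                if cohort
                else set()
            )
            profile = profile_by_type.get(cancer)
            candidate_doms = profile.candidate_ids if profile else set()
        with_mut = [g for g in with_dom if g in mutated_genes]
        with_cand = [
            g for g in with_dom if doms_by_gene.get(g, set()) & candidate_doms
        ]
        total = len(genes)
        rows.append(
            {
                "cancer_type": cancer,
                "n_causal": total,
                "with_domain": len(with_dom),
                "with_domain_mutation": len(with_mut),
                "with_candidate_domain": len(with_cand),
                "pct_with_domain": 100.0 * len(with_dom) / total if total else 0.0,
                "pct_with_domain_mutation": (
                    100.0 * len(with_mut) / total if total else 0.0
                ),
                "pct_with_candidate_domain": (
                    100.0 * len(with_cand) / total if total else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


def export_bipartite(profiles: Sequence[CandidateProfile]) -> pd.DataFrame:
    """Cancer-type/candidate-region edge table, deterministically ordered."""
    rows = [
        {
            "cancer_type": p.cancer_type,
            "region_id": region,
            "source": p.source,
            "coverage_pct": p.coverage.get(region, 0.0),
            "specific": region in p.specific_regions,
        }
        for p in profiles
        for region in sorted(p.candidate_ids)
    ]
    df = pd.DataFrame(
        rows,
        columns=["cancer_type", "region_id", "source", "coverage_pct", "specific"],
    )
    return df.sort_values(
        ["cancer_type", "source", "region_id"], ignore_index=True
    )
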