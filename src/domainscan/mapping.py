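"""Genomic-to-protein coordinate conversion and domain assignment.

A mutation's genomic position is located within the spliced, strand-oriented
CDS of its gene's canonical transcript; the residue index is then
``ceil(cds_offset / 3)`` with a 1-based offset.  Indels are assigned to the
residue containing their start position.  Mutations are matched to every
distinct domain id whose occurrences contain the residue; overlapping
occurrences of the *same* id contribute a single hit, so a domain's count
is never inflated by self-overlap.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .types import (
    DomainAnnotation,
    DomainHit,
    GeneModel,
    MutationRecord,
    VariantClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "genomic_to_residue",
    "filter_coding_nonsynonymous",
    "assign_to_domains",
]


def genomic_to_residue(pos: int, model: GeneModel) -> Optional[int]:
    """Map a 1-based genomic position to a 1-based residue index.

    Returns None when the position falls outside the CDS (intron, UTR or
    intergenic).  On the minus strand the CDS reads from the highest
    genomic coordinate downward.
    """
    segs = model.cds_segments()
    if model.strand == "-":
        segs = segs[::-1]
    offset = 0
    for lo, hi in segs:
        if lo <= pos <= hi:
            if model.strand == "+":
                cds_off = offset + (pos - lo) + 1
            else:
                cds_off = offset + (hi - pos) + 1
            return (cds_off + 2) // 3
        offset += hi - lo + 1
    return None


def filter_coding_nonsynonymous(
    records: Iterable[MutationRecord], models: Sequence[GeneModel]
) -> list[MutationRecord]:
    """Keep non-synonymous mutations that map to a residue of some gene model.

    Input order is preserved; the operation is idempotent.  A record whose
    gene has no model is dropped (it cannot be placed on a protein).
    """
    by_gene = {m.gene: m for m in models}
    kept = []
    for rec in records:
        if rec.variant_class is VariantClass.SYNONYMOUS:
            continue
        model = by_gene.get(rec.gene)
        if model is None:
            continue
        if genomic_to_residue(rec.pos, model) is None:
            continue
        kept.append(rec)
    return kept


def assign_to_domains(
    records: Iterable[MutationRecord],
    models: Sequence[GeneModel],
    annotations: Sequence[DomainAnnotation],
) -> list[DomainHit]:
    """One DomainHit per (mutation, distinct domain id containing its residue).

    A mutation inside occurrences of two different domain ids yields two
    hits; inside two overlapping occurrences of one id, a single hit.
    Records whose gene is absent from the models are skipped with a
    warning (count reported once).
    """
    by_gene_model = {m.gene: m for m in models}
    ann_by_gene: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        ann_by_gene.setdefault(ann.gene, []).append(ann)

    hits: list[DomainHit] = []
    skipped = 0
    for rec in records:
        model = by_gene_model.get(rec.gene)
        if model is None:
            skipped += 1
            continue
        residue = genomic_to_residue(rec.pos, model)
        if residue is None:
            continue
        seen: set[tuple[str, str]] = set()
        for ann in ann_by_gene.get(rec.gene, ()):
            key = (ann.domain_id, ann.source.value)
            if key in seen:
                continue
            if ann.start_res <= residue <= ann.end_res:
                seen.add(key)
                hits.append(
                    DomainHit(
                        mutation=rec,
                        domain_id=ann.domain_id,
                        source=ann.source,
                        gene=rec.gene,
                        residue=residue,
                    )
                )
    if skipped:
        logger.warning("skipped %d mutation(s) whose gene has no model", skipped)
    return hits
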