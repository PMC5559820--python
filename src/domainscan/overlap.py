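"""Pfam-vs-CATH domain-region overlap per protein.

For a protein annotated in both databases, each source's occurrences are
first merged into a union of disjoint residue intervals; the two unions are
then intersected.  The overlap is reported as a percentage of each source's
union length.  Union-then-intersect matters: nested or repeated occurrences
of the same region must not be double-counted.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .types import DomainAnnotation, DomainSource, OverlapResult

__all__ = [
    "region_union",
    "intersect_unions",
    "protein_overlap",
    "average_overlap",
]


def region_union(
    intervals: Iterable[tuple[int, int]]
) -> tuple[list[tuple[int, int]], int]:
    """Coalesce 1-based inclusive intervals; returns (merged, total length).

    Adjacent intervals (end + 1 == next start) are merged, so splitting an
    interval into contiguous pieces never changes the result.
    """
    ivs = sorted(tuple(iv) for iv in intervals)
    for start, end in ivs:
        if start > end:
            raise ValueError(f"interval start {start} > end {end}")
    merged: list[tuple[int, int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    total = sum(end - start + 1 for start, end in merged)
    return merged, total


def intersect_unions(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> tuple[list[tuple[int, int]], int]:
    """Intersection of two disjoint-sorted interval lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out, sum(hi - lo + 1 for lo, hi in out)


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def protein_overlap(
    gene: str, annotations: Sequence[DomainAnnotation]
) -> Optional[OverlapResult]:
    """Overlap between a gene's Pfam and CATH domain regions.

    Returns None when the gene lacks annotations from either source (the
    comparison is undefined, not an error).
    """
    pfam = [(a.start_res, a.end_res) for a in annotations
            if a.gene == gene and a.source is DomainSource.PFAM]
    cath = [(a.start_res, a.end_res) for a in annotations
            if a.gene == gene and a.source is DomainSource.CATH]
    if not pfam or not cath:
        return None
    pfam_union, pfam_len = region_union(pfam)
    cath_union, cath_len = region_union(cath)
    _, overlap_len = intersect_unions(pfam_union, cath_union)
    raw_cath = 100.0 * overlap_len / cath_len
    raw_pfam = 100.0 * overlap_len / pfam_len
    return OverlapResult(
        gene=gene,
        pfam_region_len=pfam_len,
        cath_region_len=cath_len,
        overlap_len=overlap_len,
        pct_of_cath=_round_half_up(raw_cath),
        pct_of_pfam=_round_half_up(raw_pfam),
        raw_pct_of_cath=raw_cath,
        raw_pct_of_pfam=raw_pfam,
    )


def average_overlap(results: Sequence[OverlapResult]) -> tuple[float, float]:
    """Unweighted mean (pct of CATH region, pct of Pfam region) over proteins.

    Every protein counts equally regardless of its region lengths.
    """
    if not results:
        raise ValueError("average_overlap requires at least one result")
    mean_cath = sum(r.raw_pct_of_cath for r in results) / len(results)
    mean_pfam = sum(r.raw_pct_of_pfam for r in results) / len(results)
    return mean_cath, mean_pfam
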