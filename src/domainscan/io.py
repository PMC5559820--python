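"""Tab-separated readers/writers for the pipeline's four table types.

Formats (all TSV, UTF-8, one fixed header line, 1-based inclusive
coordinates):

mutations
    patient_id  cancer_type  gene  chrom  pos  ref_allele  alt_allele  variant_class

gene models
    gene  transcript_id  chrom  strand  exon_starts  exon_ends  cds_start  cds_end  protein_length
    (exon_starts / exon_ends are comma-separated, parallel, ascending)

domains
    domain_id  source  gene  start_res  end_res

gene sets
    set_name  gene  group        (group may be empty)

Readers validate every type invariant and report offending line numbers
(line 1 is the header).  No computation happens here.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence, Union

from .types import (
    DomainAnnotation,
    DomainSource,
    GeneModel,
    GeneSetDefinition,
    MutationRecord,
    VariantClass,
)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Structural problem with an input table (missing columns, bad header)."""


class RecordError(ValueError):
    """A specific line failed validation; the message names the line."""


MUTATION_COLUMNS = [
    "patient_id", "cancer_type", "gene", "chrom", "pos",
    "ref_allele", "alt_allele", "variant_class",
]
GENE_MODEL_COLUMNS = [
    "gene", "transcript_id", "chrom", "strand", "exon_starts",
    "exon_ends", "cds_start", "cds_end", "protein_length",
]
DOMAIN_COLUMNS = ["domain_id", "source", "gene", "start_res", "end_res"]
GENE_SET_COLUMNS = ["set_name", "gene", "group"]


def _read_rows(path: PathLike, required: Sequence[str]):
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames
        if header is None:
            raise FormatError(f"{path}: empty file, expected header {required}")
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            yield lineno, row


def _int_field(row, col, lineno, path) -> int:
    raw = row[col]
    try:
        return int(raw)
    except (TypeError, ValueError):
        raise RecordError(
            f"{path}, line {lineno}: cannot parse {col}={raw!r} as an integer"
        ) from None


def read_mutations(path: PathLike) -> list[MutationRecord]:
    records = []
    for lineno, row in _read_rows(path, MUTATION_COLUMNS):
        try:
            rec = MutationRecord(
                patient_id=row["patient_id"],
                cancer_type=row["cancer_type"],
                gene=row["gene"],
                chrom=row["chrom"],
                pos=_int_field(row, "pos", lineno, path),
                ref_allele=row["ref_allele"] or "",
                alt_allele=row["alt_allele"] or "",
                variant_class=VariantClass(row["variant_class"]),
            )
        except RecordError:
            raise
        except ValueError as exc:
            raise RecordError(f"{path}, line {lineno}: {exc}") from None
        records.append(rec)
    return records


def read_gene_models(path: PathLike) -> list[GeneModel]:
    models = []
    for lineno, row in _read_rows(path, GENE_MODEL_COLUMNS):
        try:
            starts = [int(x) for x in row["exon_starts"].split(",") if x]
            ends = [int(x) for x in row["exon_ends"].split(",") if x]
        except ValueError:
            raise RecordError(
                f"{path}, line {lineno}: unparseable exon coordinate list"
            ) from None
        if len(starts) != len(ends):
            raise RecordError(
                f"{path}, line {lineno}: exon_starts and exon_ends differ in length"
            )
        try:
            model = GeneModel(
                gene=row["gene"],
                transcript_id=row["transcript_id"],
                chrom=row["chrom"],
                strand=row["strand"],
                exons=tuple(zip(starts, ends)),
                cds_start=_int_field(row, "cds_start", lineno, path),
                cds_end=_int_field(row, "cds_end", lineno, path),
                protein_length=_int_field(row, "protein_length", lineno, path),
            )
        except RecordError:
            raise
        except ValueError as exc:
            raise RecordError(f"{path}, line {lineno}: {exc}") from None
        models.append(model)
    return models


def read_domains(
    path: PathLike, models: Sequence[GeneModel] | None = None
) -> list[DomainAnnotation]:
    """Read domain annotations; with ``models`` given, also check that each
    interval fits inside the annotated protein."""
    lengths = {m.gene: m.protein_length for m in models} if models else None
    annotations = []
    for lineno, row in _read_rows(path, DOMAIN_COLUMNS):
        try:
            ann = DomainAnnotation(
                domain_id=row["domain_id"],
                source=DomainSource(row["source"]),
                gene=row["gene"],
                start_res=_int_field(row, "start_res", lineno, path),
                end_res=_int_field(row, "end_res", lineno, path),
            )
        except RecordError:
            raise
        except ValueError as exc:
            raise RecordError(f"{path}, line {lineno}: {exc}") from None
        if lengths is not None and ann.gene in lengths:
            if ann.end_res > lengths[ann.gene]:
                raise RecordError(
                    f"{path}, line {lineno}: end_res {ann.end_res} exceeds "
                    f"protein length {lengths[ann.gene]} of {ann.gene}"
                )
        annotations.append(ann)
    return annotations


def read_gene_sets(path: PathLike) -> list[GeneSetDefinition]:
    by_set: dict[str, list[tuple[str, str | None]]] = {}
    order: list[str] = []
    for lineno, row in _read_rows(path, GENE_SET_COLUMNS):
        name = row["set_name"]
        if not name or not row["gene"]:
            raise RecordError(
                f"{path}, line {lineno}: set_name and gene must be non-empty"
            )
        if name not in by_set:
            by_set[name] = []
            order.append(name)
        group = row["group"] or None
        by_set[name].append((row["gene"], group))
    return [GeneSetDefinition(name, tuple(by_set[name])) for name in order]


def _mutation_row(r: MutationRecord) -> list[str]:
    return [r.patient_id, r.cancer_type, r.gene, r.chrom, str(r.pos),
            r.ref_allele, r.alt_allele, r.variant_class.value]


def _gene_model_row(m: GeneModel) -> list[str]:
    return [m.gene, m.transcript_id, m.chrom, m.strand,
            ",".join(str(s) for s, _ in m.exons),
            ",".join(str(e) for _, e in m.exons),
            str(m.cds_start), str(m.cds_end), str(m.protein_length)]


def _domain_row(d: DomainAnnotation) -> list[str]:
    return [d.domain_id, d.source.value, d.gene, str(d.start_res), str(d.end_res)]


_WRITERS = {
    MutationRecord: (MUTATION_COLUMNS, _mutation_row),
    GeneModel: (GENE_MODEL_COLUMNS, _gene_model_row),
    DomainAnnotation: (DOMAIN_COLUMNS, _domain_row),
}


def write_table(records: Iterable, path: PathLike) -> None:
    """Write a homogeneous list of records as TSV (header always written).

    For an empty list the record type cannot be inferred, so use
    ``write_empty_table`` instead, or pass any known type's records.
    Gene sets are flattened to one (set_name, gene, group) row per member.
    """
    records = list(records)
    path = Path(path)
    if not records:
        raise ValueError(
            "cannot infer columns from an empty list; use write_empty_table"
        )
    first = records[0]
    if isinstance(first, GeneSetDefinition):
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(GENE_SET_COLUMNS)
            for gs in records:
                for gene, group in gs.members:
                    w.writerow([gs.set_name, gene, group or ""])
        return
    for typ, (cols, rowfn) in _WRITERS.items():
        if isinstance(first, typ):
            with path.open("w", encoding="utf-8", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(cols)
                for rec in records:
                    if not isinstance(rec, typ):
                        raise ValueError("mixed record types in write_table")
                    w.writerow(rowfn(rec))
            return
    raise TypeError(f"unsupported record type {type(first).__name__}")


def write_empty_table(record_type: type, path: PathLike) -> None:
    """Header-only file for the given record type."""
    cols = {
        MutationRecord: MUTATION_COLUMNS,
        GeneModel: GENE_MODEL_COLUMNS,
        DomainAnnotation: DOMAIN_COLUMNS,
        GeneSetDefinition: GENE_SET_COLUMNS,
    }[record_type]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        csv.writer(fh, delimiter="\t", lineterminator="\n").writerow(cols)
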