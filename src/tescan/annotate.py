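"""Cluster annotation against reference TE tables and the polymorphic-TE
database (polyTEdb); classification as reference / known non-reference /
novel.

A cluster is *reference* when a reference-genome TE annotation of the
library's targeted subfamily has a 3' anchor within the annotation window
(600 bp by default) of the cluster interval; *known non-reference* when a
polymorphic-TE record of the same TE class (subfamily information is often
unavailable in such databases) lies within the window; *novel* otherwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .clustering import Cluster
from .core import (
    DEFAULT_SUBFAMILY_CLASS,
    DEFAULT_SUBFAMILY_SYNONYMS,
    InputError,
    PipelineParams,
)

REFERENCE = "reference"
POLYTEDB = "polyTEdb"


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated TE: a reference-genome insertion or a polyTEdb entry."""

    chrom: str
    start: int
    end: int
    strand: str  # "+", "-" or "unknown"
    te_class: str  # "LINE1" or "Alu"
    subfamily: Optional[str]
    source: str  # REFERENCE or POLYTEDB
    record_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError(f"annotation {self.record_id}: end must be > start")
        if self.source == REFERENCE and not self.subfamily:
            raise InputError(
                f"annotation {self.record_id}: reference records need a subfamily"
            )


@dataclass(frozen=True)
class TECall:
    """A retained cluster with its annotation-based classification."""

    cluster: Cluster
    status: str  # "reference", "known_non_reference" or "novel"
    matched_record_id: Optional[str]
    distance_bp: Optional[int]


def three_prime_anchors(record: AnnotationRecord) -> list[int]:
    """Positions used as the TE 3' end: interval end on "+", start on "-";
    both ends when the strand is unknown (each is tested)."""
    if record.strand == "+":
        return [record.end]
    if record.strand == "-":
        return [record.start]
    return [record.start, record.end]


def anchor_distance(start: int, end: int, anchor: int) -> int:
    """Distance from a half-open interval to a point: 0 if the point lies
    inside, else the gap to the nearer covered base."""
    if start <= anchor < end:
        return 0
    if anchor < start:
        return start - anchor
    return anchor - (end - 1)


def subfamily_matches(
    library_subfamily: str,
    record_subfamily: Optional[str],
    synonyms: Mapping[str, frozenset[str]] = DEFAULT_SUBFAMILY_SYNONYMS,
) -> bool:
    """Whether an annotation subfamily satisfies a targeted library,
    honouring synonym groups (e.g. AluYa5 and AluYa8 both satisfy the
    AluYa5/8 library)."""
    if record_subfamily is None:
        return False
    group = synonyms.get(library_subfamily, frozenset({library_subfamily}))
    return record_subfamily in group or record_subfamily == library_subfamily


def classify_cluster(
    cluster: Cluster,
    annotation_records: Sequence[AnnotationRecord],
    params: PipelineParams,
    synonyms: Mapping[str, frozenset[str]] = DEFAULT_SUBFAMILY_SYNONYMS,
    class_of: Mapping[str, str] = DEFAULT_SUBFAMILY_CLASS,
) -> TECall:
    """Classify one retained cluster.

    Reference annotations of the library's subfamily are tried first, then
    polyTEdb records of the library's class; each must have a 3' anchor
    within ``annotation_window_bp`` of the cluster interval. Ties break by
    smallest distance, then reference over polyTEdb, then lowest record id.
    """
    lib_class = class_of.get(cluster.subfamily_name)
    candidates: list[tuple[int, int, str, AnnotationRecord]] = []
    for rec in annotation_records:
        if rec.chrom != cluster.chrom:
            continue
        d = min(
            anchor_distance(cluster.start, cluster.end, a)
            for a in three_prime_anchors(rec)
        )
        if d > params.annotation_window_bp:
            continue
        if rec.source == REFERENCE and subfamily_matches(
            cluster.subfamily_name, rec.subfamily, synonyms
        ):
            candidates.append((d, 0, rec.record_id, rec))
        elif rec.source == POLYTEDB and rec.te_class == lib_class:
            candidates.append((d, 1, rec.record_id, rec))
    ref_hits = [c for c in candidates if c[1] == 0]
    pool = ref_hits if ref_hits else candidates
    if not pool:
        return TECall(cluster, "novel", None, None)
    d, rank, rid, rec = min(pool, key=lambda t: t[:3])
    status = "reference" if rank == 0 else "known_non_reference"
    return TECall(cluster, status, rid, d)


def classify_clusters(
    clusters: Iterable[Cluster],
    annotation_records: Sequence[AnnotationRecord],
    params: PipelineParams,
    **kwargs,
) -> list[TECall]:
    return [classify_cluster(c, annotation_records, params, **kwargs) for c in clusters]


_TSV_COLUMNS = [
    "chrom", "start", "end", "sample_id", "subfamily", "status",
    "matched_record_id", "distance_bp", "read1_count_hq", "read1_total",
    "read2_mapped_count", "polya_count", "member_ids",
]


def write_calls(calls: Sequence[TECall], output_path: str | Path) -> None:
    """Write classified calls as a TSV (``<output_path>``) and a BED6+
    sibling (``<output_path stem>.bed``), deterministically sorted by
    (chrom, start, sample, subfamily)."""
    output_path = Path(output_path)
    rows = sorted(
        calls,
        key=lambda c: (
            c.cluster.chrom, c.cluster.start, c.cluster.sample_id,
            c.cluster.subfamily_name,
        ),
    )
    with open(output_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for call in rows:
            c = call.cluster
            w.writerow([
                c.chrom, c.start, c.end, c.sample_id, c.subfamily_name,
                call.status,
                call.matched_record_id if call.matched_record_id is not None else ".",
                call.distance_bp if call.distance_bp is not None else ".",
                c.read1_count_hq, c.read1_total, c.read2_mapped_count,
                c.polya_count, ";".join(c.member_ids),
            ])
    bed_path = output_path.with_suffix(".bed")
    with open(bed_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for call in rows:
            c = call.cluster
            w.writerow([
                c.chrom, c.start, c.end,
                f"{c.sample_id}|{c.subfamily_name}|{call.status}",
                c.read1_count_hq, ".",
                c.read1_total, c.read2_mapped_count, c.polya_count,
            ])


def read_calls(path: str | Path) -> list[TECall]:
    """Read back a call TSV written by :func:`write_calls`."""
    calls: list[TECall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _TSV_COLUMNS:
            raise InputError(f"{path}: unexpected call-table header")
        for row in reader:
            cluster = Cluster(
                sample_id=row["sample_id"],
                subfamily_name=row["subfamily"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                read1_count_hq=int(row["read1_count_hq"]),
                read1_total=int(row["read1_total"]),
                read2_mapped_count=int(row["read2_mapped_count"]),
                polya_count=int(row["polya_count"]),
                member_ids=row["member_ids"].split(";") if row["member_ids"] else [],
            )
            calls.append(
                TECall(
                    cluster,
                    row["status"],
                    None if row["matched_record_id"] == "." else row["matched_record_id"],
                    None if row["distance_bp"] == "." else int(row["distance_bp"]),
                )
            )
    return calls


__all__ = [
    "POLYTEDB",
    "REFERENCE",
    "AnnotationRecord",
    "TECall",
    "anchor_distance",
    "classify_cluster",
    "classify_clusters",
    "read_calls",
    "subfamily_matches",
    "three_prime_anchors",
    "write_calls",
]
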