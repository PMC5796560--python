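"""Positional clustering of filtered read-1 anchors into candidate loci.

Clustering is single-linkage on read-1 start positions per chromosome
within one sample x subfamily library: sorted anchors whose start-position
gap is at most ``cluster_gap_bp`` join one cluster, so retained clusters
on a chromosome are separated by more than that gap. Thresholds then
require at least ``min_read1_per_cluster`` read-1 members at
MAPQ >= ``min_cluster_mapq`` and a cluster span of at least
``min_cluster_span_bp``; finally clusters overlapping the genome mask or
on an excluded chromosome are removed (kept in an audit list).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import AlignedPair, GenomeMask, PipelineParams, in_mask
from .filtering import FilterResult


@dataclass
class Cluster:
    """A positional group of filtered read-1 anchors for one library."""

    sample_id: str
    subfamily_name: str
    chrom: str
    start: int
    end: int
    read1_count_hq: int
    read1_total: int
    read2_mapped_count: int
    polya_count: int
    member_ids: list[str] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start


def cluster_reads(
    kept_pairs: Sequence[tuple[AlignedPair, FilterResult]],
    params: PipelineParams,
) -> list[Cluster]:
    """Single-linkage clustering of read-1 start positions.

    Pre: all pairs belong to one sample x subfamily library and have a
    mapped read 1. Output is deterministic, ordered by (chrom, start).
    """
    by_chrom: dict[str, list[tuple[AlignedPair, FilterResult]]] = {}
    for pair, res in kept_pairs:
        by_chrom.setdefault(pair.read1.chrom, []).append((pair, res))
    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda pr: (pr[0].read1.start, pr[0].pair_id))
        run: list[tuple[AlignedPair, FilterResult]] = []
        prev_start = None
        for pair, res in members:
            if prev_start is not None and pair.read1.start - prev_start > params.cluster_gap_bp:
                clusters.append(_make_cluster(run, params))
                run = []
            run.append((pair, res))
            prev_start = pair.read1.start
        if run:
            clusters.append(_make_cluster(run, params))
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def _make_cluster(
    members: Sequence[tuple[AlignedPair, FilterResult]], params: PipelineParams
) -> Cluster:
    first = members[0][0]
    return Cluster(
        sample_id=first.sample_id,
        subfamily_name=first.subfamily_name,
        chrom=first.read1.chrom,
        start=min(p.read1.start for p, _ in members),
        end=max(p.read1.end for p, _ in members),
        read1_count_hq=sum(
            1 for p, _ in members if p.read1.mapq >= params.min_cluster_mapq
        ),
        read1_total=len(members),
        read2_mapped_count=sum(1 for p, _ in members if p.read2.is_mapped),
        polya_count=sum(1 for _, r in members if r.polya_detected),
        member_ids=[p.pair_id for p, _ in members],
    )


def apply_cluster_thresholds(
    clusters: Iterable[Cluster], params: PipelineParams
) -> list[Cluster]:
    """Retain clusters with >= ``min_read1_per_cluster`` high-quality
    read-1 members and span >= ``min_cluster_span_bp``. Pure filter:
    order preserved, no cluster modified."""
    return [
        c
        for c in clusters
        if c.read1_count_hq >= params.min_read1_per_cluster
        and c.span >= params.min_cluster_span_bp
    ]


def apply_mask(
    clusters: Iterable[Cluster], mask: GenomeMask
) -> tuple[list[Cluster], list[tuple[Cluster, str]]]:
    """Remove clusters overlapping the mask or on excluded chromosomes.

    Returns (retained, removed) where each removed entry carries the mask
    reason for the audit trail.
    """
    retained: list[Cluster] = []
    removed: list[tuple[Cluster, str]] = []
    for c in clusters:
        if c.chrom in mask.excluded_chroms:
            removed.append((c, "excluded_chromosome"))
        elif in_mask(mask, c.chrom, c.start, c.end):
            removed.append((c, "masked_region"))
        else:
            retained.append(c)
    return retained, removed


__all__ = ["Cluster", "apply_cluster_thresholds", "apply_mask", "cluster_reads"]
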