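"""Pipeline orchestration: one library (sample x subfamily) at a time
through filter -> cluster -> threshold -> mask -> classify, with per-stage
count logging and audit outputs.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import io as tio
from .annotate import AnnotationRecord, TECall, classify_clusters, write_calls
from .clustering import Cluster, apply_cluster_thresholds, apply_mask, cluster_reads
from .core import (
    AlignedPair,
    ConfigError,
    GenomeMask,
    PipelineParams,
    SubfamilyProfile,
    build_mask,
)
from .filtering import FilterReason, apply_filters, filter_summary

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Everything one calling run needs.

    ``libraries`` maps subfamily name -> alignment path (one library per
    sample x subfamily); annotation and mask paths are optional (an absent
    annotation file simply leaves every call "novel"; absent mask files
    leave the genome unmasked apart from ``excluded_chroms``).
    """

    sample_id: str
    libraries: dict[str, str]
    profile_path: Optional[str] = None
    params_path: Optional[str] = None
    reference_annotation_path: Optional[str] = None
    polytedb_path: Optional[str] = None
    gap_bed_path: Optional[str] = None
    satellite_bed_path: Optional[str] = None
    out_dir: str = "tescan_out"

    def validate(self) -> None:
        for sub, path in self.libraries.items():
            if not Path(path).exists():
                raise ConfigError(f"library {sub}: missing alignment file {path}")
        for p in (self.profile_path, self.params_path,
                  self.reference_annotation_path, self.polytedb_path,
                  self.gap_bed_path, self.satellite_bed_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"missing input file {p}")


@dataclass
class LibraryResult:
    """Per-library pipeline outcome with the per-stage counts that feed a
    summary table."""

    sample_id: str
    subfamily_name: str
    calls: list[TECall]
    clusters_all: list[Cluster]
    clusters_retained: list[Cluster]
    clusters_masked: list[tuple[Cluster, str]]
    filter_tally: dict
    n_pairs_in: int

    def filter_tally_counter(self) -> Counter:
        return Counter(self.filter_tally)


def call_library(
    pairs: Sequence[AlignedPair],
    profile: SubfamilyProfile,
    params: PipelineParams,
    mask: GenomeMask,
    annotations: Sequence[AnnotationRecord],
) -> LibraryResult:
    """Run one library through the full calling cascade (in memory)."""
    kept, tally = apply_filters(pairs, profile, params)
    clusters = cluster_reads(kept, params)
    retained = apply_cluster_thresholds(clusters, params)
    unmasked, masked = apply_mask(retained, mask)
    calls = classify_clusters(unmasked, annotations, params)
    n_in = len(pairs)
    assert sum(tally.values()) == n_in, "filter tally must conserve pair count"
    logger.info(
        "%s/%s: %d pairs in, %d kept (%s), %d clusters, %d retained, "
        "%d masked, calls: %s",
        pairs[0].sample_id if pairs else "?",
        profile.name,
        n_in,
        len(kept),
        ", ".join(f"{r.value}={n}" for r, n in sorted(tally.items(), key=lambda x: x[0].value)),
        len(clusters),
        len(retained),
        len(masked),
        {s: sum(1 for c in calls if c.status == s)
         for s in ("reference", "known_non_reference", "novel")},
    )
    return LibraryResult(
        sample_id=pairs[0].sample_id if pairs else "",
        subfamily_name=profile.name,
        calls=calls,
        clusters_all=clusters,
        clusters_retained=retained,
        clusters_masked=masked,
        filter_tally=dict(tally),
        n_pairs_in=n_in,
    )


def _file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_call(manifest: RunManifest) -> dict[str, LibraryResult]:
    """Execute the calling pipeline for every library in a manifest.

    Writes per-library call tables (TSV + BED), filter summaries and a
    masked-cluster audit list under ``manifest.out_dir``; returns the
    in-memory results keyed by subfamily.
    """
    manifest.validate()
    from .core import default_profiles

    profiles = (
        tio.load_profiles(manifest.profile_path)
        if manifest.profile_path
        else default_profiles()
    )
    params = tio.load_params(manifest.params_path)
    gaps = tio.read_bed3(manifest.gap_bed_path) if manifest.gap_bed_path else []
    sats = tio.read_bed3(manifest.satellite_bed_path) if manifest.satellite_bed_path else []
    mask = build_mask(gaps, sats, params)
    annotations: list[AnnotationRecord] = []
    if manifest.reference_annotation_path:
        annotations += tio.read_annotation_bed(
            manifest.reference_annotation_path, "reference"
        )
    if manifest.polytedb_path:
        annotations += tio.read_annotation_bed(manifest.polytedb_path, "polyTEdb")

    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sub, path in manifest.libraries.items():
        logger.info("input %s: sha256 %s", path, _file_checksum(path))
    logger.info("parameters: %s", params)

    results: dict[str, LibraryResult] = {}
    for sub, path in manifest.libraries.items():
        if sub not in profiles:
            raise ConfigError(f"no subfamily profile for library {sub!r}")
        pairs = tio.read_alignments(path, manifest.sample_id, sub)
        res = call_library(pairs, profiles[sub], params, mask, annotations)
        results[sub] = res
        tag = sub.replace("/", "")
        write_calls(res.calls, out_dir / f"{manifest.sample_id}_{tag}_calls.tsv")
        summary = filter_summary(res.filter_tally_counter())
        tio.write_tsv(
            [{"metric": k, "value": v} for k, v in summary.items()],
            out_dir / f"{manifest.sample_id}_{tag}_filter_summary.tsv",
        )
        tio.write_tsv(
            [
                {
                    "chrom": c.chrom, "start": c.start, "end": c.end,
                    "reason": reason, "read1_total": c.read1_total,
                }
                for c, reason in res.clusters_masked
            ],
            out_dir / f"{manifest.sample_id}_{tag}_masked_audit.tsv",
        )
    return results


__all__ = ["LibraryResult", "RunManifest", "call_library", "run_call"]
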