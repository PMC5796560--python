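"""Readers and writers for the standard formats the pipeline consumes.

Alignments are read with pysam (SAM or BAM), genomes with pyfaidx, MEI
truth VCFs with cyvcf2; annotation/mask/truth tables are BED-like TSV.
All coordinates become 0-based half-open on the way in.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Iterator, Optional

import pysam
import yaml

from .annotate import POLYTEDB, REFERENCE, AnnotationRecord
from .core import (
    AlignedPair,
    ConfigError,
    InputError,
    PipelineParams,
    Read1,
    Read2,
    SubfamilyProfile,
)
from .evaluate import LongRead, TruthRecord


def read_alignments(
    path: str | Path, sample_id: str, subfamily_name: str
) -> list[AlignedPair]:
    """Read a coordinate-sorted, duplicate-marked SAM/BAM into
    :class:`AlignedPair` records (one per template).

    Secondary and supplementary records are skipped; read identity (first
    vs second of pair) comes from the pairing flags; read-2 sequences are
    reported in original (sequencing) orientation.
    """
    firsts: dict[str, pysam.AlignedSegment] = {}
    seconds: dict[str, pysam.AlignedSegment] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_read1:
                firsts[rec.query_name] = rec
            elif rec.is_read2:
                seconds[rec.query_name] = rec
    pairs: list[AlignedPair] = []
    for name in firsts:
        r1 = firsts[name]
        r2 = seconds.get(name)
        if r2 is None or r2.query_sequence is None:
            raise InputError(f"template {name!r}: missing read 2 sequence")
        if r1.is_unmapped:
            read1 = Read1(None, None, None, "+", 0, is_mapped=False)
        else:
            read1 = Read1(
                chrom=r1.reference_name,
                start=r1.reference_start,
                end=r1.reference_end,
                strand="-" if r1.is_reverse else "+",
                mapq=r1.mapping_quality,
                is_mapped=True,
            )
        seq2 = r2.get_forward_sequence() if not r2.is_unmapped else r2.query_sequence
        read2 = Read2(
            sequence=seq2,
            is_mapped=not r2.is_unmapped,
            mapq=r2.mapping_quality if not r2.is_unmapped else 0,
        )
        pairs.append(
            AlignedPair(
                sample_id=sample_id,
                subfamily_name=subfamily_name,
                read1=read1,
                read2=read2,
                is_duplicate=r1.is_duplicate or r2.is_duplicate,
                pair_id=name,
            )
        )
    pairs.sort(key=lambda p: (p.read1.chrom or "", p.read1.start or -1, p.pair_id))
    return pairs


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """BED3 intervals (extra columns ignored, track/browser lines skipped)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}: BED line with < 3 columns: {line!r}")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def read_annotation_bed(path: str | Path, source: str) -> list[AnnotationRecord]:
    """BED6-like annotation table.

    Column 4 (name) is ``subfamily`` for reference annotations
    (RepeatMasker-style) and ``class[:subfamily]`` for polyTEdb records
    (subfamily optional); column 6 is strand ("." = unknown).
    """
    if source not in (REFERENCE, POLYTEDB):
        raise ConfigError(f"unknown annotation source {source!r}")
    records: list[AnnotationRecord] = []
    alu_like = {"Alu", "ALU", "SVA_ALU"}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise InputError(f"{path}: annotation line with < 4 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "unknown"
            if source == REFERENCE:
                subfamily = name
                te_class = "Alu" if name.startswith("Alu") else "LINE1"
            else:
                bits = name.split(":")
                raw_class = bits[0]
                te_class = "Alu" if raw_class in alu_like or raw_class.startswith("Alu") else "LINE1"
                subfamily = bits[1] if len(bits) > 1 and bits[1] else None
            records.append(
                AnnotationRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    te_class=te_class,
                    subfamily=subfamily,
                    source=source,
                    record_id=f"{source}_{i:06d}",
                )
            )
    return records


def read_truth_bed(path: str | Path, source: str = "reference_truth") -> list[TruthRecord]:
    """Truth anchors from a BED file whose name column is
    ``subfamily[|...]`` (the simulator's truth.bed follows this layout)."""
    records: list[TruthRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise InputError(f"{path}: truth line with < 3 columns")
            name = f[3] if len(f) > 3 else ""
            subfamily = name.split("|")[0] if name else None
            records.append(
                TruthRecord(
                    chrom=f[0],
                    anchor_pos=int(f[1]),
                    subfamily=subfamily or None,
                    te_class="Alu" if (subfamily or "").startswith("Alu") else "LINE1",
                    source=source,
                    record_id=name or f"truth_{i:05d}",
                )
            )
    return records


def read_mei_truth_vcf(path: str | Path) -> list[TruthRecord]:
    """Mobile-element-insertion truth from a VCF (1000 Genomes Phase-3
    style): ``<INS:ME:ALU>`` / ``<INS:ME:LINE1>`` ALT alleles, optional
    MEINFO for the subfamily. Positions convert to 0-based anchors."""
    from cyvcf2 import VCF

    records: list[TruthRecord] = []
    for i, var in enumerate(VCF(str(path))):
        alt = var.ALT[0] if var.ALT else ""
        upper = alt.upper()
        if "ALU" in upper:
            te_class = "Alu"
        elif "LINE1" in upper or ":L1" in upper:
            te_class = "LINE1"
        else:
            continue
        meinfo = var.INFO.get("MEINFO")
        subfamily = None
        if meinfo:
            subfamily = str(meinfo).split(",")[0] or None
        records.append(
            TruthRecord(
                chrom=var.CHROM,
                anchor_pos=var.POS - 1,
                subfamily=subfamily,
                te_class=te_class,
                source="mei_truth",
                record_id=var.ID or f"mei_{i:05d}",
            )
        )
    return records


def read_long_reads(path: str | Path) -> list[LongRead]:
    """Long-read alignments (SAM/BAM) as footprint + full sequence."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    reads: list[LongRead] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_sequence is None:
                continue
            reads.append(
                LongRead(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    sequence=rec.query_sequence,
                )
            )
    return reads


def read_fasta(path: str | Path) -> dict[str, str]:
    """Whole-genome FASTA as a name -> sequence dict (pyfaidx-backed)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def load_profiles(path: str | Path) -> dict[str, SubfamilyProfile]:
    """Subfamily profiles from a YAML file: a mapping or list of records
    with name, te_class, target_primer, nested_primer, te_like,
    max_te_like_mismatches and optional index_tag."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ConfigError(f"{path}: empty profile file")
    entries = data.values() if isinstance(data, dict) else data
    profiles: dict[str, SubfamilyProfile] = {}
    for entry in entries:
        try:
            prof = SubfamilyProfile(**entry)
        except TypeError as exc:
            raise ConfigError(f"{path}: bad profile record: {exc}") from exc
        profiles[prof.name] = prof
    return profiles


def dump_profiles(profiles: dict[str, SubfamilyProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {name: dataclasses.asdict(p) for name, p in profiles.items()},
            fh, sort_keys=True,
        )


def load_params(path: Optional[str | Path]) -> PipelineParams:
    """Pipeline parameters from YAML; missing keys keep their defaults."""
    if path is None:
        return PipelineParams()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "excluded_chroms" in data:
        data["excluded_chroms"] = frozenset(data["excluded_chroms"])
    try:
        return PipelineParams(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: unknown parameter: {exc}") from exc


def write_tsv(rows: list[dict], path: str | Path) -> None:
    """Write a list of flat dicts as a TSV with a header row."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if not rows:
            fh.write("\n")
            return
        w = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t",
                           lineterminator="\n")
        w.writeheader()
        w.writerows(rows)


__all__ = [
    "dump_profiles",
    "load_params",
    "load_profiles",
    "read_alignments",
    "read_annotation_bed",
    "read_bed3",
    "read_fasta",
    "read_long_reads",
    "read_mei_truth_vcf",
    "read_truth_bed",
    "write_tsv",
]
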